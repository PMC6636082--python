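"""Forward TRF model: features, lagged design, fitting, shuffle nulls."""

import numpy as np
import pytest

import speechtrack as st
from speechtrack import synthetic
from speechtrack.containers import EEGRecording
from speechtrack.encoding import FEATURES, lag_axis
from speechtrack.envelope import Envelope
from speechtrack.filters import FilterSpec, apply_filter, design_fir
from speechtrack.synthetic import TRFComponent, make_ground_truth_trfs


class TestBuildFeatures:
    def test_quiet_native_condition(self):
        y = np.random.default_rng(0).uniform(0, 1, 100)
        f = st.build_features(y, np.zeros(100), 1.0, 1.0)
        assert np.all(f["background"] == 0)
        assert np.array_equal(f["clarity"], y)
        assert np.array_equal(f["comprehension"], y)

    def test_foreign_language_zeroes_comprehension(self):
        y = np.ones(50)
        f = st.build_features(y, y, 0.81, 0.0)
        assert np.all(f["comprehension"] == 0)
        assert np.allclose(f["clarity"], 0.81)
        assert np.allclose(f["background"], 1 - 0.81)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.build_features(np.ones(10), np.ones(11), 1.0, 1.0)

    def test_out_of_range_weights_rejected(self):
        with pytest.raises(ValueError):
            st.build_features(np.ones(5), np.ones(5), 1.5, 0.0)


class TestLaggedDesign:
    def test_single_feature_zero_lag_is_identity(self):
        f = np.arange(10.0)
        X, sl, lags = st.lagged_design([f], 0, 0, 100.0)
        assert np.array_equal(X[:, 0], f)
        assert sl == slice(0, 10)

    def test_column_count(self):
        feats = {k: np.zeros(500) for k in FEATURES}
        X, _, lags = st.lagged_design(feats, -500, 700, 100.0)
        assert X.shape[1] == 3 * len(lags)
        assert len(lags) == 121

    def test_deconvolution_recovers_known_kernel(self):
        """Convolving with a kernel then ridge-fitting at λ→0 inverts it."""
        rng = np.random.default_rng(1)
        f = rng.standard_normal(4000)
        kern = np.array([0.0, 0.5, 1.0, -0.3, 0.1])   # lags 0..4
        y = np.convolve(f, kern)[:4000]
        X, sl, lags = st.lagged_design([f], 0, 40, 100.0)
        from speechtrack._ridge import ridge_solve
        beta = ridge_solve(X, y[sl], 1e-10)
        assert np.allclose(beta, kern, atol=1e-6)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            st.lagged_design([np.zeros(50)], -500, 700, 100.0)


class TestFitTRF:
    def test_noiseless_recovery_is_exact(self, grid):
        gt = make_ground_truth_trfs(
            2, lag_axis(-200, 400, 100) * 10.0,
            [TRFComponent("clarity", 90.0, 40.0, 1.0),
             TRFComponent("background", 80.0, 40.0, 0.8),
             TRFComponent("comprehension", 230.0, 60.0, -1.0)], seed=0)
        envs = synthetic.synth_condition_envelopes(grid, 30.0, seed=1)
        eegs = synthetic.synth_eeg(grid, envs, gt, noise_gain=0.0, seed=2)
        conds = []
        for row, label in zip(grid, grid.labels):
            y_t, y_b = envs[label]
            conds.append((st.build_features(y_t, y_b, row.clarity_pct / 100,
                                            row.comprehension_pct / 100),
                          eegs[label]))
        trfs = st.fit_trf(conds, -200, 400, 100.0, lam=1e-8)
        for feat in FEATURES:
            for ch in range(2):
                r = np.corrcoef(trfs[feat][ch], gt.trfs[feat][ch])[0, 1]
                assert r > 0.999

    def test_zeroed_feature_has_null_coefficients(self, grid):
        """All-zero comprehension features yield an exactly zero TRF."""
        gt = make_ground_truth_trfs(
            2, lag_axis(-100, 300, 100) * 10.0,
            [TRFComponent("clarity", 90.0, 40.0, 1.0)], seed=3)
        g = grid.table.copy()
        g["comprehension_pct"] = 0
        from speechtrack.conditions import ConditionGrid
        zgrid = ConditionGrid(g)
        envs = synthetic.synth_condition_envelopes(zgrid, 20.0, seed=4)
        eegs = synthetic.synth_eeg(zgrid, envs, gt, noise_gain=0.0, seed=5)
        conds = []
        for row, label in zip(zgrid, zgrid.labels):
            y_t, y_b = envs[label]
            conds.append((st.build_features(y_t, y_b, row.clarity_pct / 100,
                                            0.0), eegs[label]))
        trfs = st.fit_trf(conds, -100, 300, 100.0, lam=1.0)
        assert np.allclose(trfs["comprehension"], 0.0, atol=1e-9)

    def test_linearity_in_the_eeg(self, grid, small_conditions):
        """TRFs of summed EEG equal the sum of separate TRFs at fixed λ."""
        conds_a = small_conditions
        conds_b = [(f, EEGRecording(e.data[:, ::-1].copy(), e.rate))
                   for f, e in conds_a]
        conds_sum = [(f, EEGRecording(ea.data + eb.data, ea.rate))
                     for (f, ea), (_, eb) in zip(conds_a, conds_b)]
        ta = st.fit_trf(conds_a, -100, 300, 100.0, lam=10.0)
        tb = st.fit_trf(conds_b, -100, 300, 100.0, lam=10.0)
        ts = st.fit_trf(conds_sum, -100, 300, 100.0, lam=10.0)
        for feat in FEATURES:
            assert np.allclose(ts[feat], ta[feat] + tb[feat], atol=1e-6)

    def test_estimator_api_and_lambda_selection(self, small_conditions):
        from sklearn.base import clone
        enc = st.TRFEncoder(lag_start_ms=-200, lag_stop_ms=400)
        enc2 = clone(enc)
        enc2.fit(small_conditions)
        assert enc2.lambda_ in np.asarray(enc2.lambda_grid)
        assert enc2.trf_["clarity"].shape == (3, 61)
        preds = enc2.predict(small_conditions[:1])
        assert preds[0].shape[0] == 3


class TestAverageTRFs:
    def _mk(self, scale):
        lags = np.arange(-10, 11) * 10.0
        return st.TRFSet({f: scale * np.ones((2, 21)) for f in FEATURES},
                         lags)

    def test_single_subject_identity(self):
        t = self._mk(1.0)
        avg = st.average_trfs([t])
        for f in FEATURES:
            assert np.array_equal(avg[f], t[f])

    def test_opposite_subjects_cancel(self):
        avg = st.average_trfs([self._mk(1.0), self._mk(-1.0)])
        assert np.all(avg["clarity"] == 0)

    def test_averaging_reduces_error(self, grid):
        """The subject-average TRF is closer to truth than single fits."""
        gt = make_ground_truth_trfs(
            2, lag_axis(-100, 300, 100) * 10.0,
            [TRFComponent("clarity", 90.0, 40.0, 1.0)], seed=6)
        fits = []
        for subj in range(3):
            envs = synthetic.synth_condition_envelopes(grid, 20.0,
                                                       seed=10 + subj)
            eegs = synthetic.synth_eeg(grid, envs, gt, noise_gain=2.0,
                                       seed=20 + subj)
            conds = []
            for row, label in zip(grid, grid.labels):
                y_t, y_b = envs[label]
                conds.append((st.build_features(
                    y_t, y_b, row.clarity_pct / 100,
                    row.comprehension_pct / 100), eegs[label]))
            fits.append(st.fit_trf(conds, -100, 300, 100.0, lam=1.0))
        avg = st.average_trfs(fits)
        err_avg = np.linalg.norm(avg["clarity"] - gt.trfs["clarity"])
        errs = [np.linalg.norm(f["clarity"] - gt.trfs["clarity"])
                for f in fits]
        assert err_avg < np.median(errs)

    def test_axis_mismatch_rejected(self):
        a = self._mk(1.0)
        b = st.TRFSet({f: np.ones((2, 5)) for f in FEATURES},
                      np.arange(5) * 10.0)
        with pytest.raises(ValueError):
            st.average_trfs([a, b])


class TestShuffleNull:
    def test_thresholds_symmetric_and_positive(self, small_conditions):
        null = st.shuffle_null_trf(small_conditions, n_shuffles=100, seed=0,
                                   lag_start_ms=-200, lag_stop_ms=400,
                                   lam=100.0)
        for f in FEATURES:
            assert np.all(null.sd[f] > 0)
            assert np.all(null.threshold[f] > 0)

    def test_masks_detect_injected_and_ignore_absent_components(
            self, grid, small_synth, small_conditions):
        enc = st.TRFEncoder(lag_start_ms=-200, lag_stop_ms=400, lam=100.0)
        enc.fit(small_conditions)
        null = st.shuffle_null_trf(small_conditions, n_shuffles=100, seed=1,
                                   lag_start_ms=-200, lag_stop_ms=400,
                                   lam=100.0)
        masks = st.significant_regions(enc.trf_, null)
        lags = enc.trf_.lags_ms
        # clarity truth peaks at 90 ms: the mask must contain it
        near_peak = (lags >= 50) & (lags <= 130)
        assert masks["clarity"][:, near_peak].any()

    def test_mask_monotone_in_p(self, small_conditions):
        enc = st.TRFEncoder(lag_start_ms=-200, lag_stop_ms=400, lam=100.0)
        enc.fit(small_conditions)
        loose = st.shuffle_null_trf(small_conditions, n_shuffles=100, seed=2,
                                    lag_start_ms=-200, lag_stop_ms=400,
                                    lam=100.0, p=0.05)
        strict = st.shuffle_null_trf(small_conditions, n_shuffles=100, seed=2,
                                     lag_start_ms=-200, lag_stop_ms=400,
                                     lam=100.0, p=0.001)
        m_loose = st.significant_regions(enc.trf_, loose)
        m_strict = st.significant_regions(enc.trf_, strict)
        for f in FEATURES:
            assert not (m_strict[f] & ~m_loose[f]).any()

    def test_too_few_shuffles_rejected(self, small_conditions):
        with pytest.raises(ValueError):
            st.shuffle_null_trf(small_conditions, n_shuffles=10)


class TestSignificantLagRuns:
    def test_isolated_cells_removed_runs_kept(self):
        mask = np.array([[False, True, False, True, True, False]])
        out = st.significant_lag_runs(mask, min_run=2)
        assert not out[0, 1]
        assert out[0, 3] and out[0, 4]

    def test_run_at_boundary(self):
        mask = np.array([[True, True, False, False, False, True]])
        out = st.significant_lag_runs(mask, min_run=2)
        assert out[0, 0] and out[0, 1] and not out[0, 5]


class TestCausalPath:
    """The minimum-phase control for pre-stimulus artifacts."""

    def _causal_conditions(self, grid, gt, seed):
        envs = synthetic.synth_condition_envelopes(grid, 40.0, seed=seed)
        eegs = synthetic.synth_eeg(grid, envs, gt, noise_gain=1.0,
                                   seed=seed + 100)
        kernel = design_fir(FilterSpec("lowpass", cutoff_hi=16.0,
                                       transition_bw=16.0, order=202,
                                       phase="minimum"), 100)
        conds = []
        for row, label in zip(grid, grid.labels):
            y_t, y_b = envs[label]
            f = st.build_features(
                st.band_envelope(y_t, "broadband", 100.0, causal=True),
                st.band_envelope(y_b, "broadband", 100.0, causal=True),
                row.clarity_pct / 100, row.comprehension_pct / 100)
            e = apply_filter(eegs[label].data, kernel, "causal")
            conds.append((f, EEGRecording(e, 100.0)))
        return conds

    def test_genuine_prestimulus_component_survives_causal_filtering(
            self, grid):
        """A true pre-stimulus comprehension response stays significant at
        negative lags even under the strictly causal filter path."""
        gt = make_ground_truth_trfs(
            3, lag_axis(-500, 700, 100) * 10.0,
            [TRFComponent("background", 80.0, 40.0, 0.8),
             TRFComponent("clarity", 90.0, 40.0, 1.0),
             TRFComponent("comprehension", -110.0, 50.0, 1.5)], seed=0)
        conds = self._causal_conditions(grid, gt, seed=0)
        enc = st.TRFEncoder(lam=None).fit(conds)
        null = st.shuffle_null_trf(conds, n_shuffles=100, seed=0,
                                   lam=enc.lambda_)
        mask = st.significant_lag_runs(
            st.significant_regions(enc.trf_, null)["comprehension"])
        neg = enc.trf_.lags_ms < 0
        assert mask[:, neg].any()
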