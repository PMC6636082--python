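"""Second-level clarity/comprehension decoding and its permutation nulls."""

import itertools

import numpy as np
import pytest

import speechtrack as st
from speechtrack.backward import LagCorrelationTensor
from speechtrack.property_decoder import (NullDistribution,
                                          coefficient_null_band)

LAGS = st.make_lag_grid().lags_ms()


def _tensors_from(signal_fn, grid, n_seg=6, seed=0, noise=0.1):
    """Build per-condition lag tensors where the mean level at each lag is
    signal_fn(condition_row) and segments add Gaussian noise."""
    rng = np.random.default_rng(seed)
    tensors = {}
    for row, label in zip(grid, grid.labels):
        base = signal_fn(row)             # length-31 mean profile
        vals = base[:, None] + noise * rng.standard_normal((31, n_seg))
        tensors[label] = LagCorrelationTensor(vals, LAGS, condition=label)
    return tensors


class TestAssemble:
    def test_row_count_and_targets(self, grid):
        tensors = _tensors_from(lambda r: np.zeros(31), grid, n_seg=9)
        X, y, cond = st.assemble_training_table(tensors, grid, "clarity")
        assert X.shape == (72, 31)
        # English and Dutch rows at matched noise share clarity targets
        clarities = {c: y[cond == c][0] for c in range(8)}
        for i in range(4):
            assert clarities[i] == clarities[i + 4]
        ydutch = st.assemble_training_table(tensors, grid, "comprehension")[1]
        assert np.all(ydutch[36:] == 0)

    def test_nan_segments_dropped(self, grid):
        tensors = _tensors_from(lambda r: np.zeros(31), grid, n_seg=4)
        tensors["english-quiet"].values[3, 1] = np.nan
        X, y, cond = st.assemble_training_table(tensors, grid, "clarity")
        assert X.shape == (31, 31)

    def test_missing_condition_rejected(self, grid):
        tensors = _tensors_from(lambda r: np.zeros(31), grid)
        del tensors["dutch-high"]
        with pytest.raises(ValueError):
            st.assemble_training_table(tensors, grid, "clarity")


class TestRmse:
    def test_examples(self):
        assert st.rmse(np.arange(5.0), np.arange(5.0)) == 0.0
        assert st.rmse(np.arange(5.0) + 2.5, np.arange(5.0)) == 2.5
        assert st.rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == \
            pytest.approx(3.5355, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.rmse(np.array([]), np.array([]))


class TestPropertyDecoder:
    def test_noiseless_linear_target_gives_zero_rmse(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 31))
        y = 3.0 * X[:, 4] + 1.0
        dec, zhat = st.fit_property_decoder(X, y)
        assert dec.cv_rmse_ < 1e-6
        assert st.rmse(zhat, y) < 1e-6

    def test_permuted_targets_score_at_target_sd(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 31))
        y = rng.permutation(np.repeat([0.0, 50.0, 100.0], 67))[:200]
        dec, _ = st.fit_property_decoder(X, y)
        assert dec.cv_rmse_ == pytest.approx(np.std(y), rel=0.15)

    def test_selected_lambda_minimises_cv_rmse(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 31))
        y = X[:, 0] + 0.5 * rng.standard_normal(80)
        dec = st.PropertyDecoder().fit(X, y)
        from speechtrack._ridge import FoldedRidge, contiguous_folds
        fr = FoldedRidge(X, contiguous_folds(80, 5),
                         np.asarray(dec.lambda_grid, float))
        preds = fr.cv_predict(y)
        rmses = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        assert dec.cv_rmse_ <= rmses.min() + 1e-12

    def test_constant_targets_rejected(self):
        with pytest.raises(ValueError):
            st.PropertyDecoder().fit(np.zeros((10, 3)), np.ones(10))


class TestForwardTransform:
    def test_whitened_features_give_pattern_proportional_to_weights(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20000, 5))
        rho = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        pat = st.forward_transform(rho, X)
        assert np.allclose(pat / pat[0], rho / rho[0], atol=0.05)

    def test_pattern_peaks_at_informative_lag(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(2000)
        X = 0.1 * rng.standard_normal((2000, 8))
        X[:, 5] += z
        dec, _ = st.fit_property_decoder(X, z)
        pat = st.forward_transform(dec.coef_, X)
        assert np.argmax(np.abs(pat)) == 5

    def test_equivariance_under_feature_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((500, 6))
        rho = rng.standard_normal(6)
        perm = rng.permutation(6)
        a = st.forward_transform(rho, X)[perm]
        b = st.forward_transform(rho[perm], X[:, perm])
        assert np.allclose(a, b, atol=1e-10)

    def test_zero_variance_prediction_rejected(self):
        with pytest.raises(ValueError):
            st.forward_transform(np.zeros(3),
                                 np.random.default_rng(6).standard_normal(
                                     (50, 3)))


class TestShuffleNull:
    def test_strong_signal_reaches_minimal_p(self, grid):
        clar = grid.clarity()
        tensors = _tensors_from(
            lambda r: np.full(31, r.clarity_pct / 100.0), grid,
            noise=0.01, seed=6)
        dist, dec = st.shuffle_null_rmse(tensors, grid, "clarity",
                                         n_shuffles=100, seed=0)
        assert dist.p_value == pytest.approx(1 / 101, abs=1e-9)

    def test_determinism_per_seed(self, grid):
        tensors = _tensors_from(lambda r: np.zeros(31), grid, seed=7)
        a, _ = st.shuffle_null_rmse(tensors, grid, "clarity",
                                    n_shuffles=100, seed=3)
        b, _ = st.shuffle_null_rmse(tensors, grid, "clarity",
                                    n_shuffles=100, seed=3)
        assert a.p_value == b.p_value
        assert np.array_equal(a.samples, b.samples)

    def test_too_few_shuffles_rejected(self, grid):
        tensors = _tensors_from(lambda r: np.zeros(31), grid)
        with pytest.raises(ValueError):
            st.shuffle_null_rmse(tensors, grid, "clarity", n_shuffles=50)

    def test_anti_leakage_between_properties(self, grid):
        """Profiles driven purely by clarity do not let the comprehension
        decoder beat its null: the single model spanning all eight
        conditions cannot exploit acoustics-only structure."""
        tensors = _tensors_from(
            lambda r: np.full(31, r.clarity_pct / 100.0), grid,
            noise=0.05, seed=8)
        # comprehension targets decouple from clarity on the Dutch half
        dist, _ = st.shuffle_null_rmse(tensors, grid, "comprehension",
                                       n_shuffles=200, seed=1)
        # clarity-only structure may fit the English half but the Dutch
        # conditions anchor the null; p should not be extreme
        assert dist.p_value > 0.01


class TestCoefficientNullBand:
    def test_observed_at_null_median_is_nonsignificant(self):
        rng = np.random.default_rng(9)
        nulls = rng.standard_normal((500, 31))
        obs = np.median(nulls, axis=0)
        out = coefficient_null_band(obs, nulls, q=0.05)
        assert not out["significant"].any()

    def test_single_extreme_lag_detected(self):
        # enough nulls that the add-one two-sided p can clear BH at rank 1
        rng = np.random.default_rng(10)
        nulls = rng.standard_normal((2000, 31))
        obs = np.median(nulls, axis=0)
        obs[7] = 10.0
        out = coefficient_null_band(obs, nulls, q=0.05)
        assert out["significant"][7]
        assert out["significant"].sum() == 1
        assert out["band_lo"][7] < out["band_hi"][7]

    def test_requires_enough_nulls(self):
        with pytest.raises(ValueError):
            coefficient_null_band(np.zeros(5), np.zeros((50, 5)))


def _bh_oracle(p, q):
    """Definitional Benjamini–Hochberg: largest k with p_(k) <= kq/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, bool)
    if len(below):
        reject[order[:below[-1] + 1]] = True
    return reject


def test_bh_matches_definitional_oracle_exhaustively():
    """Library BH equals brute-force definition on all small p-vectors."""
    levels = [0.001, 0.01, 0.04, 0.2, 0.9]
    for m in (1, 2, 3):
        for combo in itertools.product(levels, repeat=m):
            p = np.array(combo)
            assert np.array_equal(st.benjamini_hochberg(p, 0.05),
                                  _bh_oracle(p, 0.05)), combo
    rng = np.random.default_rng(11)
    for _ in range(200):
        p = rng.uniform(0, 1, rng.integers(1, 7))
        assert np.array_equal(st.benjamini_hochberg(p, 0.05),
                              _bh_oracle(p, 0.05))


def test_bh_single_small_p_among_large():
    p = np.array([0.001] + [0.9] * 30)
    rej = st.benjamini_hochberg(p, 0.05)
    assert rej[0] and rej.sum() == 1


def test_bh_invariant_to_input_order():
    rng = np.random.default_rng(12)
    p = rng.uniform(0, 1, 20)
    perm = rng.permutation(20)
    assert np.array_equal(st.benjamini_hochberg(p, 0.05)[perm],
                          st.benjamini_hochberg(p[perm], 0.05))
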