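"""Forward (encoding) TRF model of clarity- and comprehension-weighted speech.

Each EEG channel j is modelled as the superposition of three convolved
stimulus features::

    ê_j = (1 − a) · T_B ∗ y_B  +  T_A ∗ (a · y_T)  +  T_C ∗ (c · y_T)

where y_T and y_B are the target-speech and babble envelopes, a and c
the condition's clarity and comprehension, and T_B, T_A, T_C the temporal
response functions (TRFs) for the acoustic background, speech clarity
and speech comprehension.  The model is fitted jointly over all eight
conditions by ridge regression on a lagged design spanning −500..700 ms,
with condition boundaries excluded from the design so that no row mixes
two recordings.  Null TRFs are obtained by shuffling which EEG recording
is paired with which condition's features; the pooled null coefficients
per (channel, feature) are summarised by a fitted Gaussian whose
two-tailed, Bonferroni-corrected p = 0.01 quantiles act as significance
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._ridge import DEFAULT_LAMBDA_GRID, ridge_solve
from .containers import EEGRecording
from .envelope import Envelope

FEATURES = ("background", "clarity", "comprehension")


@dataclass
class TRFSet:
    """TRFs per feature: channels × lags coefficient matrices."""

    trfs: dict[str, np.ndarray]
    lags_ms: np.ndarray
    band: str = ""

    def __post_init__(self) -> None:
        shapes = {f: np.asarray(t).shape for f, t in self.trfs.items()}
        if len({s for s in shapes.values()}) > 1:
            raise ValueError(f"inconsistent TRF shapes {shapes}")
        for f in self.trfs:
            self.trfs[f] = np.atleast_2d(np.asarray(self.trfs[f], float))

    @property
    def n_channels(self) -> int:
        return next(iter(self.trfs.values())).shape[0]

    def __getitem__(self, feature: str) -> np.ndarray:
        return self.trfs[feature]


@dataclass
class TRFNull:
    """Gaussian summary of shuffled-pairing null TRF coefficients."""

    mean: dict[str, np.ndarray]      # feature → (channels,)
    sd: dict[str, np.ndarray]
    threshold: dict[str, np.ndarray]  # half-width: |coef − mean| > threshold
    p: float
    n_comparisons: int
    n_shuffles: int
    seed: int


def build_features(y_t: Envelope | np.ndarray, y_b: Envelope | np.ndarray,
                   a: float, c: float) -> dict[str, np.ndarray]:
    """The three weighted envelope features of one condition.

    f_B = (1−a)·y_B, f_A = a·y_T, f_C = c·y_T.  In quiet (a=1) the
    background feature vanishes both through its weight and through the
    silent babble envelope.
    """
    yt = y_t.samples if isinstance(y_t, Envelope) else np.asarray(y_t, float)
    yb = y_b.samples if isinstance(y_b, Envelope) else np.asarray(y_b, float)
    if len(yt) != len(yb):
        raise ValueError("target and babble envelopes differ in length")
    if not (0 <= a <= 1 and 0 <= c <= 1):
        raise ValueError("clarity and comprehension must be in [0, 1]")
    return {"background": (1.0 - a) * yb, "clarity": a * yt,
            "comprehension": c * yt}


def lag_axis(lag_start_ms: float, lag_stop_ms: float, rate: float
             ) -> np.ndarray:
    """Sample lags (int) covering the requested window at ``rate``."""
    l0 = int(np.floor(lag_start_ms * rate / 1000.0))
    l1 = int(np.ceil(lag_stop_ms * rate / 1000.0))
    return np.arange(l0, l1 + 1)


def lagged_design(features: dict[str, np.ndarray] | list[np.ndarray],
                  lag_start_ms: float, lag_stop_ms: float, rate: float
                  ) -> tuple[np.ndarray, slice, np.ndarray]:
    """Time × (features · lags) convolutional design matrix.

    Column (f, τ) holds feature f delayed by τ samples; rows where any
    lag would fall outside the recording are trimmed, and the returned
    slice selects the EEG samples aligned with the remaining rows.
    """
    if isinstance(features, dict):
        feats = [np.asarray(features[f], float) for f in FEATURES
                 if f in features]
    else:
        feats = [np.asarray(f, float) for f in features]
    n = len(feats[0])
    if any(len(f) != n for f in feats):
        raise ValueError("features must be equal length")
    lags = lag_axis(lag_start_ms, lag_stop_ms, rate)
    lmin, lmax = int(lags.min()), int(lags.max())
    t0, t1 = max(0, lmax), n + min(0, lmin)
    if t1 <= t0:
        raise ValueError("recording shorter than the lag span")
    cols = []
    for f in feats:
        for lag in lags:
            cols.append(f[t0 - lag:t1 - lag])
    return np.column_stack(cols), slice(t0, t1), lags


def _pooled_blocks(conditions, lag_start_ms, lag_stop_ms, rate):
    """Per-condition lagged designs and aligned EEG blocks."""
    Xs, Ys = [], []
    lags = None
    for feats, eeg in conditions:
        data = eeg.data if isinstance(eeg, EEGRecording) else np.atleast_2d(eeg)
        X, sl, lags = lagged_design(feats, lag_start_ms, lag_stop_ms, rate)
        Xs.append(X)
        Ys.append(data[:, sl].T)
    return Xs, Ys, lags


class TRFEncoder(BaseEstimator):
    """sklearn-style ridge estimator of the three-feature TRF model.

    Parameters
    ----------
    lag_start_ms, lag_stop_ms : float
        TRF lag window (default −500..700 ms; positive lags are neural
        delays after the stimulus).
    rate : float
        Sampling rate of envelopes and EEG (Hz).
    lam : float or None
        Fixed ridge parameter; if None, selected from ``lambda_grid`` by
        leave-conditions-out CV on predicted-EEG correlation.
    lambda_grid : array-like
    n_folds : int
        Folds of the condition-level CV used for λ selection.

    Attributes after ``fit(conditions)`` where conditions is a list of
    (features dict, EEGRecording or channels × time array)
    ----------
    trf_ : TRFSet — fitted TRFs, channels × lags per feature
    lags_ms_ : ndarray
    lambda_ : float
    """

    def __init__(self, lag_start_ms: float = -500.0,
                 lag_stop_ms: float = 700.0, rate: float = 100.0,
                 lam: float | None = None,
                 lambda_grid=DEFAULT_LAMBDA_GRID, n_folds: int = 4,
                 band: str = ""):
        self.lag_start_ms = lag_start_ms
        self.lag_stop_ms = lag_stop_ms
        self.rate = rate
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.n_folds = n_folds
        self.band = band

    # -- internals -------------------------------------------------------

    def _gram_pieces(self, Xs, Ys):
        p = Xs[0].shape[1]
        nch = Ys[0].shape[1]
        G = np.zeros((p, p))
        B = np.zeros((p, nch))
        Gs, Bs = [], []
        for X, Y in zip(Xs, Ys):
            g = X.T @ X
            b = X.T @ Y
            Gs.append(g)
            Bs.append(b)
            G += g
            B += b
        return G, B, Gs, Bs

    def _select_lambda(self, Xs, Ys, Gs, Bs):
        lams = np.asarray(self.lambda_grid, float)
        n_cond = len(Xs)
        n_folds = min(self.n_folds, n_cond)
        edges = np.linspace(0, n_cond, n_folds + 1).astype(int)
        scores = np.zeros(len(lams))
        for f in range(n_folds):
            test = list(range(edges[f], edges[f + 1]))
            train = [i for i in range(n_cond) if i not in test]
            G = sum(Gs[i] for i in train)
            B = sum(Bs[i] for i in train)
            w, V = np.linalg.eigh(G)
            VtB = V.T @ B
            for li, lam in enumerate(lams):
                beta = V @ (VtB / (w + lam)[:, None])
                r_sum, r_n = 0.0, 0
                for i in test:
                    pred = Xs[i] @ beta
                    for ch in range(pred.shape[1]):
                        sy = Ys[i][:, ch].std()
                        sp = pred[:, ch].std()
                        if sy > 0 and sp > 0:
                            r_sum += float(np.corrcoef(
                                pred[:, ch], Ys[i][:, ch])[0, 1])
                            r_n += 1
                scores[li] += r_sum / max(r_n, 1)
        return float(lams[int(np.argmax(scores))])

    # -- public API ------------------------------------------------------

    def fit(self, conditions, y=None):
        if len(conditions) < 1:
            raise ValueError("at least one condition required")
        Xs, Ys, lags = _pooled_blocks(conditions, self.lag_start_ms,
                                      self.lag_stop_ms, self.rate)
        G, B, Gs, Bs = self._gram_pieces(Xs, Ys)
        self.lambda_ = (self._select_lambda(Xs, Ys, Gs, Bs)
                        if self.lam is None else float(self.lam))
        p = G.shape[0]
        beta = np.linalg.solve(G + self.lambda_ * np.eye(p), B)
        n_lags = len(lags)
        self.lags_ms_ = lags * 1000.0 / self.rate
        trfs = {}
        for fi, feat in enumerate(FEATURES):
            trfs[feat] = beta[fi * n_lags:(fi + 1) * n_lags].T  # ch × lags
        self.trf_ = TRFSet(trfs, self.lags_ms_, band=self.band)
        self._blocks = (Xs, Ys)
        return self

    def predict(self, conditions):
        """Predicted EEG (channels × time) per condition."""
        Xs, _, lags = _pooled_blocks(conditions, self.lag_start_ms,
                                     self.lag_stop_ms, self.rate)
        n_lags = len(lags)
        beta = np.concatenate([self.trf_[f].T for f in FEATURES], axis=0)
        return [(X @ beta).T for X in Xs]


def fit_trf(conditions, lag_start_ms: float = -500.0,
            lag_stop_ms: float = 700.0, rate: float = 100.0,
            lam: float | None = None, band: str = "") -> TRFSet:
    """Functional wrapper: pooled TRF fit over a list of conditions."""
    enc = TRFEncoder(lag_start_ms, lag_stop_ms, rate, lam=lam, band=band)
    return enc.fit(conditions).trf_


def average_trfs(trf_sets: list[TRFSet]) -> TRFSet:
    """Element-wise mean of TRF sets over subjects."""
    first = trf_sets[0]
    for t in trf_sets[1:]:
        if not np.array_equal(t.lags_ms, first.lags_ms) or \
                set(t.trfs) != set(first.trfs):
            raise ValueError("TRF sets have mismatched axes")
    out = {f: np.mean([t[f] for t in trf_sets], axis=0) for f in first.trfs}
    return TRFSet(out, first.lags_ms.copy(), band=first.band)


def _permutation_no_fixed_points(rng: np.random.Generator, n: int
                                 ) -> np.ndarray:
    """A random permutation avoiding fixed points when possible."""
    for _ in range(100):
        perm = rng.permutation(n)
        if n == 1 or not np.any(perm == np.arange(n)):
            return perm
    return perm


def shuffle_null_trf(conditions, n_shuffles: int = 500, seed: int = 0,
                     lag_start_ms: float = -500.0, lag_stop_ms: float = 700.0,
                     rate: float = 100.0, lam: float = 1.0, p: float = 0.01,
                     n_comparisons: int | None = None, band: str = ""
                     ) -> TRFNull:
    """Null TRF distribution by mismatching EEG and stimulus features.

    The pairing of EEG recordings to conditions is permuted (fixed points
    avoided where possible) and the pooled TRF model refit for every
    permutation; per (channel, feature) the null coefficients over the
    whole lag range are pooled, a Gaussian fitted, and a two-tailed
    threshold computed at ``p`` divided by ``n_comparisons`` (Bonferroni;
    defaults to channels × features × lags, the number of cells the
    mass-univariate test examines simultaneously).

    All conditions are truncated to the shortest recording so that the
    shuffled pairings stay length-consistent.
    """
    if n_shuffles < 100:
        raise ValueError("at least 100 shuffles required")
    n_min = min(
        (e.data.shape[1] if isinstance(e, EEGRecording)
         else np.atleast_2d(e).shape[1]) for _, e in conditions)
    trimmed = []
    for feats, eeg in conditions:
        data = eeg.data if isinstance(eeg, EEGRecording) else np.atleast_2d(eeg)
        trimmed.append(({f: v[:n_min] for f, v in feats.items()},
                        data[:, :n_min]))
    Xs, Ys, lags = _pooled_blocks(trimmed, lag_start_ms, lag_stop_ms, rate)
    n_cond = len(Xs)
    p_dim = Xs[0].shape[1]
    nch = Ys[0].shape[1]
    G = sum(X.T @ X for X in Xs)
    w, V = np.linalg.eigh(G)
    inv = 1.0 / (w + lam)
    # cross products X_c1ᵀ Y_c2 for every pairing, reused across shuffles
    Z = [[Xs[i].T @ Ys[j] for j in range(n_cond)] for i in range(n_cond)]
    n_lags = len(lags)
    rng = np.random.default_rng(seed)
    pooled = {f: [] for f in FEATURES}
    for _ in range(n_shuffles):
        perm = _permutation_no_fixed_points(rng, n_cond)
        B = sum(Z[i][perm[i]] for i in range(n_cond))
        beta = V @ (inv[:, None] * (V.T @ B))        # p × channels
        for fi, feat in enumerate(FEATURES):
            pooled[feat].append(beta[fi * n_lags:(fi + 1) * n_lags].T)
    m = (n_comparisons if n_comparisons is not None
         else nch * len(FEATURES) * n_lags)
    p_corr = p / m
    z = stats.norm.ppf(1 - p_corr / 2)
    mean, sd, thr = {}, {}, {}
    for feat in FEATURES:
        coefs = np.stack(pooled[feat])               # shuffles × ch × lags
        mean[feat] = coefs.mean(axis=(0, 2))
        sd[feat] = coefs.std(axis=(0, 2))
        thr[feat] = z * sd[feat]
    return TRFNull(mean, sd, thr, p, m, n_shuffles, seed)


def significant_lag_runs(mask: np.ndarray, min_run: int = 2) -> np.ndarray:
    """Keep only significant cells belonging to a contiguous lag run.

    Mass-univariate maps are read as regions: an isolated single-lag
    threshold crossing is discounted, and only runs of at least
    ``min_run`` consecutive significant lags within a channel survive.
    """
    mask = np.atleast_2d(np.asarray(mask, bool))
    out = np.zeros_like(mask)
    for ch in range(mask.shape[0]):
        run_start = None
        row = mask[ch]
        for i in range(len(row) + 1):
            on = i < len(row) and row[i]
            if on and run_start is None:
                run_start = i
            elif not on and run_start is not None:
                if i - run_start >= min_run:
                    out[ch, run_start:i] = True
                run_start = None
    return out


def significant_regions(trfs: TRFSet, null: TRFNull
                        ) -> dict[str, np.ndarray]:
    """Boolean channels × lags mask of TRF coefficients beyond the null.

    True where |coefficient − null mean| exceeds the Bonferroni-corrected
    two-tailed Gaussian threshold for that channel and feature.
    """
    masks = {}
    for feat, coef in trfs.trfs.items():
        if feat not in null.mean:
            raise ValueError(f"null distribution lacks feature {feat!r}")
        masks[feat] = (np.abs(coef - null.mean[feat][:, None])
                       > null.threshold[feat][:, None])
    return masks
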