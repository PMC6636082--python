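"""Single-lag backward (stimulus-reconstruction) models.

For each time lag τ, a linear model reconstructs the attended speech
envelope from all EEG channels shifted by that lag::

    ŷ(t) = Σ_j β_j x_j(t + τ)

Positive τ means the EEG lags the stimulus (a neural response delay).
The models are ridge regressions with fivefold cross-validation on
contiguous blocks; performance is the Pearson correlation between the
held-out reconstruction and the true envelope on consecutive 10-s
segments.  The lags × segments matrix of correlations is the
entrainment profile that the second-level property decoder consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._ridge import (DEFAULT_LAMBDA_GRID, FoldedRidge, contiguous_folds,
                     ridge_solve)
from .containers import EEGRecording

SEGMENT_SECONDS = 10.0


@dataclass(frozen=True)
class LagGrid:
    """Evenly spaced inclusive grid of lags in milliseconds."""

    start_ms: float
    stop_ms: float
    step_ms: float

    def __post_init__(self) -> None:
        if self.step_ms <= 0:
            raise ValueError("step must be positive")
        if self.stop_ms < self.start_ms:
            raise ValueError("stop must be >= start")
        span = self.stop_ms - self.start_ms
        n = span / self.step_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("lag span must be divisible by step")

    def lags_ms(self) -> np.ndarray:
        n = int(round((self.stop_ms - self.start_ms) / self.step_ms)) + 1
        return self.start_ms + self.step_ms * np.arange(n)

    def __len__(self) -> int:
        return len(self.lags_ms())

    def to_samples(self, rate: float) -> np.ndarray:
        """Lags as whole sample offsets at ``rate`` (nearest-sample)."""
        return np.round(self.lags_ms() * rate / 1000.0).astype(int)


def make_lag_grid(start_ms: float = -200.0, stop_ms: float = 400.0,
                  step_ms: float = 20.0) -> LagGrid:
    """The default −200..400 ms grid in 20 ms steps (31 lags)."""
    return LagGrid(start_ms, stop_ms, step_ms)


@dataclass
class LagCorrelationTensor:
    """Per-segment reconstruction correlations c_k^(l), lags × segments."""

    values: np.ndarray            # (n_lags, n_segments), NaN where undefined
    lags_ms: np.ndarray
    segment_s: float = SEGMENT_SECONDS
    band: str = ""
    condition: str = ""
    selected_lambdas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.lags_ms):
            raise ValueError("values first axis must match the lag grid")

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    def mean_profile(self) -> np.ndarray:
        """Mean correlation per lag, NaN segments excluded."""
        return np.nanmean(self.values, axis=1)

    def peak_latency_ms(self) -> float:
        return float(self.lags_ms[int(np.nanargmax(self.mean_profile()))])


def single_lag_design(eeg: EEGRecording | np.ndarray, lag_samples: int,
                      valid: tuple[int, int] | None = None) -> tuple[np.ndarray, slice]:
    """Time × channels design with every channel shifted by one lag.

    Row t holds x_j(t + lag) for all channels j.  Out-of-range rows are
    dropped symmetrically from design and target: the returned slice
    selects the envelope samples aligned with the design rows.  ``valid``
    optionally forces a common (start, stop) target range (used to keep
    the row count identical across the lags of a grid).
    """
    data = eeg.data if isinstance(eeg, EEGRecording) else np.atleast_2d(eeg)
    n = data.shape[1]
    if abs(lag_samples) >= n:
        raise ValueError("lag exceeds recording length")
    t0, t1 = (max(0, -lag_samples), n - max(0, lag_samples))
    if valid is not None:
        v0, v1 = valid
        if v0 < t0 or v1 > t1:
            raise ValueError("requested valid range not covered by this lag")
        t0, t1 = v0, v1
    X = data[:, t0 + lag_samples:t1 + lag_samples].T
    return X, slice(t0, t1)


def ridge_fit(design: np.ndarray, target: np.ndarray, lam: float) -> np.ndarray:
    """Ridge weights minimising ||y − Xβ||² + λ||β||² (λ=0 → OLS)."""
    return ridge_solve(design, target, lam)


def crossval_single_lag(eeg, envelope: np.ndarray, lag_samples: int,
                        lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                        n_folds: int = 5,
                        valid: tuple[int, int] | None = None
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Cross-validated reconstruction at one lag.

    Contiguous-block folds; λ selected by mean held-out correlation
    across folds.  Returns (ŷ over all held-out folds, aligned y,
    selected λ).  Every aligned sample is predicted exactly once.
    """
    X, sl = single_lag_design(eeg, lag_samples, valid=valid)
    y = np.asarray(envelope, dtype=float)[sl]
    if len(y) < n_folds:
        raise ValueError("insufficient data for the requested fold count")
    fr = FoldedRidge(X, contiguous_folds(len(y), n_folds), lambda_grid)
    lam, yhat, _ = fr.select(y, metric="corr")
    return yhat, y, lam


def segment_correlations(yhat: np.ndarray, y: np.ndarray, rate: float,
                         segment_s: float = SEGMENT_SECONDS) -> np.ndarray:
    """Pearson r on consecutive non-overlapping segments.

    The trailing partial segment is discarded.  Segments where either
    series is constant have undefined correlation and yield NaN.
    """
    yhat = np.asarray(yhat, float)
    y = np.asarray(y, float)
    if yhat.shape != y.shape:
        raise ValueError("prediction and target lengths differ")
    seg = int(round(segment_s * rate))
    n_seg = len(y) // seg
    out = np.full(n_seg, np.nan)
    for i in range(n_seg):
        a = yhat[i * seg:(i + 1) * seg]
        b = y[i * seg:(i + 1) * seg]
        if a.std() > 0 and b.std() > 0:
            out[i] = float(np.corrcoef(a, b)[0, 1])
    return out


class SingleLagDecoder(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper around one single-lag backward model.

    Parameters
    ----------
    lag_samples : int
        EEG shift in samples (positive = EEG later than stimulus).
    lambda_grid : array-like
        Ridge regularisation candidates, chosen by CV correlation.
    n_folds : int
        Contiguous-block cross-validation folds.

    Attributes (after ``fit(X, y)`` with X = time × channels EEG)
    ----------
    coef_ : ndarray — backward-model weights β_j at the selected λ
    intercept_ : float
    lambda_ : float — selected regularisation
    cv_predictions_ : ndarray — held-out reconstruction of the envelope
    """

    def __init__(self, lag_samples: int = 0,
                 lambda_grid=DEFAULT_LAMBDA_GRID, n_folds: int = 5):
        self.lag_samples = lag_samples
        self.lambda_grid = lambda_grid
        self.n_folds = n_folds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        eeg = EEGRecording(X.T, rate=1.0)
        Xd, sl = single_lag_design(eeg, self.lag_samples)
        ya = y[sl]
        fr = FoldedRidge(Xd, contiguous_folds(len(ya), self.n_folds),
                         np.asarray(self.lambda_grid, float))
        self.lambda_, self.cv_predictions_, self.cv_score_ = fr.select(
            ya, metric="corr")
        self.coef_, self.intercept_ = fr.refit(ya, self.lambda_)
        self.target_slice_ = sl
        return self

    def predict(self, X):
        Xd, _ = single_lag_design(EEGRecording(np.asarray(X, float).T, 1.0),
                                  self.lag_samples)
        return Xd @ self.coef_ + self.intercept_


def entrainment_profile(eeg: EEGRecording, envelope: np.ndarray,
                        lag_grid: LagGrid,
                        lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                        n_folds: int = 5,
                        segment_s: float = SEGMENT_SECONDS,
                        band: str = "", condition: str = ""
                        ) -> LagCorrelationTensor:
    """Lag-wise envelope-reconstruction accuracy for one recording.

    Runs the cross-validated single-lag decoder at every lag of the grid
    and scores 10-s segment correlations.  A common valid time range
    (trimmed by the extreme lags) keeps the segment count identical
    across lags.
    """
    envelope = np.asarray(envelope, dtype=float)
    if eeg.n_samples != len(envelope):
        raise ValueError("EEG and envelope must be band-matched and "
                         "equal-length")
    lags = lag_grid.to_samples(eeg.rate)
    n = eeg.n_samples
    valid = (max(0, -int(lags.min())), n - max(0, int(lags.max())))
    rows = []
    sel = []
    for lag in lags:
        yhat, y, lam = crossval_single_lag(
            eeg, envelope, int(lag), lambda_grid, n_folds, valid=valid)
        rows.append(segment_correlations(yhat, y, eeg.rate, segment_s))
        sel.append(lam)
    return LagCorrelationTensor(np.array(rows), lag_grid.lags_ms(),
                                segment_s=segment_s, band=band,
                                condition=condition,
                                selected_lambdas=np.array(sel))
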