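"""Second-level decoding of speech clarity and comprehension.

The entrainment profiles — per-segment envelope-reconstruction
correlations c_k^(l) at each of the M lags — become features of a linear
model predicting a stimulus property z (clarity or comprehension, on the
0–100% scale) for every 10-s segment::

    ẑ(s_l) = Σ_k ρ_k c_k^(l)

One single ridge model spans all eight conditions, so acoustic cues
cannot stand in for comprehension nor comprehension differences for
clarity.  Statistical significance comes from a permutation null: the
eight condition property values are shuffled between conditions (same
multiset of values, random assignment), the decoder is refit, and the
observed held-out RMSE is compared with the null RMSE distribution.
The decoder's temporal structure is interpreted through its forward
(activation-pattern) version, with per-lag significance bounds corrected
by Benjamini–Hochberg FDR over lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from ._ridge import (DEFAULT_LAMBDA_GRID, FoldedRidge,
                     stratified_contiguous_folds)
from .backward import LagCorrelationTensor
from .conditions import ConditionGrid


@dataclass
class NullDistribution:
    """Samples of a statistic under condition-label shuffling."""

    statistic: str
    samples: np.ndarray
    n_shuffles: int
    seed: int
    observed: float = np.nan
    p_value: float = np.nan


def rmse(pred: np.ndarray, target: np.ndarray) -> float:
    """Root-mean-square error."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != target.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def assemble_training_table(tensors: dict[str, LagCorrelationTensor],
                            grid: ConditionGrid, prop: str
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool segments of all eight conditions into one training table.

    Returns (features, targets, condition_index): one row per 10-s
    segment, feature k the reconstruction correlation at lag k, target
    the condition's clarity or comprehension in percent.  Segments with
    undefined correlations at any lag are dropped.
    """
    labels = grid.labels
    missing = [la for la in labels if la not in tensors]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    values = grid.property_values(prop, percent=True)
    feats, targs, conds = [], [], []
    for ci, label in enumerate(labels):
        block = tensors[label].values.T          # segments × lags
        keep = ~np.isnan(block).any(axis=1)
        feats.append(block[keep])
        targs.append(np.full(keep.sum(), values[ci]))
        conds.append(np.full(keep.sum(), ci))
    return (np.concatenate(feats), np.concatenate(targs),
            np.concatenate(conds))


class PropertyDecoder(BaseEstimator, RegressorMixin):
    """Ridge decoder of a stimulus property from entrainment profiles.

    Parameters
    ----------
    lambda_grid : array-like
        Regularisation candidates; the λ with the lowest held-out RMSE
        is selected.
    n_folds : int
        Cross-validation folds; stratified so every fold holds segments
        of every condition, contiguous within a condition.

    Attributes after ``fit(X, y, condition_index=...)``
    ----------
    coef_ : ndarray, shape (M,) — decoder coefficients ρ_k
    intercept_ : float
    lambda_ : float
    cv_predictions_ : held-out predictions ẑ(s_l)
    cv_rmse_ : float — held-out RMSE at the selected λ
    """

    def __init__(self, lambda_grid=DEFAULT_LAMBDA_GRID, n_folds: int = 5):
        self.lambda_grid = lambda_grid
        self.n_folds = n_folds

    def _folds(self, n: int, condition_index):
        if condition_index is None:
            from ._ridge import contiguous_folds
            return contiguous_folds(n, self.n_folds)
        return stratified_contiguous_folds(condition_index, self.n_folds)

    def fit(self, X, y, condition_index: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ValueError("targets are constant; nothing to decode")
        folded = FoldedRidge(X, self._folds(len(y), condition_index),
                             np.asarray(self.lambda_grid, float))
        self.lambda_, self.cv_predictions_, self.cv_rmse_ = folded.select(
            y, metric="rmse")
        self.coef_, self.intercept_ = folded.refit(y, self.lambda_)
        self._folded = folded
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_ + self.intercept_


def fit_property_decoder(features: np.ndarray, targets: np.ndarray,
                         lambda_grid=DEFAULT_LAMBDA_GRID, n_folds: int = 5,
                         condition_index: np.ndarray | None = None
                         ) -> tuple[PropertyDecoder, np.ndarray]:
    """Fit a :class:`PropertyDecoder`; returns it plus held-out ẑ."""
    dec = PropertyDecoder(lambda_grid, n_folds).fit(
        features, targets, condition_index=condition_index)
    return dec, dec.cv_predictions_


def forward_transform(coef: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Activation-pattern (forward) version of a backward decoder.

    pattern = Cov(features) · ρ / Var(ẑ), the standard transformation of
    decoder weights into interpretable encoding patterns.
    """
    X = np.asarray(features, float)
    rho = np.asarray(coef, float)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (len(X) - 1)
    zhat = Xc @ rho
    var = float(zhat.var(ddof=1))
    if var <= 0:
        raise ValueError("prediction variance is zero; pattern undefined")
    return cov @ rho / var


def shuffle_null_rmse(tensors: dict[str, LagCorrelationTensor] | None,
                      grid: ConditionGrid, prop: str,
                      n_shuffles: int = 1000, seed: int = 0,
                      lambda_grid=DEFAULT_LAMBDA_GRID, n_folds: int = 5,
                      table: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                      return_patterns: bool = False):
    """Permutation test of property decodability.

    The property values of the eight conditions are permuted between
    conditions; the full cross-validated decoder (including λ selection)
    is refit for every permutation on the same fold partition.  p is the
    add-one estimator (1 + #{null RMSE ≤ observed}) / (1 + n_shuffles).

    Returns (NullDistribution, observed decoder); with
    ``return_patterns=True`` additionally the observed forward pattern
    and the n_shuffles × M null forward patterns.
    """
    if n_shuffles < 100:
        raise ValueError("at least 100 shuffles required for a "
                         "significance call")
    if table is None:
        table = assemble_training_table(tensors, grid, prop)
    X, y, cond = table
    values = grid.property_values(prop, percent=True)
    rng = np.random.default_rng(seed)

    folded = FoldedRidge(X, stratified_contiguous_folds(cond, n_folds),
                         np.asarray(lambda_grid, float))
    lam, cv_pred, observed = folded.select(y, metric="rmse")
    coef, intercept = folded.refit(y, lam)
    dec = PropertyDecoder(lambda_grid, n_folds)
    dec.coef_, dec.intercept_, dec.lambda_ = coef, intercept, lam
    dec.cv_predictions_, dec.cv_rmse_ = cv_pred, observed
    dec.n_features_in_ = X.shape[1]

    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (len(X) - 1)

    def pattern_of(rho):
        var = float((Xc @ rho).var(ddof=1))
        return cov @ rho / var if var > 0 else np.zeros_like(rho)

    null = np.empty(n_shuffles)
    patterns = np.empty((n_shuffles, X.shape[1])) if return_patterns else None
    for i in range(n_shuffles):
        perm_values = values[rng.permutation(len(values))]
        y_perm = perm_values[cond]
        if np.unique(y_perm).size < 2:      # degenerate draw; rare
            null[i] = np.inf
            if return_patterns:
                patterns[i] = 0.0
            continue
        lam_i, _, null[i] = folded.select(y_perm, metric="rmse")
        if return_patterns:
            patterns[i] = pattern_of(folded.refit(y_perm, lam_i)[0])

    p = (1 + int(np.sum(null <= observed))) / (1 + n_shuffles)
    dist = NullDistribution("rmse", null, n_shuffles, seed,
                            observed=observed, p_value=p)
    if return_patterns:
        return dist, dec, pattern_of(coef), patterns
    return dist, dec


def coefficient_null_band(observed_pattern: np.ndarray,
                          null_patterns: np.ndarray, q: float = 0.05
                          ) -> dict:
    """Per-lag significance of forward-pattern coefficients, FDR over lags.

    Two-sided add-one permutation p per lag from the null patterns,
    Benjamini–Hochberg correction across the M lags, plus the null
    quantile band at the uncorrected level for display.
    """
    obs = np.asarray(observed_pattern, float)
    nulls = np.asarray(null_patterns, float)
    n = nulls.shape[0]
    if n < 100:
        raise ValueError("at least 100 null patterns required")
    p_hi = (1 + np.sum(nulls >= obs[None, :], axis=0)) / (1 + n)
    p_lo = (1 + np.sum(nulls <= obs[None, :], axis=0)) / (1 + n)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    lo = np.quantile(nulls, q / 2, axis=0)
    hi = np.quantile(nulls, 1 - q / 2, axis=0)
    return dict(p_values=p, p_adjusted=p_adj, significant=reject,
                band_lo=lo, band_hi=hi)


def benjamini_hochberg(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """BH rejection mask (wrapper over statsmodels' implementation)."""
    return multipletests(np.asarray(p_values, float), alpha=q,
                         method="fdr_bh")[0]


def decode_report_row(band: str, prop: str, dist: NullDistribution) -> dict:
    """One row of the decoding results table."""
    return dict(band=band, property=prop, observed_rmse=dist.observed,
                null_mean=float(np.mean(dist.samples[np.isfinite(dist.samples)])),
                null_sd=float(np.std(dist.samples[np.isfinite(dist.samples)])),
                p_value=dist.p_value)
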