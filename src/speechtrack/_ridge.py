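"""Ridge regression cores shared by the backward, property and TRF models.

All models in the pipeline are ridge regressions, β = (XᵀX + λI)⁻¹Xᵀy,
with λ chosen by cross-validation on contiguous folds.  The permutation
nulls refit the same model thousands of times with only the target
changing, so the cross-validated path caches a thin SVD of each training
fold once and re-solves for new targets in O(np) instead of O(np²).
"""

from __future__ import annotations

import numpy as np

#: Default logarithmic regularisation grid, 10^-6 .. 10^6.
DEFAULT_LAMBDA_GRID = np.logspace(-6, 6, 13)


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Exact minimiser of ||y − Xβ||² + λ||β||² (no intercept).

    λ=0 reduces to ordinary least squares (via lstsq for rank safety).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)


def ridge_path_svd(U: np.ndarray, s: np.ndarray, Vt: np.ndarray,
                   y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """β(λ) for every λ from a precomputed thin SVD X = U s Vt.

    Returns an array of shape (len(lams), p) for 1-D y, or
    (len(lams), p, m) for 2-D y.
    """
    uty = U.T @ y                                   # (r,) or (r, m)
    shrink = s[None, :] / (s[None, :] ** 2 + np.asarray(lams)[:, None])
    if y.ndim == 1:
        return np.einsum("lr,r,rp->lp", shrink, uty, Vt)
    return np.einsum("lr,rm,rp->lpm", shrink, uty, Vt).transpose(0, 2, 1)


def contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Split range(n) into n_folds contiguous index blocks."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]


def stratified_contiguous_folds(groups: np.ndarray, n_folds: int
                                ) -> list[np.ndarray]:
    """Contiguous folds within each group, merged across groups.

    Every fold contains samples from every group; within a group the
    samples assigned to one fold form a contiguous block (respecting
    temporal autocorrelation of consecutive segments).
    """
    groups = np.asarray(groups)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        for i, block in enumerate(contiguous_folds(len(idx), n_folds)):
            folds[i].extend(idx[block])
    return [np.array(sorted(f)) for f in folds]


class FoldedRidge:
    """Cross-validated ridge with per-fold SVD caching.

    Designed for permutation testing: the design matrix and fold partition
    are fixed, while ``cv_predict`` / ``select`` are called once per
    shuffled target.  Training data are centred per fold; the intercept is
    the (unpenalised) training mean.
    """

    def __init__(self, X: np.ndarray, folds: list[np.ndarray],
                 lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID):
        self.X = np.asarray(X, dtype=float)
        self.folds = folds
        self.lams = np.asarray(lambda_grid, dtype=float)
        n = self.X.shape[0]
        all_idx = np.arange(n)
        self._cache = []
        for test in folds:
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            Xtr = self.X[train]
            mu = Xtr.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xtr - mu, full_matrices=False)
            self._cache.append(
                dict(train=train, test=test, mu=mu, U=U, s=s, Vt=Vt,
                     Xte=self.X[test] - mu))

    def cv_predict(self, y: np.ndarray) -> np.ndarray:
        """Held-out predictions for every λ; shape (n, len(lams))."""
        y = np.asarray(y, dtype=float)
        out = np.empty((len(y), len(self.lams)))
        for c in self._cache:
            ytr = y[c["train"]]
            ym = ytr.mean()
            betas = ridge_path_svd(c["U"], c["s"], c["Vt"], ytr - ym, self.lams)
            out[c["test"]] = c["Xte"] @ betas.T + ym
        return out

    def select(self, y: np.ndarray, metric: str = "rmse"
               ) -> tuple[float, np.ndarray, float]:
        """Pick λ by held-out RMSE (or mean per-fold correlation).

        Returns (lambda, cv_predictions at that lambda, score).
        """
        preds = self.cv_predict(y)
        if metric == "rmse":
            scores = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
            best = int(np.argmin(scores))
        elif metric == "corr":
            scores = np.zeros(len(self.lams))
            for c in self._cache:
                yt = y[c["test"]]
                pt = preds[c["test"]]
                if yt.std() > 0:
                    denom = pt.std(axis=0) * yt.std()
                    cov = ((pt - pt.mean(axis=0))
                           * (yt - yt.mean())[:, None]).mean(axis=0)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        scores += np.where(denom > 0, cov / denom, 0.0)
            scores /= len(self.folds)
            best = int(np.argmax(scores))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        return float(self.lams[best]), preds[:, best], float(scores[best])

    def refit(self, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
        """Coefficients and intercept on the full data at a fixed λ."""
        mu = self.X.mean(axis=0)
        ym = float(np.mean(y))
        beta = ridge_solve(self.X - mu, np.asarray(y, float) - ym, lam)
        return beta, ym - float(mu @ beta)
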