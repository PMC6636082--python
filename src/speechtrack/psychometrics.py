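"""Speech-in-noise psychometrics.

Comprehension of speech in babble noise follows a two-parameter logistic
psychometric function of the SNR ``x`` (dB)::

    c(x) = 1 / (1 + exp(-beta * (x - alpha)))

with midpoint ``alpha`` (the SNR giving 50% comprehension, in dB) and
steepness ``beta`` (1/dB); the slope of the curve at its midpoint is
``beta / 4``.  The curve is estimated from a speech-in-noise session in
which each sentence is scored by the number of five keywords repeated
correctly, using a grid-based adaptive Bayesian procedure in the
Kontsevich–Tyler family: after each trial the posterior over (alpha, beta)
is updated and the next SNR is placed to minimise the expected posterior
entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import (BACKGROUNDS, ConditionGrid, LANGUAGES, NOISE_SNRS_DB)

N_KEYWORDS = 5


@dataclass(frozen=True)
class PsychometricCurve:
    """Sigmoidal SNR → comprehension curve."""

    alpha: float  # midpoint SNR, dB
    beta: float   # steepness, 1/dB

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def __call__(self, snr_db) -> np.ndarray | float:
        return comprehension_at(self, snr_db)


@dataclass(frozen=True)
class SinTrial:
    """One speech-in-noise sentence: presented SNR and keywords repeated."""

    snr: float
    keywords_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.keywords_correct <= N_KEYWORDS:
            raise ValueError("keywords_correct must be in 0..5")


def comprehension_at(curve: PsychometricCurve, snr_db) -> np.ndarray | float:
    """Evaluate c(x) = [1 + exp(−β(x−α))]⁻¹ at the given SNR(s)."""
    x = np.asarray(snr_db, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-curve.beta * (x - curve.alpha)))
    return float(out) if np.isscalar(snr_db) else out


def midpoint_slope(curve: PsychometricCurve) -> float:
    """Derivative of the sigmoid at its midpoint: β/4, in 1/dB."""
    return curve.beta / 4.0


class AdaptivePsychometricEstimator:
    """Grid-based Bayesian estimation of (alpha, beta) with adaptive SNRs.

    Maintains a discrete posterior over a grid of (alpha, beta) pairs under
    a binomial keyword-scoring likelihood (five keywords per sentence,
    treated as independent Bernoulli(c(snr)) draws).  ``next_snr`` proposes
    the candidate SNR minimising the expected posterior entropy.
    """

    def __init__(self,
                 alpha_grid: np.ndarray | None = None,
                 beta_grid: np.ndarray | None = None,
                 snr_candidates: np.ndarray | None = None):
        self.alpha_grid = (np.linspace(-15.0, 10.0, 51)
                           if alpha_grid is None else np.asarray(alpha_grid))
        self.beta_grid = (np.geomspace(0.05, 3.0, 31)
                          if beta_grid is None else np.asarray(beta_grid))
        self.snr_candidates = (np.linspace(-15.0, 10.0, 26)
                               if snr_candidates is None
                               else np.asarray(snr_candidates))
        A, B = np.meshgrid(self.alpha_grid, self.beta_grid, indexing="ij")
        self._alpha = A.ravel()
        self._beta = B.ravel()
        # c(x) for every hypothesis at every candidate SNR, precomputed.
        self._pc = 1.0 / (1.0 + np.exp(
            -self._beta[:, None]
            * (self.snr_candidates[None, :] - self._alpha[:, None])))
        # binomial outcome pmf table (k, hypothesis, candidate), fixed
        k = np.arange(N_KEYWORDS + 1)
        from scipy.special import comb
        pc = np.clip(self._pc, 1e-12, 1 - 1e-12)[None]
        self._pmf = (comb(N_KEYWORDS, k)[:, None, None]
                     * pc ** k[:, None, None]
                     * (1 - pc) ** (N_KEYWORDS - k)[:, None, None])
        self.log_posterior = np.zeros(self._alpha.size)
        self.trials: list[SinTrial] = []

    # -- posterior bookkeeping ------------------------------------------

    @property
    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()

    def _binom_loglik(self, pc: np.ndarray, k: int) -> np.ndarray:
        pc = np.clip(pc, 1e-12, 1 - 1e-12)
        return k * np.log(pc) + (N_KEYWORDS - k) * np.log1p(-pc)

    def update(self, snr: float, keywords_correct: int) -> None:
        pc = 1.0 / (1.0 + np.exp(-self._beta * (snr - self._alpha)))
        self.log_posterior += self._binom_loglik(pc, keywords_correct)
        self.trials.append(SinTrial(snr, keywords_correct))

    # -- adaptive placement ---------------------------------------------

    def next_snr(self) -> float:
        """Candidate SNR minimising expected posterior entropy."""
        post = self.posterior
        pmf = self._pmf
        p_k = np.einsum("h,khc->kc", post, pmf)          # outcome predictive
        with np.errstate(divide="ignore", invalid="ignore"):
            post_k = post[None, :, None] * pmf           # unnormalised
            z = post_k.sum(axis=1, keepdims=True)
            post_k = np.where(z > 0, post_k / z, 0.0)
            ent = -np.nansum(np.where(post_k > 0,
                                      post_k * np.log(post_k), 0.0), axis=1)
        expected_entropy = np.einsum("kc,kc->c", p_k, ent)
        return float(self.snr_candidates[np.argmin(expected_entropy)])

    def entropy(self) -> float:
        p = self.posterior
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    def estimate(self) -> PsychometricCurve:
        """Posterior-mean point estimate."""
        post = self.posterior
        ks = [t.keywords_correct for t in self.trials]
        if self.trials and (all(k == 0 for k in ks)
                            or all(k == N_KEYWORDS for k in ks)):
            warnings.warn("all-floor or all-ceiling data: estimate shrinks "
                          "to the grid boundary", stacklevel=2)
        return PsychometricCurve(float(post @ self._alpha),
                                 float(post @ self._beta))


def simulate_sin_session(true_curve: PsychometricCurve, n_sentences: int,
                         seed: int,
                         estimator: AdaptivePsychometricEstimator | None = None,
                         ) -> tuple[list[SinTrial], AdaptivePsychometricEstimator]:
    """Simulate an adaptive speech-in-noise session.

    A binomial observer draws keywords_correct ~ Binomial(5, c(snr)) from
    ``true_curve``; SNRs follow the estimator's entropy-minimising policy.
    Returns the trials and the updated estimator.
    """
    if n_sentences < 1:
        raise ValueError("need at least one sentence")
    rng = np.random.default_rng(seed)
    est = estimator if estimator is not None else AdaptivePsychometricEstimator()
    for _ in range(n_sentences):
        snr = est.next_snr()
        pc = comprehension_at(true_curve, snr)
        k = int(rng.binomial(N_KEYWORDS, pc))
        est.update(snr, k)
    return est.trials[-n_sentences:], est


def bayesian_adaptive_fit(trials: list[SinTrial],
                          estimator: AdaptivePsychometricEstimator | None = None,
                          ) -> tuple[AdaptivePsychometricEstimator,
                                     PsychometricCurve]:
    """Posterior and point estimate from an already-recorded trial list."""
    est = estimator if estimator is not None else AdaptivePsychometricEstimator()
    for t in trials:
        est.update(t.snr, t.keywords_correct)
    return est, est.estimate()


def build_condition_grid(curve: PsychometricCurve) -> ConditionGrid:
    """Condition grid derived from a psychometric curve.

    Clarity at each noise level is the curve's comprehension at that SNR,
    rounded to integer percent (quiet → 100); comprehension equals clarity
    for English and 0 for Dutch.
    """
    rows = []
    for lang in LANGUAGES:
        for bg in BACKGROUNDS:
            snr = NOISE_SNRS_DB[bg]
            clarity = 100 if snr is None else int(
                round(100 * comprehension_at(curve, snr)))
            rows.append({
                "language": lang,
                "background": bg,
                "snr_db": np.nan if snr is None else snr,
                "clarity_pct": clarity,
                "comprehension_pct": clarity if lang == "english" else 0,
            })
    return ConditionGrid(pd.DataFrame(rows))
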