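"""FIR filtering primitives shared by every stage of the pipeline.

Two filter families are used throughout:

* **linear-phase** (noncausal) FIR filters applied one-pass forward and
  compensated for their group delay, so that filtered signals stay aligned
  with the stimulus.  These are the default for all band filtering.
* **minimum-phase** (causal) FIR filters whose output depends only on past
  and present input, used as a control to rule out negative-lag artifacts
  that delay compensation can introduce.

Cutoff frequencies follow the −6 dB (half-amplitude) convention, which is
what a windowed-sinc design centred on the cutoff produces naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np
from scipy import signal

#: Canonical EEG analysis bands (Hz): low edge, high edge.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
}

# Hamming-window transition width: Δf ≈ 3.3 / N · fs, so N ≈ 3.3 fs / Δf.
_HAMMING_TBW = 3.3


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one FIR filter.

    Parameters
    ----------
    kind : {"lowpass", "highpass", "bandpass"}
    cutoff_lo, cutoff_hi : float or None
        −6 dB cutoff(s) in Hz.  Lowpass uses ``cutoff_hi``, highpass uses
        ``cutoff_lo``, bandpass uses both.
    transition_bw : float
        Transition bandwidth in Hz; sets the order when ``order`` is None.
    order : int or None
        Number of taps minus one.  If None, derived from ``transition_bw``
        for a Hamming window and rounded to the nearest even integer.
    phase : {"linear", "minimum"}
    """

    kind: str
    cutoff_lo: float | None = None
    cutoff_hi: float | None = None
    transition_bw: float = 1.0
    order: int | None = None
    phase: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.phase not in ("linear", "minimum"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.kind in ("lowpass", "bandpass") and not self.cutoff_hi:
            raise ValueError(f"{self.kind} requires cutoff_hi")
        if self.kind in ("highpass", "bandpass") and not self.cutoff_lo:
            raise ValueError(f"{self.kind} requires cutoff_lo")
        if self.transition_bw <= 0:
            raise ValueError("transition_bw must be positive")
        if self.order is not None and self.order <= 0:
            raise ValueError("order must be positive")

    def resolve_order(self, rate: float) -> int:
        """Taps−1 at the given sampling rate (even, so taps is odd/type I)."""
        if self.order is not None:
            n = self.order
        else:
            n = int(round(_HAMMING_TBW * rate / self.transition_bw))
        return n + (n % 2)

    def cutoffs(self) -> list[float]:
        if self.kind == "lowpass":
            return [float(self.cutoff_hi)]
        if self.kind == "highpass":
            return [float(self.cutoff_lo)]
        return [float(self.cutoff_lo), float(self.cutoff_hi)]

    def to_dict(self) -> dict:
        """Plain-dict form for YAML/JSON run configs."""
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(**d)


def band_spec(band: str, order: int | None = None) -> FilterSpec:
    """Bandpass :class:`FilterSpec` for a named EEG band (delta/theta/alpha)."""
    lo, hi = BANDS[band]
    # The top band edge sits at 12.5 Hz −6 dB so that 12 Hz content passes.
    if band == "alpha":
        hi = 12.5
    if band == "delta":
        lo = 0.5
    return FilterSpec("bandpass", cutoff_lo=lo, cutoff_hi=hi,
                      transition_bw=1.0, order=order)


def design_fir(spec: FilterSpec, rate: float) -> np.ndarray:
    """Design the impulse response of ``spec`` at sampling rate ``rate``.

    Linear-phase kernels are symmetric windowed-sinc (Hamming) designs with
    their −6 dB point at the spec cutoff.  Minimum-phase kernels are obtained
    from the linear-phase prototype by the homomorphic (cepstral) method and
    are causal: strictly zero support at negative time.
    """
    nyq = rate / 2.0
    cut = spec.cutoffs()
    if any(c <= 0 or c >= nyq for c in cut):
        raise ValueError(f"cutoffs {cut} outside (0, {nyq}) at rate {rate}")
    ntaps = spec.resolve_order(rate) + 1
    pass_zero = {"lowpass": True, "highpass": False, "bandpass": False}[spec.kind]
    kernel = signal.firwin(ntaps, cut, pass_zero=pass_zero, fs=rate,
                           window="hamming")
    if spec.phase == "minimum":
        kernel = signal.minimum_phase(kernel, method="homomorphic")
    return kernel


def group_delay_samples(kernel: np.ndarray) -> int:
    """Group delay of a symmetric linear-phase kernel, in samples."""
    return (len(kernel) - 1) // 2


def apply_filter(x: np.ndarray, kernel: np.ndarray,
                 direction: str = "forward-compensated") -> np.ndarray:
    """Filter ``x`` along its last axis.

    direction:
        * ``"forward-compensated"`` — one-pass forward convolution, output
          advanced by the kernel's linear-phase group delay (zero net delay
          in the passband).  Edges are reflect-padded by one kernel length.
        * ``"causal"`` — plain causal convolution; y[t] depends on x[<=t].
        * ``"anticausal"`` — the signal is flipped in time, filtered by the
          causal filter, and flipped back.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= len(kernel):
        raise ValueError("signal must be longer than the filter kernel")
    if direction == "causal":
        # direct (time-domain) convolution: exact zeros before an impulse,
        # which the causality control asserts exactly
        if x.ndim == 1:
            return np.convolve(x, kernel)[:n]
        return np.stack([np.convolve(row, kernel)[:n] for row in x])
    if direction == "anticausal":
        return apply_filter(x[..., ::-1], kernel, "causal")[..., ::-1]
    if direction != "forward-compensated":
        raise ValueError(f"unknown direction {direction!r}")
    pad = len(kernel)
    xp = np.concatenate(
        [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]], axis=-1)
    k = kernel[np.newaxis] if x.ndim == 2 else kernel
    full = signal.fftconvolve(xp, k, axes=-1, mode="full")
    delay = group_delay_samples(kernel)
    start = pad + delay
    return full[..., start:start + n]


def filter_band(x: np.ndarray, rate: float, band: str,
                order: int | None = None) -> np.ndarray:
    """Delay-compensated bandpass of ``x`` into a named EEG band."""
    kernel = design_fir(band_spec(band, order=order), rate)
    return apply_filter(x, kernel, "forward-compensated")


def polynomial_detrend(x: np.ndarray, degree: int = 1) -> np.ndarray:
    """Fit and subtract a low-order polynomial (slow-drift removal).

    The residual is orthogonal to the polynomial basis up to ``degree``.
    Works on 1-D signals or (channels, time) arrays, per channel.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if n <= degree + 1:
        raise ValueError("signal too short for requested degree")
    t = np.linspace(-1.0, 1.0, n)
    # Vandermonde in a Chebyshev-ish scaled variable keeps the fit stable.
    basis = np.polynomial.polynomial.polyvander(t, degree)
    coef, *_ = np.linalg.lstsq(basis, x.reshape(-1, n).T, rcond=None)
    trend = (basis @ coef).T.reshape(x.shape)
    return x - trend


def resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase resampling with anti-alias filtering (last axis).

    Duration is preserved to within one output sample.
    """
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("rates must be positive")
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=float),
                                frac.numerator, frac.denominator, axis=-1)


def kernel_to_text(kernel: np.ndarray) -> str:
    """Plain-text export of a kernel (one coefficient per line)."""
    return "\n".join(f"{c:.18e}" for c in np.asarray(kernel)) + "\n"
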