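"""Speech-envelope computation.

The amplitude envelope is the slow modulation of the speech waveform that
low-frequency cortical activity tracks.  The pipeline is: a gentle lowpass
imitating the presentation earphones' frequency response (−6 dB at 3500 Hz,
1000 Hz transition), resampling to 8 kHz, full-wave rectification, and a
power-law compression with exponent 0.6 mimicking the compressive
nonlinearity of the auditory periphery.  Band-limited variants at the
decoder (50 Hz) and encoder (100 Hz) rates are derived from the compressed
envelope; a causal (time-flipped minimum-phase) variant of the encoder
lowpass exists for the causality control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile

from .filters import FilterSpec, apply_filter, design_fir, filter_band, resample

#: Default power-law compression exponent.
COMPRESSION_EXPONENT = 0.6

# Intermediate rate at which band/low-pass envelope filters are designed.
_FILTER_RATE = 1000.0


@dataclass
class Envelope:
    """A nonnegative 1-D amplitude-envelope signal.

    Attributes
    ----------
    samples : np.ndarray
    rate : float
        Sampling rate in Hz.
    band : str
        "broadband", "delta", "theta" or "alpha".  Band-filtered envelopes
        are zero-mean and may go negative.
    causal : bool
        Whether causal (minimum-phase) filtering was used downstream.
    """

    samples: np.ndarray
    rate: float
    band: str = "broadband"
    causal: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("envelope must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file as float samples in [-1, 1] plus its rate."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim != 1:
        raise ValueError("multichannel audio: downmix explicitly before use")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def raw_envelope(audio: np.ndarray, rate: float) -> Envelope:
    """Rectified broadband envelope at 8 kHz.

    Earphone-response lowpass (−6 dB 3500 Hz, transition 1000 Hz, linear
    phase, delay-compensated) → resample to 8000 Hz → absolute value.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("multichannel audio: downmix explicitly before use")
    if rate < 8000:
        raise ValueError("audio rate must be at least 8000 Hz")
    if rate > 8000:
        lpf = design_fir(
            FilterSpec("lowpass", cutoff_hi=3500.0, transition_bw=1000.0), rate)
        audio = apply_filter(audio, lpf, "forward-compensated")
        audio = resample(audio, rate, 8000.0)
    return Envelope(np.abs(audio), 8000.0)


def compress(env: Envelope, exponent: float = COMPRESSION_EXPONENT) -> Envelope:
    """Power-law amplitude compression, samples ↦ samples**exponent."""
    if not 0 < exponent <= 1:
        raise ValueError("exponent must be in (0, 1]")
    if np.any(env.samples < 0):
        raise ValueError("compression requires a nonnegative envelope")
    return replace(env, samples=env.samples ** exponent)


def band_envelope(env: Envelope, band: str, target_rate: float = 50.0,
                  causal: bool = False) -> Envelope:
    """Band-limited envelope for decoding (50 Hz) or encoding (100 Hz).

    ``band`` in {"delta","theta","alpha"} selects the decoder path: the
    compressed envelope is bandpass filtered with the same filters used on
    the EEG and resampled (default 50 Hz).  ``band="broadband"`` selects the
    encoder path: a gentle 31 Hz lowpass (order 86, transition 38 Hz), then
    resampling (default 100 Hz); with ``causal=True`` the lowpass is the
    anticausal variant — the envelope is flipped in time, filtered by the
    causal minimum-phase filter, and flipped back — so that no information
    from past samples leaks forward once the EEG side uses causal filters.
    """
    x = env.samples
    rate = env.rate
    if rate > _FILTER_RATE:
        x = resample(x, rate, _FILTER_RATE)
        rate = _FILTER_RATE
    if band == "broadband":
        spec = FilterSpec("lowpass", cutoff_hi=31.0, transition_bw=38.0,
                          order=86, phase="minimum" if causal else "linear")
        kernel = design_fir(spec, rate)
        direction = "anticausal" if causal else "forward-compensated"
        x = apply_filter(x, kernel, direction)
    elif band in ("delta", "theta", "alpha"):
        if causal:
            raise ValueError("causal path is defined for the broadband "
                             "(encoder) envelope only")
        x = filter_band(x, rate, band)
    else:
        raise ValueError(f"unknown band {band!r}")
    x = resample(x, rate, target_rate)
    return Envelope(x, target_rate, band=band, causal=causal)


def speech_envelope(audio: np.ndarray, rate: float, band: str,
                    target_rate: float | None = None,
                    causal: bool = False) -> Envelope:
    """Full audio→envelope pipeline for one band.

    Convenience wrapper: raw envelope, power-law compression, band filtering
    and resampling to the conventional rate (50 Hz for the delta/theta/alpha
    decoder envelopes, 100 Hz for the broadband encoder envelope).
    """
    if target_rate is None:
        target_rate = 100.0 if band == "broadband" else 50.0
    env = compress(raw_envelope(audio, rate))
    return band_envelope(env, band, target_rate, causal=causal)
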