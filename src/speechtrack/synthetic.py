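"""Synthetic stimuli, ground-truth TRFs and EEG with known answers.

Real audiobook narrations and EEG recordings are not redistributable, so
every downstream stage is validated on synthetic data built from the same
generative assumptions the analysis makes:

* speech-like audio: a noise carrier amplitude-modulated by a positive,
  low-frequency (1–12 Hz, syllabic-rate) process;
* babble: a sum of RMS-equalised independent speech-like talkers;
* mixtures at exact target SNRs;
* EEG: the encoding model run forward — three TRF-convolved weighted
  envelope features per channel — plus spatially mixed 1/f noise.

Everything is deterministic per seed (numpy SeedSequence spawning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .conditions import ConditionGrid
from .containers import EEGRecording
from .encoding import FEATURES, TRFSet, build_features, lag_axis
from .envelope import Envelope, COMPRESSION_EXPONENT
from .filters import FilterSpec, apply_filter, design_fir, resample


# ---------------------------------------------------------------------------
# audio-level generators
# ---------------------------------------------------------------------------

def _modulator(n: int, rate: float, band: tuple[float, float],
               rng: np.random.Generator) -> np.ndarray:
    """Positive syllabic-rate modulation process.

    Gaussian noise bandpassed to ``band`` with a gentle emphasis towards
    ~4 Hz (an extra lowpass pole), offset and rectified so the process is
    nonnegative with rich modulation depth.
    """
    lo, hi = band
    bp = design_fir(FilterSpec("bandpass", cutoff_lo=lo, cutoff_hi=hi,
                               transition_bw=max(lo, 1.0)), rate)
    # one-pole-style tilt concentrating energy near the syllabic rate
    tilt = design_fir(FilterSpec("lowpass", cutoff_hi=min(4.5, hi),
                                 transition_bw=4.0), rate)
    pad = len(bp) + len(tilt)        # short requests padded out, then cropped
    g = rng.standard_normal(n + 2 * pad)
    g = apply_filter(g, bp, "forward-compensated")
    g = apply_filter(g, tilt, "forward-compensated")
    g = g[pad:pad + n]
    g /= max(g.std(), 1e-12)
    return np.maximum(g + 1.0, 0.0)


def synth_speech_audio(duration: float, rate: float = 44100.0,
                       modulation_band: tuple[float, float] = (1.0, 12.0),
                       seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Speech-like audio: noise carrier × low-frequency modulator.

    The amplitude envelope of the output concentrates its modulation
    energy inside ``modulation_band`` (default 1–12 Hz, peaking near the
    ~4 Hz syllabic rate).  Deterministic per seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    # modulator computed at a low rate and upsampled: cheap and band-exact
    mod_rate = 100.0
    m = _modulator(int(round(duration * mod_rate)), mod_rate,
                   modulation_band, rng)
    m_up = resample(m, mod_rate, rate)
    m_up = np.maximum(m_up, 0.0)
    if len(m_up) < n:
        m_up = np.pad(m_up, (0, n - len(m_up)), mode="edge")
    carrier = rng.standard_normal(n)
    audio = carrier * m_up[:n]
    return 0.1 * audio / max(audio.std(), 1e-12)


def synth_babble(duration: float, rate: float = 44100.0,
                 n_talkers: int = 4,
                 seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Multi-talker babble: RMS-equalised independent speech-like streams."""
    if n_talkers < 1:
        raise ValueError("need at least one talker")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_talkers)
    total = None
    for child in children:
        s = synth_speech_audio(duration, rate, seed=child)
        s = s / np.sqrt(np.mean(s ** 2))
        total = s if total is None else total + s
    return total


def mix_at_snr(target: np.ndarray, noise: np.ndarray,
               snr_db: float | None) -> np.ndarray:
    """Add noise rescaled so the target-to-noise RMS ratio equals snr_db.

    ``snr_db=None`` is the quiet condition: the target is returned as is.
    """
    target = np.asarray(target, float)
    if snr_db is None:
        return target.copy()
    noise = np.asarray(noise, float)
    if target.shape != noise.shape:
        raise ValueError("target and noise must be equal length")
    rms_t = np.sqrt(np.mean(target ** 2))
    rms_n = np.sqrt(np.mean(noise ** 2))
    if rms_n == 0:
        raise ValueError("zero-RMS noise cannot be scaled to a finite SNR")
    scale = rms_t / (rms_n * 10 ** (snr_db / 20.0))
    return target + scale * noise


# ---------------------------------------------------------------------------
# ground-truth TRFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRFComponent:
    """One response component of a ground-truth TRF.

    A Gaussian-windowed bump at ``latency_ms`` with SD ``width_ms``,
    optionally riding on a cosine carrier (band-limiting the component to
    a chosen EEG band), with a smooth cross-channel topography.
    """

    feature: str
    latency_ms: float
    width_ms: float
    amplitude: float
    carrier_hz: float | None = None
    topography: np.ndarray | None = None


@dataclass
class GroundTruth:
    """Known TRFs plus the noise model used to generate synthetic EEG."""

    trfs: TRFSet
    noise_exponent: float = 1.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.trfs.n_channels


def make_ground_truth_trfs(n_channels: int, lags_ms: np.ndarray,
                           components: list[TRFComponent],
                           seed: int = 0,
                           noise_exponent: float = 1.0) -> GroundTruth:
    """Assemble ground-truth TRFs from a list of components."""
    lags_ms = np.asarray(lags_ms, float)
    rng = np.random.default_rng(seed)
    trfs = {f: np.zeros((n_channels, len(lags_ms))) for f in FEATURES}
    ch = np.arange(n_channels)
    for comp in components:
        if comp.feature not in trfs:
            raise ValueError(f"unknown feature {comp.feature!r}")
        if not lags_ms.min() <= comp.latency_ms <= lags_ms.max():
            raise ValueError(f"latency {comp.latency_ms} ms outside the "
                             f"lag axis")
        t = lags_ms - comp.latency_ms
        bump = np.exp(-0.5 * (t / comp.width_ms) ** 2)
        if comp.carrier_hz is not None:
            bump = bump * np.cos(2 * np.pi * comp.carrier_hz * t / 1000.0)
        if comp.topography is not None:
            topo = np.asarray(comp.topography, float)
        else:
            centre = rng.uniform(0, n_channels - 1)
            topo = np.exp(-0.5 * ((ch - centre)
                                  / max(n_channels / 3.0, 1.0)) ** 2)
        trfs[comp.feature] += comp.amplitude * topo[:, None] * bump[None, :]
    return GroundTruth(TRFSet(trfs, lags_ms), noise_exponent, seed)


def default_ground_truth(n_channels: int = 3, rate: float = 100.0,
                         seed: int = 0) -> GroundTruth:
    """Plausible three-feature ground truth.

    Component latencies follow the canonical delta-band response
    cartography: background at 80 ms, clarity at 90 and 390 ms,
    comprehension at −110 and 230 ms.
    """
    lags = lag_axis(-500, 700, rate) * 1000.0 / rate
    comps = [
        TRFComponent("background", 80.0, 40.0, 1.0),
        TRFComponent("clarity", 90.0, 40.0, 1.0),
        TRFComponent("clarity", 390.0, 60.0, -0.6),
        TRFComponent("comprehension", -110.0, 50.0, 0.7),
        TRFComponent("comprehension", 230.0, 60.0, -1.0),
    ]
    return make_ground_truth_trfs(n_channels, lags, comps, seed=seed)


def dissociated_ground_truth(n_channels: int = 4, rate: float = 100.0,
                             seed: int = 0) -> GroundTruth:
    """Band-dissociated ground truth for the headline property test.

    The clarity TRF is confined to the theta band (6 Hz carrier) and the
    comprehension TRF to the delta band (2.5 Hz carrier), so clarity
    should be decodable from theta-band tracking only and comprehension
    from delta-band tracking only.
    """
    lags = lag_axis(-500, 700, rate) * 1000.0 / rate
    comps = [
        TRFComponent("background", 80.0, 120.0, 0.3, carrier_hz=2.5),
        TRFComponent("background", 60.0, 60.0, 0.3, carrier_hz=6.0),
        TRFComponent("clarity", 90.0, 120.0, 1.0, carrier_hz=6.0),
        TRFComponent("comprehension", 230.0, 250.0, 1.0, carrier_hz=2.5),
    ]
    return make_ground_truth_trfs(n_channels, lags, comps, seed=seed)


# ---------------------------------------------------------------------------
# envelopes and EEG
# ---------------------------------------------------------------------------

def synth_envelope(duration: float, rate: float = 100.0,
                   modulation_band: tuple[float, float] = (1.0, 12.0),
                   seed: int | np.random.SeedSequence = 0,
                   compressed: bool = True) -> Envelope:
    """Speech-like compressed envelope generated directly at ``rate``.

    Equivalent in statistics to running the audio pipeline's envelope
    extraction on :func:`synth_speech_audio`, but generated directly at
    the analysis rate — used for EEG-level simulations where the audio
    carrier itself is irrelevant.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    m = _modulator(n, rate, modulation_band, rng)
    if compressed:
        m = m ** COMPRESSION_EXPONENT
    return Envelope(m, rate)


def synth_condition_envelopes(grid: ConditionGrid, duration: float,
                              rate: float = 100.0, seed: int = 0,
                              n_talkers: int = 4
                              ) -> dict[str, tuple[Envelope, Envelope]]:
    """(target, babble) compressed envelopes per condition at ``rate``.

    Babble envelopes are sums of ``n_talkers`` RMS-equalised modulators,
    compressed; quiet conditions get an all-zero babble envelope.  Each
    condition uses an independent child seed, mirroring the experiment's
    non-repeating stimuli.
    """
    ss = np.random.SeedSequence(seed)
    out = {}
    for label, child in zip(grid.labels, ss.spawn(len(grid))):
        sub = child.spawn(n_talkers + 1)
        y_t = synth_envelope(duration, rate, seed=sub[0])
        row = grid.table.iloc[[i for i, la in enumerate(grid.labels)
                               if la == label][0]]
        if row.background == "quiet":
            y_b = Envelope(np.zeros_like(y_t.samples), rate)
        else:
            acc = None
            for s in sub[1:]:
                m = synth_envelope(duration, rate, seed=s,
                                   compressed=False).samples
                m = m / np.sqrt(np.mean(m ** 2))
                acc = m if acc is None else acc + m
            y_b = Envelope((acc / n_talkers) ** COMPRESSION_EXPONENT, rate)
        out[label] = (y_t, y_b)
    return out


def one_over_f_noise(n_channels: int, n_samples: int, rate: float,
                     exponent: float, rng: np.random.Generator
                     ) -> np.ndarray:
    """Spatially mixed 1/f^exponent noise, unit RMS per channel."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * shaping
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    # smooth random spatial mixing correlates the channels
    mix = np.eye(n_channels) + 0.5 * rng.standard_normal(
        (n_channels, n_channels)) / np.sqrt(n_channels)
    noise = mix @ noise
    noise /= noise.std(axis=1, keepdims=True)
    return noise


def _convolve_trf(feature: np.ndarray, trf_row: np.ndarray,
                  lags: np.ndarray) -> np.ndarray:
    """y(t) = Σ_l T[l] · f(t − l) with an arbitrary integer lag axis."""
    full = signal.fftconvolve(feature, trf_row)
    n = len(feature)
    lmin = int(lags.min())
    idx = np.arange(n) - lmin
    out = np.zeros(n)
    ok = (idx >= 0) & (idx < len(full))
    out[ok] = full[idx[ok]]
    return out


def synth_eeg(grid: ConditionGrid,
              envelopes: dict[str, tuple[Envelope, Envelope]],
              gt: GroundTruth, noise_gain: float = 1.0,
              seed: int = 0, rate: float = 100.0
              ) -> dict[str, EEGRecording]:
    """Synthetic EEG per condition from the forward encoding equation.

    The signal part of channel j is exactly
    (1−a)·T_B∗y_B + T_A∗(a·y_T) + T_C∗(c·y_T) for the condition's
    clarity a and comprehension c; additive 1/f noise is scaled so its
    per-channel RMS equals ``noise_gain`` × the mean signal RMS over all
    conditions and channels.
    """
    lags = np.round(gt.trfs.lags_ms * rate / 1000.0).astype(int)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid))
    signals = {}
    rms_acc = []
    for row, label in zip(grid, grid.labels):
        y_t, y_b = envelopes[label]
        if y_t.rate != rate or y_b.rate != rate:
            raise ValueError("envelopes must be at the EEG synthesis rate")
        feats = build_features(y_t, y_b, row.clarity_pct / 100.0,
                               row.comprehension_pct / 100.0)
        sig = np.zeros((gt.n_channels, len(y_t.samples)))
        for feat in FEATURES:
            trf = gt.trfs[feat]
            for ch in range(gt.n_channels):
                if np.any(trf[ch]):
                    sig[ch] += _convolve_trf(feats[feat], trf[ch], lags)
        signals[label] = sig
        rms_acc.append(np.sqrt(np.mean(sig ** 2)))
    ref_rms = float(np.mean(rms_acc))
    out = {}
    for (label, sig), child in zip(signals.items(), children):
        rng = np.random.default_rng(child)
        if noise_gain > 0:
            noise = one_over_f_noise(gt.n_channels, sig.shape[1], rate,
                                     gt.noise_exponent, rng)
            sig = sig + noise_gain * ref_rms * noise
        out[label] = EEGRecording(sig, rate)
    return out
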