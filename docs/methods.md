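# Methods

This note documents the models implemented in `speechtrack`, the defaults
chosen where the design was open, and what the synthetic-data validation
does and does not establish.

## Experimental design being modelled

Eight acoustic conditions: {English, Dutch} × {quiet, low, medium, high
babble noise}, the three noise levels at SNRs of 0.4, −1.4 and −3.2 dB.
Clarity (a) is the comprehension a native listener would achieve at that
SNR — 100, 81, 60, 34% — identical for both languages. Comprehension (c)
equals clarity for English and is 0 for Dutch. `design_grid()` carries
these printed integers; `build_condition_grid(curve)` recomputes them from
a psychometric curve. With the rounded curve parameters (α = −2.0 dB,
midpoint slope 0.15 dB⁻¹) the recomputed medium/high values are 59/33
rather than the printed 60/34; the printed values evidently come from an
unrounded fit, so the canonical grid keeps them as design inputs.

## Psychometric model

c(x) = [1 + e^(−β(x−α))]⁻¹ with α in dB and β in 1/dB; the midpoint slope
is β/4. Estimation is grid-based Bayesian (α ∈ [−15, 10] dB × 51,
β ∈ [0.05, 3] dB⁻¹ × 31, log-spaced): each sentence contributes a
Binomial(5, c(snr)) keyword-scoring likelihood — the five keywords are
treated as independent Bernoulli draws, a modelling choice since the
scoring protocol does not specify a dependence structure. The adaptive
placement picks, from 26 candidate SNRs, the one minimising the expected
posterior entropy (Kontsevich–Tyler style); the point estimate is the
posterior mean. With 72 adaptive sentences the midpoint is recovered to
~0.15 dB (median over seeds) — comfortably inside the ±1 dB target —
and adaptive placement beats fixed off-midpoint placement by a large
entropy margin.

## Signal conditioning

* Linear-phase FIR filters are Hamming-windowed sinc designs
  (`scipy.signal.firwin`), whose cutoff is naturally the −6 dB
  (half-amplitude) point. When a design order is not given explicitly it
  follows the Hamming rule order ≈ 3.3·rate/transition-bandwidth, rounded
  even (type I). Applied one-pass forward with reflect-padding by one
  kernel length and compensated for the group delay, a passband tone is
  aligned with its filtered version to 0 ± 1 sample.
* Minimum-phase (causal) filters are homomorphic transforms of the
  linear-phase prototype (`scipy.signal.minimum_phase`); their impulse
  response is identically zero before the impulse, which the tests assert
  exactly. The anticausal variant (for the causal-path envelope) flips the
  signal in time, filters causally, and flips back.
* Band edges: delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–12.5 Hz at −6 dB, so
  the nominal 1–4 / 4–8 / 8–12 Hz bands sit inside the passbands.
* Resampling is polyphase (`scipy.signal.resample_poly`) with its standard
  Kaiser anti-alias design; duration is preserved to one output sample.
* Slow drifts are removed by least-squares polynomial detrending.

## Envelope

Audio → earphone-response lowpass (−6 dB at 3500 Hz, transition 1 kHz) →
resample to 8 kHz → full-wave rectification → power-law compression with
exponent 0.6 → band filtering → resampling. Band filtering operates at an
intermediate 1 kHz rate: the conventional filter orders (3204 for the
band edges, 86 for the gentle 31 Hz encoder lowpass) encode transition
widths at a 1 kHz processing rate, so the compressed envelope is resampled
to 1 kHz first, filtered, then taken to 50 Hz (decoder) or 100 Hz
(encoder). Rectification only — no Hilbert transform, no auditory
filterbank. The pipeline is scale-covariant: scaling audio by k scales the
compressed envelope by k^0.6.

## Backward decoding

Single-lag ridge models over a −200..400 ms grid in 20 ms steps (M = 31;
the step is exactly one sample at the 50 Hz decoder rate). Positive lag
means the EEG follows the stimulus. Fivefold cross-validation uses
contiguous temporal blocks (random folds would leak autocorrelated
samples); the ridge parameter is selected from a logarithmic grid
10⁻⁶..10⁶ (13 points) by mean held-out correlation. All lags share a
common trimmed time range so each lag contributes the same segments.
Reconstructions are scored by Pearson r on consecutive 10-s segments;
segments with undefined correlation (constant signal) become missing
values and are dropped downstream.

## Property decoding

One ridge model per band and property maps the M-dimensional lag profile
of each 10-s segment to that segment's condition-level clarity or
comprehension, on the 0–100 scale, predictions not clipped. Folds are
stratified so every fold contains contiguous segment blocks from every
condition. λ is chosen by held-out RMSE. The permutation null shuffles
the *eight condition values* (segments inherit their condition's shuffled
value) and refits the complete cross-validated decoder per shuffle — fold
partition held fixed for paired comparability — with the add-one p
estimator p = (1 + #{null ≤ observed}) / (1 + N). The forward
(activation-pattern) transform is pattern = Cov(features)·ρ / Var(ẑ);
per-lag two-sided permutation p-values are corrected by Benjamini–Hochberg
over the M lags.

Permutation refits reuse a per-fold SVD of the fixed design, so the
thousandfold null refits cost O(n·M) each; under a null in which profiles
are independent of the property, the test rejects at 5.5% over 400 runs
at nominal α = 5%.

## Forward TRF model

Lagged ridge design over −500..700 ms at 100 Hz (121 lags × 3 features),
pooled across all eight conditions with per-condition designs built
separately so no row mixes two recordings. λ is selected by
leave-conditions-out cross-validation on predicted-EEG correlation. The
shuffle null permutes the EEG↔condition pairing (derangements preferred,
5000 shuffles at full experiment scale, 100–500 at desk scale), refits the pooled
model per permutation using precomputed per-condition cross-products, and
pools null coefficients over the lag range per (channel, feature). A
Gaussian is fitted and two-tailed thresholds computed at p = 0.01 divided
by the Bonferroni count. The comparison count defaults to
channels × features × lags — the cells the mass-univariate map examines
simultaneously — and is configurable. Significant *regions* are read as
runs of at least two consecutive significant lags within a channel;
isolated single-lag threshold crossings are discounted, the usual
minimal-cluster convention for mass-univariate maps.

## Synthetic data

The generator emulates the study conditions, not any particular
recording:

* **Speech-like audio**: Gaussian-noise carrier amplitude-modulated by a
  positive process whose spectrum is confined to 1–12 Hz with a gentle
  emphasis near the ~4 Hz syllabic rate (bandpassed noise, lowpass tilt,
  offset-rectified). Babble is the sum of four RMS-equalised independent
  streams; mixtures hit requested SNRs to 0.01 dB.
* **Ground-truth TRFs**: Gaussian-windowed bumps at chosen latencies with
  smooth cross-channel topographies, optionally on a cosine carrier to
  confine a component to one EEG band. Default component latencies follow
  the canonical response cartography (background 80 ms; clarity 90 and
  390 ms; comprehension −110 and 230 ms). The band-dissociated variant
  puts the clarity response on a 6 Hz carrier (theta) and the
  comprehension response on a 2.5 Hz carrier (delta).
* **EEG**: exactly the three-feature encoding equation per channel, plus
  1/f noise (spectral shaping, exponent 1.0 by default, spatially mixed
  across channels) scaled so per-channel noise RMS equals `noise_gain`
  times the mean signal RMS. `noise_gain = 1` is the "moderate noise"
  default: TRF recovery correlation is then ≈ 0.96, against ≥ 0.999
  noiseless.

Because the generator *is* the encoding model, passing recovery tests
shows the estimators invert the assumed generative process correctly — it
does not show the generative assumptions hold for real EEG (no
subject-level variability, no artifacts, no nonlinearity, no
head-geometry forward model).

## Problem sizes

Defaults mirror the study: ~10 min per condition (the dissociation runner
uses 600 s), 31 lags, fivefold CV, 1000/5000 shuffles at full scale. The
test-suite and acceptance runs use reduced sizes chosen as standard
desk-scale validation settings: 60 s per condition and 3 channels for TRF
recovery and the causality control, 600 s and 4 channels with 200
shuffles for the band dissociation, 100-shuffle nulls for calibration.
At these sizes the dissociation succeeds in ~85% of seeded replicates
(the residual misses are marginal p-values at exactly the 0.05 boundary,
as expected of a statistical criterion), and the causal path leaves no
negative-lag region in ≥95% of seeds.

## Known limitations

* The adaptive psychometric procedure is one member of the cited family;
  exact trial-by-trial behaviour of other implementations will differ.
* The envelope's "earphone response" is approximated by the stated
  3.5 kHz lowpass only.
* Clarity/comprehension enter linearly; the sigmoidal link between SNR
  and the properties is not modelled inside the decoders.
* ICA-based artifact rejection, bad-channel interpolation, scalp
  topography rendering and source localisation are out of scope.
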