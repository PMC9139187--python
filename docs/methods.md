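# Methods

## Scope and model

`usvkit` analyses isolation-induced ultrasonic vocalizations (USVs) of mouse
pups: it segments calls from audio, extracts spectrotemporal features,
assigns each call to one of ten syllable categories by a fixed rule system,
and tests per-pup call counts for genotype, sex and genotype × sex effects in
an unbalanced 2×2 cohort. A synthetic generator supplies labeled audio and
cohort tables so every stage can be validated against ground truth.

## Spectrogram

Short-time Fourier magnitudes with FFT length 256 samples, Hamming window of
the same length (no zero-padding), and 50% frame overlap (hop 128 samples).
Only full frames are analysed, so a waveform of *n* samples yields
⌊(*n* − 256)/128⌋ + 1 frames. Bin *k* is centred at *k*·fs/256 (0-based); at
the 375 kHz acquisition rate the bin spacing is ≈ 1.465 kHz and the frame
period ≈ 0.341 ms. All bins below the 20 kHz cut-off are zeroed (shapes kept
stable; idempotent). Magnitudes are stored linearly; dB conversion
(20 log₁₀, floor −120 dB) happens only at thresholding or display time,
because detection thresholds are defined in dB while features live in Hz.

## Call detection

The background level of each frequency bin is estimated as its median dB
over the whole recording — robust as long as calls are temporally sparse. A
frame is *voiced* when any in-band bin exceeds its floor by `threshold_db`
(default 15 dB). Maximal voiced runs become calls after closing unvoiced
gaps ≤ `max_gap_ms` (default 3 ms; jump calls are temporally continuous, so
longer gaps separate calls) and discarding runs shorter than
`min_duration_ms` (default 1 ms, which must stay below the 5 ms "Short"
class). Each segment carries its per-frame peak-frequency contour (argmax
over in-band bins) and peak magnitude. Segment bounds are half-open frame
intervals converted to seconds at frame centres ± half a frame period.

## Features

Per segment: duration (offset − onset, ms); f_max, f_min and modulation
Δf = f_max − f_min from the contour; *jumps* as inter-frame contour steps
|Δf| ≥ `jump_min_hz` (default 10 kHz — larger than any per-frame sweep of a
tonal call yet far below the synthetic jump sizes) on the raw contour;
*direction changes* as zigzag reversals of the 5-frame-median-smoothed
contour with excursion ≥ `reversal_min_hz` (default 3 kHz, suppressing
~1.5 kHz bin-quantization jitter) on both sides; *noisiness* as the fraction
of frames whose normalized in-band spectral entropy exceeds 0.85 being above
0.3; *extra components* as the fraction of frames with a secondary local
spectral maximum ≥ 0.25 of the primary at ≥ 10 kHz offset being above 0.3.
Shape descriptors (rise to / fall from the global contour maximum, and the
symmetric trough quantities) feed the chevron rule. By default extrema are
taken over the whole contour, jump discontinuities included; an option
restricts modulation to the widest inter-jump limb. "Noisy" and "additional
components" have no universally agreed operational definition in the USV
literature; the entropy and secondary-peak statistics above are this
package's operationalization, with all thresholds configurable.

## Taxonomy

Ten categories; the written criteria (duration vs 5 ms, modulation vs
6.25 kHz, one/multiple jumps, noisiness, overtones, chevron rise ≥ 12.5 kHz
/ fall ≥ 6.25 kHz, monotone vs multi-directional modulation) are not
mutually exclusive, so the classifier applies a fixed precedence in which
the most specific structural evidence wins:

jumps+noise (Mixed) → multiple jumps → one jump → extra components
(Complex) → Short/Flat (low modulation) → Chevron → Upward/Downward
(monotone) → Modulated (catch-all for modulated, multi-directional calls).

Open points resolved here: "Flat: time modulation > 5 ms" is read as call
duration (an evident typo); the unassigned boundary at exactly 5 ms goes to
Flat (half-open: Short is strictly < 5 ms); sub-5 ms calls with modulation
≥ 6.25 kHz fall through to the shape rules; the chevron is read as
rise-then-fall ("inverse U"), with a config flag for the fall-then-rise
reading. The classifier is total — an `Unclassified` sentinel exists
defensively but is unreachable under the precedence order, which tests
assert on 10,000 random feature vectors against an independent
exhaustive rule evaluator.

## Cohort statistics

Per outcome (total calls and each of the 10 type counts): fixed-effects
two-way ANOVA with interaction on raw counts. Because the default design is
unbalanced (13/26/7/9), main effects use **Type III (marginal) sums of
squares** under sum-to-zero coding: the SS of a term is the residual-SS
increase when its column is dropped from the full model
y = μ + a·g + b·s + c·gs (g, s ∈ {−1, +1}); F = SS/MSE with 1 and N−4 df.
Type I and II are available for sensitivity; all coincide on balanced data.
Post-hoc: all six pairwise comparisons of the four genotype × sex cells by
the Tukey–Kramer statistic, using the full-model MSE and residual df, with
SE(i,j) = √(MSE/2 · (1/nᵢ + 1/nⱼ)) and p from the studentized-range
distribution (k = 4). Group summaries report n, mean, and SEM = sd/√n
(missing for n = 1). No correction is applied across the 11 outcomes; a
within-sex-only contrast mode and log1p transform exist but are off by
default. The full report also derives two cohort-level counts: the number
of types with a significant genotype main effect, and the number of those
whose male WT-vs-KO Tukey contrast is significant while the female contrast
is not ("male-specific" types).

In the limit of very large effect sizes the significant-type count equals
the number of truly affected types *up to* the α-level false positives of
the unaffected outcomes, which no sample size removes; validation therefore
asserts that every affected type is always flagged and that the modal count
over replicate cohorts equals the affected number.

## Synthetic data

**Audio.** Calls are additive frequency-modulated sinusoids: the
instantaneous frequency follows piecewise-linear contour knots (a jump is an
instantaneous carrier step with no amplitude gap; phase is continuous
throughout), with raised-cosine anti-click ramps ≤ 0.5 ms. Complex calls add
a phase-locked overtone at twice the fundamental at 0.5 relative amplitude;
Mixed calls add broadband noise across the usable band at tone-comparable
power (narrower noise bands cannot push normalized spectral entropy —
normalized over all in-band bins — decisively above the 0.85 threshold).
Background noise is white Gaussian; per-call SNR is tone RMS over background
RMS in dB (30 dB in fixtures — a clean-recording convention, since real
studies report no per-call SNR). Prototype calls per category are randomized
within construction margins of at least twice each classification-threshold
distance (documented in `make_prototype`); calls never overlap and sessions
space them ≥ 20 ms apart, matching the detector's non-overlap contract.
Sessions default to the acquisition format (375 kHz, 5 min), but fixtures
and simulation studies render seconds-long sessions at 250 kHz — Nyquist
125 kHz still covers the 30–90 kHz call band and the Complex overtone — as
the package's standard problem size for validation.

What the generator does *not* emulate: overlapping or multi-animal calls,
room reverberation, microphone transfer functions, amplitude modulation
within calls, or realistic call-sequence syntax. Passing tests therefore
demonstrate correctness of the pipeline's contracts on clean, well-separated
calls, not field performance on degraded recordings.

**Cohorts.** Per-pup type counts are drawn with mean
baseline × genotype_mult (KO) × sex_mult (M) × interaction_mult (KO-M);
WT-female is the reference cell. Defaults: baseline 40 calls/type per
session (pups of this strain produce a few hundred calls in 5 min),
negative-binomial noise with size 8 (moderate overdispersion; size = ∞
degenerates to Poisson), or Gaussian pseudo-counts (sd 12, truncated at 0 —
truncation essentially never binds at the default mean) matching the
ANOVA's normality assumption for calibration studies. The effect structure
is synthetic: group sizes mirror a real unbalanced litter outcome, but the
multipliers are free parameters, not estimates of any real strain's biology.

## Numerical and design choices

* Least-squares fits use `numpy.linalg.lstsq`; the ANOVA's correctness is
  cross-checked in tests against statsmodels (`anova_lm` typ-3 with Sum
  coding, `pairwise_tukeyhsd`) and an explicit projection oracle to 1e−8.
* Type-I calibration: 5,000 Gaussian null cohorts give a genotype rejection
  rate within 3 binomial SE (±0.009) of α = 0.05; a 20,000-replicate spot
  check sits within 1.5 SE.
* Determinism: every stochastic component takes an integer seed
  (`numpy.random.default_rng`); rendering the same session spec twice is
  bit-identical, and CLI outputs embed the config hash and seed in a
  manifest.
* Degenerate inputs: empty spectrograms yield empty segment lists;
  one-frame segments take their duration from the frame hop with zero
  modulation; an ANOVA with an empty design cell or zero residual variance
  raises a named error rather than returning NaNs.

## Known limitations

Detection assumes non-overlapping calls and a stationary noise floor; the
classifier is strictly the rule system above (no learned typing); the
statistics are cell-means fixed-effects ANOVA — no litter random effects,
repeated measures, or count-GLM alternatives. Real recordings with heavy
overlap, drifting noise, or non-normal counts need care beyond these
contracts.
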