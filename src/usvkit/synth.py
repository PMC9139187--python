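"""Synthetic ultrasonic-vocalization sessions and cohort count tables.

Every downstream stage (spectrogram, detection, features, taxonomy,
statistics) is testable against ground truth produced here, without any
recorded audio. Two generators live in this module:

* **Audio sessions** — frequency-modulated sinusoid calls of the ten
  syllable categories, rendered additively over Gaussian background noise.
  :func:`make_prototype` constructs, per category, a call whose noise-free
  rendering is classified as that category by construction margins of at
  least twice each rule threshold (margins documented there).

* **Cohort tables** — per-pup counts for a 2x2 genotype x sex design with
  the unbalanced group sizes of a typical litter-limited study
  (WT-M 13, WT-F 26, KO-M 7, KO-F 9), with known multiplicative genotype,
  sex and interaction effect structure and negative-binomial or Gaussian
  count noise.

Calls never overlap in time (the detection stage assumes non-overlap); the
per-call signal-to-noise ratio is defined as tone RMS over background
noise RMS, in dB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .taxonomy import CallType, CALL_TYPES

TRUTH_COLUMNS = ["call_id", "onset_s", "offset_s", "type_label"]

#: Default pup call band (Hz): comfortably above the 20 kHz cut-off and
#: below Nyquist at every supported sampling rate.
CALL_BAND_HZ = (30000.0, 90000.0)

_JUMP_TYPES = {CallType.ONE_FREQUENCY_JUMP, CallType.FREQUENCY_JUMPS, CallType.MIXED}


@dataclass
class CallSpec:
    """One synthetic call.

    ``contour_points`` are (time-offset s, frequency Hz) knots; two
    consecutive knots with the same time offset encode an instantaneous
    frequency jump. ``jump_offsets_hz`` lists the signed step sizes (must
    match the zero-duration knot pairs). The harmonic component is an
    overtone at twice the instantaneous frequency; the noisy component is
    band-limited broadband noise spanning ``noise_bandwidth_hz`` around
    the contour mean at tone-comparable power.
    """

    type_label: CallType
    onset_s: float
    duration_s: float
    contour_points: list[tuple[float, float]]
    jump_offsets_hz: list[float] = field(default_factory=list)
    harmonic: bool = False
    harmonic_rel_amp: float = 0.0
    noisy: bool = False
    # Full usable band by default: normalized spectral entropy (the
    # downstream noisiness statistic) needs broadband energy across most
    # in-band bins to rise decisively above a tonal call's entropy.
    noise_bandwidth_hz: float = math.inf
    amplitude: float = 1.0

    def validate(self, nyquist_hz: float | None = None) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not self.contour_points:
            raise ValueError("contour_points must be nonempty")
        times = [t for t, _ in self.contour_points]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("contour_points must be time-sorted")
        for _, f in self.contour_points:
            if f <= 20000.0:
                raise ValueError(f"knot frequency {f} Hz not above 20 kHz")
            if nyquist_hz is not None and f >= nyquist_hz:
                raise ValueError(f"knot frequency {f} Hz not below Nyquist")
        n_steps = sum(1 for a, b in zip(times, times[1:]) if b == a)
        if n_steps != len(self.jump_offsets_hz):
            raise ValueError("jump_offsets_hz must match zero-duration knot pairs")
        if self.jump_offsets_hz and self.type_label not in _JUMP_TYPES:
            raise ValueError(f"{self.type_label.value} must not carry jumps")
        if self.harmonic and self.type_label is not CallType.COMPLEX:
            raise ValueError("harmonic flag reserved for Complex prototypes")
        if self.noisy and self.type_label is not CallType.MIXED:
            raise ValueError("noisy flag reserved for Mixed prototypes")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SessionSpec:
    """A synthetic recording session.

    Defaults mirror the recording setup the pipeline targets: 375 kHz
    sampling and 5-minute isolation sessions. Tests and simulation studies
    typically use shorter sessions at 250 kHz, which still covers the call
    band and the Complex overtone.
    """

    sample_rate_hz: float = 375000.0
    duration_s: float = 300.0
    calls: list[CallSpec] = field(default_factory=list)
    background_noise_rms: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        nyq = self.sample_rate_hz / 2.0
        prev_end = -math.inf
        for c in sorted(self.calls, key=lambda c: c.onset_s):
            c.validate(nyq)
            if c.onset_s < prev_end:
                raise ValueError("calls must not overlap in time")
            if c.onset_s < 0 or c.offset_s > self.duration_s:
                raise ValueError("call extends past session bounds")
            prev_end = c.offset_s


def snr_to_amplitude(snr_db: float, background_noise_rms: float) -> float:
    """Peak amplitude of a sinusoid whose RMS sits ``snr_db`` above noise."""
    return background_noise_rms * (10.0 ** (snr_db / 20.0)) * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Prototypes

def make_prototype(
    type_label: CallType,
    rng_seed: int,
    amplitude: float = 1.0,
    onset_s: float = 0.0,
) -> CallSpec:
    """Construct a call guaranteed (by margin) to classify as its label.

    Construction margins, relative to the classifier/extractor defaults
    (all at least 2x the threshold distance):

    * Short: 2.5-3.2 ms flat tone (5 ms bound; window smearing adds < 1 ms).
    * Flat: 30-50 ms flat tone (modulation ~0 vs the 6.25 kHz bound).
    * Upward/Downward: monotone 15-25 kHz sweep (>= 2x 6.25 kHz).
    * Modulated: two reversals with 10-14 kHz excursions (>= 2x the 3 kHz
      reversal threshold; modulation >= 2x 6.25 kHz).
    * Complex: flat tone plus overtone at 0.5 relative amplitude
      (2x the 0.25 secondary-peak threshold) one octave up (>= 2x the
      10 kHz offset threshold at 45-55 kHz fundamentals).
    * One jump / jumps: flat limbs stepped by 20-25 kHz (>= 2x the 10 kHz
      jump threshold), temporally continuous.
    * Mixed: a jump call plus in-call broadband noise at tone-comparable
      power (drives normalized spectral entropy well above 0.85).
    * Chevron: rise 25-30 kHz (>= 2x 12.5 kHz) then fall 13-18 kHz
      (>= 2x 6.25 kHz), single interior maximum.

    Raises ``ValueError`` for an unknown or sentinel label.
    """
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform

    def ms(lo: float, hi: float) -> float:
        return u(lo, hi) / 1e3

    if type_label is CallType.SHORT:
        f0 = u(55e3, 75e3)
        dur = ms(2.5, 3.2)
        pts = [(0.0, f0), (dur, f0)]
        return CallSpec(type_label, onset_s, dur, pts, amplitude=amplitude)

    if type_label is CallType.FLAT:
        f0 = u(50e3, 70e3)
        dur = ms(30, 50)
        return CallSpec(type_label, onset_s, dur, [(0.0, f0), (dur, f0)],
                        amplitude=amplitude)

    if type_label is CallType.UPWARD:
        f0 = u(45e3, 60e3)
        rise = u(15e3, 25e3)
        dur = ms(30, 50)
        return CallSpec(type_label, onset_s, dur, [(0.0, f0), (dur, f0 + rise)],
                        amplitude=amplitude)

    if type_label is CallType.DOWNWARD:
        f0 = u(65e3, 80e3)
        fall = u(15e3, 25e3)
        dur = ms(30, 50)
        return CallSpec(type_label, onset_s, dur, [(0.0, f0), (dur, f0 - fall)],
                        amplitude=amplitude)

    if type_label is CallType.MODULATED:
        f0 = u(55e3, 65e3)
        a = u(10e3, 14e3)
        b = u(10e3, 14e3)
        c = u(10e3, 14e3)
        dur = ms(40, 60)
        pts = [
            (0.0, f0),
            (dur / 3.0, f0 + a),
            (2.0 * dur / 3.0, f0 + a - b),
            (dur, f0 + a - b + c),
        ]
        return CallSpec(type_label, onset_s, dur, pts, amplitude=amplitude)

    if type_label is CallType.COMPLEX:
        f0 = u(45e3, 55e3)
        dur = ms(30, 50)
        return CallSpec(
            type_label, onset_s, dur, [(0.0, f0), (dur, f0)],
            harmonic=True, harmonic_rel_amp=0.5, amplitude=amplitude,
        )

    if type_label is CallType.ONE_FREQUENCY_JUMP:
        f0 = u(50e3, 62e3)
        step = u(20e3, 25e3)
        dur = ms(30, 50)
        tj = u(0.4, 0.6) * dur
        pts = [(0.0, f0), (tj, f0), (tj, f0 + step), (dur, f0 + step)]
        return CallSpec(type_label, onset_s, dur, pts, jump_offsets_hz=[step],
                        amplitude=amplitude)

    if type_label is CallType.FREQUENCY_JUMPS:
        f0 = u(50e3, 60e3)
        s1 = u(20e3, 25e3)
        s2 = -u(20e3, 25e3)
        dur = ms(40, 60)
        t1 = u(0.28, 0.38) * dur
        t2 = u(0.62, 0.72) * dur
        pts = [
            (0.0, f0), (t1, f0),
            (t1, f0 + s1), (t2, f0 + s1),
            (t2, f0 + s1 + s2), (dur, f0 + s1 + s2),
        ]
        return CallSpec(type_label, onset_s, dur, pts, jump_offsets_hz=[s1, s2],
                        amplitude=amplitude)

    if type_label is CallType.MIXED:
        f0 = u(50e3, 62e3)
        step = u(20e3, 25e3)
        dur = ms(30, 50)
        tj = u(0.4, 0.6) * dur
        pts = [(0.0, f0), (tj, f0), (tj, f0 + step), (dur, f0 + step)]
        return CallSpec(type_label, onset_s, dur, pts, jump_offsets_hz=[step],
                        noisy=True, amplitude=amplitude)

    if type_label is CallType.CHEVRON:
        f0 = u(45e3, 55e3)
        rise = u(25e3, 30e3)
        fall = u(13e3, 18e3)
        dur = ms(30, 50)
        tp = u(0.4, 0.6) * dur
        pts = [(0.0, f0), (tp, f0 + rise), (dur, f0 + rise - fall)]
        return CallSpec(type_label, onset_s, dur, pts, amplitude=amplitude)

    raise ValueError(f"unknown call type label: {type_label!r}")


# ---------------------------------------------------------------------------
# Rendering

def _render_call(call: CallSpec, sample_rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(call.duration_s * sample_rate_hz))
    if n < 2:
        raise ValueError("call too short for the sampling rate")
    t = np.arange(n) / sample_rate_hz

    pts = call.contour_points
    times = np.array([p[0] for p in pts])
    freqs = np.array([p[1] for p in pts])
    # Zero-duration knot pairs encode jumps: nudge the left knot epsilon
    # earlier so np.interp realises the step between adjacent samples.
    eps = 0.25 / sample_rate_hz
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i - 1] -= eps
    f_inst = np.interp(t, times, freqs)

    phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate_hz
    x = np.sin(phase)
    if call.harmonic and call.harmonic_rel_amp > 0:
        phase2 = 2.0 * phase  # overtone, phase-locked to the fundamental
        x = x + call.harmonic_rel_amp * np.sin(phase2)

    if call.noisy:
        x = x + _band_noise(
            n, sample_rate_hz, rng,
            center_hz=float(freqs.mean()),
            bandwidth_hz=call.noise_bandwidth_hz,
            rms=1.0 / math.sqrt(2.0),  # tone-comparable power
        )

    x *= _envelope(n, sample_rate_hz)
    return call.amplitude * x


def _envelope(n: int, sample_rate_hz: float) -> np.ndarray:
    """Raised-cosine onset/offset ramps (anti-click), <= 10% of the call."""
    ramp = min(int(0.5e-3 * sample_rate_hz), n // 10)
    env = np.ones(n)
    if ramp >= 2:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def _band_noise(
    n: int, sample_rate_hz: float, rng: np.random.Generator,
    center_hz: float, bandwidth_hz: float, rms: float,
) -> np.ndarray:
    """Gaussian noise band-limited by FFT masking, scaled to a target RMS."""
    nyq = sample_rate_hz / 2.0
    lo = max(25000.0, center_hz - bandwidth_hz / 2.0)
    hi = min(nyq - 5000.0, center_hz + bandwidth_hz / 2.0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate_hz)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def render_session(spec: SessionSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a session to a waveform plus its ground-truth call table.

    The waveform is the sum of phase-continuous frequency-modulated
    sinusoid calls (a jump is an instantaneous carrier step with no
    amplitude gap) over Gaussian background noise. Bit-identical for the
    same spec and seed.
    """
    spec.validate()
    n = int(round(spec.sample_rate_hz * spec.duration_s))
    rng = np.random.default_rng(spec.seed)
    wave = (
        rng.standard_normal(n) * spec.background_noise_rms
        if spec.background_noise_rms > 0
        else np.zeros(n)
    )
    rows = []
    for i, call in enumerate(sorted(spec.calls, key=lambda c: c.onset_s)):
        call_rng = np.random.default_rng((spec.seed, 1000003, i))
        x = _render_call(call, spec.sample_rate_hz, call_rng)
        i0 = int(round(call.onset_s * spec.sample_rate_hz))
        wave[i0:i0 + len(x)] += x[: max(0, n - i0)]
        rows.append(
            {
                "call_id": i,
                "onset_s": call.onset_s,
                "offset_s": call.offset_s,
                "type_label": call.type_label.value,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return wave, truth


def make_random_session(
    n_calls: int,
    seed: int,
    sample_rate_hz: float = 250000.0,
    snr_db: float = 30.0,
    background_noise_rms: float = 0.01,
    min_gap_s: float = 0.02,
    types: tuple[CallType, ...] = CALL_TYPES,
) -> SessionSpec:
    """A session of random non-overlapping prototype calls at a given SNR.

    Session length adapts to the call count (roughly 0.3 s per call) so
    simulation studies stay cheap; calls are spaced by at least
    ``min_gap_s`` to keep detection unambiguous.
    """
    rng = np.random.default_rng(seed)
    amp = snr_to_amplitude(snr_db, background_noise_rms)
    duration_s = max(0.5, 0.3 * n_calls)
    calls = []
    cursor = 0.05
    for i in range(n_calls):
        label = types[int(rng.integers(len(types)))]
        proto = make_prototype(label, int(rng.integers(2**31)), amplitude=amp)
        slack = (duration_s - 0.1 - cursor) - sum(
            0.08 for _ in range(n_calls - i)
        )
        jitter = rng.uniform(0.0, max(0.0, slack / max(1, n_calls - i)))
        proto.onset_s = cursor + jitter
        cursor = proto.offset_s + min_gap_s
        calls.append(proto)
    if calls and calls[-1].offset_s > duration_s - 0.01:
        duration_s = calls[-1].offset_s + 0.05
    return SessionSpec(
        sample_rate_hz=sample_rate_hz,
        duration_s=duration_s,
        calls=calls,
        background_noise_rms=background_noise_rms,
        seed=int(rng.integers(2**31)),
    )


def write_session(
    spec: SessionSpec, out_dir: str | Path, stem: str = "session"
) -> dict[str, Path]:
    """Write WAV (PCM 16-bit), ground-truth CSV, and the spec as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wave, truth = render_session(spec)
    peak = np.abs(wave).max()
    scaled = wave / (peak * 1.05) if peak > 0 else wave
    pcm = (scaled * 32767).astype(np.int16)
    wav_path = out / f"{stem}.wav"
    wavfile.write(wav_path, int(spec.sample_rate_hz), pcm)
    csv_path = out / f"{stem}_truth.csv"
    truth.to_csv(csv_path, index=False)
    yaml_path = out / f"{stem}_spec.yaml"
    d = asdict(spec)
    for c in d["calls"]:
        c["type_label"] = c["type_label"].value
        c["contour_points"] = [[float(a), float(b)] for a, b in c["contour_points"]]
    yaml_path.write_text(yaml.safe_dump(d, sort_keys=False))
    return {"wav": wav_path, "truth": csv_path, "spec": yaml_path}


# ---------------------------------------------------------------------------
# Cohort simulation

DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("WT", "M"): 13,
    ("WT", "F"): 26,
    ("KO", "M"): 7,
    ("KO", "F"): 9,
}


@dataclass
class CohortDesign:
    """A 2x2 genotype x sex cohort with known effect structure.

    Per-type expected counts are multiplicative:
    ``baseline * genotype_mult[KO] * sex_mult[M] * interaction_mult[KO-M]``
    (multipliers apply to the KO, male, and KO-male cells respectively;
    WT-female is the reference cell). ``dispersion`` is the
    negative-binomial size parameter (``inf`` degenerates to Poisson);
    ``noise_model="gaussian"`` draws truncated-at-zero Gaussian
    pseudo-counts instead, matching the normality assumption of the
    downstream ANOVA.
    """

    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    baseline_mean_per_type: np.ndarray = field(
        default_factory=lambda: np.full(10, 40.0)
    )
    genotype_mult: np.ndarray = field(default_factory=lambda: np.ones(10))
    sex_mult: np.ndarray = field(default_factory=lambda: np.ones(10))
    interaction_mult: np.ndarray = field(default_factory=lambda: np.ones(10))
    dispersion: float = 8.0
    noise_model: str = "negbin"
    gaussian_sd: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        for arr in (
            self.baseline_mean_per_type, self.genotype_mult,
            self.sex_mult, self.interaction_mult,
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != (10,) or np.any(a < 0):
                raise ValueError("effect vectors must be length-10 and >= 0")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("every group needs n >= 1")
        if self.noise_model not in ("negbin", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def cell_means(self, genotype: str, sex: str) -> np.ndarray:
        m = np.asarray(self.baseline_mean_per_type, dtype=float).copy()
        if genotype == "KO":
            m = m * np.asarray(self.genotype_mult, dtype=float)
        if sex == "M":
            m = m * np.asarray(self.sex_mult, dtype=float)
        if genotype == "KO" and sex == "M":
            m = m * np.asarray(self.interaction_mult, dtype=float)
        return m


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """One simulated cohort: a per-pup count table.

    Columns: pup_id, genotype, sex, total_calls, then one count column per
    syllable type. Deterministic given the design seed. Gaussian draws are
    truncated at 0.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    type_names = [ct.value for ct in CALL_TYPES]
    rows = []
    pup = 0
    for (genotype, sex), n in sorted(design.group_sizes.items()):
        means = design.cell_means(genotype, sex)
        for _ in range(n):
            if design.noise_model == "gaussian":
                counts = np.maximum(
                    0.0, rng.normal(means, design.gaussian_sd)
                )
            elif not np.isfinite(design.dispersion):
                counts = rng.poisson(means).astype(float)
            else:
                k = design.dispersion
                counts = np.where(
                    means > 0,
                    rng.negative_binomial(k, k / (k + np.maximum(means, 1e-12))),
                    0.0,
                ).astype(float)
            row = {
                "pup_id": f"pup{pup:03d}",
                "genotype": genotype,
                "sex": sex,
                "total_calls": float(counts.sum()),
            }
            row.update(dict(zip(type_names, counts)))
            rows.append(row)
            pup += 1
    return pd.DataFrame(rows, columns=["pup_id", "genotype", "sex", "total_calls"] + type_names)
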