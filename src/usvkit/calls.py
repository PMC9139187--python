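"""Call segmentation and acoustic feature extraction.

Detection operates on the cut-off spectrogram: a frame is "voiced" when its
loudest in-band bin rises more than ``threshold_db`` above that bin's
robust (median) noise floor; maximal voiced runs, after closing short gaps
and dropping sub-millisecond blips, become call segments carrying a
per-frame peak-frequency contour.

Feature extraction turns each segment into the complete input of the
10-type syllable classifier: duration, peak-frequency extrema and
modulation (max - min of the contour), significant contour reversals,
instantaneous frequency jumps, broadband noisiness (spectral entropy), and
additional spectral components (overtones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectro import Spectrogram, magnitudes_to_db


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation parameters.

    threshold_db : dB a bin must exceed its per-bin median to count as voiced.
    min_duration_ms : shortest run kept; must stay below the 5 ms "Short"
        class (3 ms calls exist), hence the 1 ms default.
    max_gap_ms : unvoiced gap bridged inside one call; jump calls are
        temporally continuous, so larger gaps split calls.
    """

    threshold_db: float = 15.0
    min_duration_ms: float = 1.0
    max_gap_ms: float = 3.0


@dataclass(frozen=True)
class FeatureParams:
    """Feature-extraction parameters (all configurable).

    jump_min_hz : minimum inter-frame contour step counted as an
        instantaneous frequency jump; must exceed per-frame sweep of tonal
        calls.
    reversal_min_hz : excursion a contour reversal needs on both sides to
        count as a direction change (suppresses ~1.5 kHz bin jitter).
    smooth_frames : median-filter length applied before reversal counting.
    entropy_thresh / noisy_frame_frac : a call is "noisy" when the fraction
        of frames whose normalized in-band spectral entropy exceeds
        ``entropy_thresh`` is above ``noisy_frame_frac``.
    secondary_rel_amp / min_offset_hz / harmonic_frame_frac : a call has
        "extra components" when enough frames show a secondary spectral
        peak at least ``secondary_rel_amp`` of the primary, at least
        ``min_offset_hz`` away.
    exclude_jumps_from_modulation : when True, peak-frequency extrema are
        taken per inter-jump limb; default False (whole contour).
    """

    jump_min_hz: float = 10000.0
    reversal_min_hz: float = 3000.0
    smooth_frames: int = 5
    entropy_thresh: float = 0.85
    noisy_frame_frac: float = 0.3
    secondary_rel_amp: float = 0.25
    min_offset_hz: float = 10000.0
    harmonic_frame_frac: float = 0.3
    exclude_jumps_from_modulation: bool = False


@dataclass(frozen=True)
class CallSegment:
    """A detected vocalization: time bounds plus peak-frequency contour."""

    onset_s: float
    offset_s: float
    frame_start: int  # half-open frame range [frame_start, frame_stop)
    frame_stop: int
    contour_hz: np.ndarray  # per-frame peak frequency
    contour_amp: np.ndarray  # per-frame peak magnitude

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")
        if len(self.contour_hz) != self.frame_stop - self.frame_start:
            raise ValueError("contour length must equal frame span length")


@dataclass(frozen=True)
class CallFeatures:
    """Complete classifier input for one call."""

    duration_ms: float
    fmax_hz: float
    fmin_hz: float
    modulation_hz: float  # fmax - fmin
    n_direction_changes: int
    monotone_direction: str  # "up" | "down" | "none"
    n_jumps: int
    noisy: bool
    extra_components: bool
    rise_to_peak_hz: float = 0.0  # contour max minus preceding minimum
    fall_from_peak_hz: float = 0.0  # contour max minus following minimum
    fall_to_trough_hz: float = 0.0  # preceding maximum minus contour min
    rise_from_trough_hz: float = 0.0  # following maximum minus contour min

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if not np.isclose(self.modulation_hz, self.fmax_hz - self.fmin_hz):
            raise ValueError("modulation_hz must equal fmax_hz - fmin_hz")
        if self.modulation_hz < 0 or self.n_jumps < 0:
            raise ValueError("negative modulation or jump count")


def _in_band(spec: Spectrogram) -> np.ndarray:
    """Boolean mask of analysis bins (at/above the applied cut-off)."""
    return spec.freqs_hz >= max(spec.cutoff_hz, 0.0)


def detect_calls(spec: Spectrogram, params: DetectionParams | None = None) -> list[CallSegment]:
    """Segment calls from a cut-off spectrogram.

    Returns segments sorted by onset, non-overlapping. An empty
    spectrogram yields an empty list.
    """
    params = params or DetectionParams()
    if spec.n_frames == 0:
        return []
    db = spec.to_db()
    band = _in_band(spec)
    db_band = db[band, :]
    # Robust per-bin noise floor: median over the whole recording. Calls are
    # sparse in time, so the median tracks the background, not the calls.
    floor = np.median(db_band, axis=1, keepdims=True)
    voiced = np.any(db_band - floor > params.threshold_db, axis=0)

    frame_ms = spec.frame_period_s * 1e3
    max_gap = int(np.floor(params.max_gap_ms / frame_ms))
    min_len = max(1, int(np.ceil(params.min_duration_ms / frame_ms)))

    runs = _runs(voiced)
    runs = _close_gaps(runs, max_gap)
    runs = [(a, b) for a, b in runs if b - a >= min_len]

    band_freqs = spec.freqs_hz[band]
    mags_band = spec.magnitudes[band, :]
    segments: list[CallSegment] = []
    for a, b in runs:
        sub = mags_band[:, a:b]
        peak_bins = np.argmax(sub, axis=0)
        contour = band_freqs[peak_bins]
        amps = sub[peak_bins, np.arange(b - a)]
        onset = spec.times_s[a] - spec.frame_period_s / 2.0
        offset = spec.times_s[b - 1] + spec.frame_period_s / 2.0
        segments.append(
            CallSegment(
                onset_s=float(onset),
                offset_s=float(offset),
                frame_start=int(a),
                frame_stop=int(b),
                contour_hz=contour,
                contour_amp=amps,
            )
        )
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _close_gaps(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def _median_smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or x.size <= 2:
        return x.astype(float)
    k = min(k, x.size if x.size % 2 == 1 else x.size - 1)
    if k % 2 == 0:
        k -= 1
    if k <= 1:
        return x.astype(float)
    pad = k // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.median(sliding_windows(xp, k), axis=1)


def sliding_windows(x: np.ndarray, k: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    return sliding_window_view(x, k)


def _count_reversals(
    contour: np.ndarray, min_excursion: float
) -> tuple[int, str, float, float, float, float]:
    """Zigzag reversal count on a (smoothed) contour.

    A reversal is a turning point with excursion >= ``min_excursion`` on
    both sides. Returns (n_reversals, monotone_direction, rise_to_peak,
    fall_from_peak, fall_to_trough, rise_from_trough); the shape numbers
    describe the excursions around the global contour maximum/minimum,
    used by the chevron rule.
    """
    x = np.asarray(contour, dtype=float)
    if x.size < 2:
        return 0, "none", 0.0, 0.0, 0.0, 0.0

    # Walk the contour keeping the last confirmed extremum; flip direction
    # only on moves >= min_excursion the other way.
    direction = 0  # +1 rising, -1 falling, 0 undecided
    last_ext = x[0]
    n_rev = 0
    for v in x[1:]:
        if direction == 0:
            if v - last_ext >= min_excursion:
                direction = 1
                last_ext = v
            elif last_ext - v >= min_excursion:
                direction = -1
                last_ext = v
        elif direction == 1:
            if v > last_ext:
                last_ext = v
            elif last_ext - v >= min_excursion:
                direction = -1
                last_ext = v
                n_rev += 1
        else:
            if v < last_ext:
                last_ext = v
            elif v - last_ext >= min_excursion:
                direction = 1
                last_ext = v
                n_rev += 1

    if n_rev == 0:
        if direction == 1:
            mono = "up"
        elif direction == -1:
            mono = "down"
        else:
            mono = "none"
    else:
        mono = "none"

    ipk = int(np.argmax(x))
    rise = float(x[ipk] - x[:ipk + 1].min())
    fall = float(x[ipk] - x[ipk:].min())
    itr = int(np.argmin(x))
    fall_tr = float(x[:itr + 1].max() - x[itr])
    rise_tr = float(x[itr:].max() - x[itr])
    return n_rev, mono, rise, fall, fall_tr, rise_tr


def _spectral_entropy(mag_col: np.ndarray) -> float:
    """Normalized Shannon entropy of the in-band magnitude distribution."""
    s = mag_col.sum()
    if s <= 0 or mag_col.size < 2:
        return 0.0
    p = mag_col / s
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(mag_col.size))


def _has_secondary_peak(
    mag_col: np.ndarray, freqs: np.ndarray, params: FeatureParams
) -> bool:
    ipk = int(np.argmax(mag_col))
    primary = mag_col[ipk]
    if primary <= 0:
        return False
    away = np.abs(freqs - freqs[ipk]) >= params.min_offset_hz
    if not np.any(away):
        return False
    # Secondary peak must be a local maximum, not the skirt of the primary.
    local_max = np.zeros_like(away)
    interior = slice(1, len(mag_col) - 1)
    local_max[interior] = (mag_col[1:-1] >= mag_col[:-2]) & (mag_col[1:-1] >= mag_col[2:])
    cand = away & local_max
    if not np.any(cand):
        return False
    return bool(mag_col[cand].max() >= params.secondary_rel_amp * primary)


def extract_features(
    seg: CallSegment, spec: Spectrogram, params: FeatureParams | None = None
) -> CallFeatures:
    """Compute the classifier's feature vector for one detected call.

    Deterministic: re-running on the same segment/spectrogram yields
    identical values. A one-frame segment gets its duration from the frame
    hop and zero modulation.
    """
    params = params or FeatureParams()
    contour = np.asarray(seg.contour_hz, dtype=float)
    duration_ms = (seg.offset_s - seg.onset_s) * 1e3

    fmax = float(contour.max())
    fmin = float(contour.min())

    # Instantaneous jumps: inter-frame steps of the raw contour with no
    # intervening silence (segments are gap-closed voiced runs, so all
    # consecutive frames are temporally continuous).
    steps = np.abs(np.diff(contour))
    n_jumps = int(np.count_nonzero(steps >= params.jump_min_hz))

    smooth = _median_smooth(contour, params.smooth_frames)
    n_rev, mono, rise, fall, fall_tr, rise_tr = _count_reversals(
        smooth, params.reversal_min_hz
    )

    if params.exclude_jumps_from_modulation and n_jumps > 0:
        # Modulation within limbs only: report the extrema of the widest
        # inter-jump limb, so the jump discontinuity itself does not count
        # toward frequency modulation.
        cut = np.flatnonzero(steps >= params.jump_min_hz) + 1
        spans = [
            (float(limb.max()), float(limb.min()))
            for limb in np.split(contour, cut)
            if limb.size > 0
        ]
        fmax, fmin = max(spans, key=lambda s: s[0] - s[1])

    band = _in_band(spec)
    sub = spec.magnitudes[band, :][:, seg.frame_start:seg.frame_stop]
    freqs = spec.freqs_hz[band]
    n_frames = sub.shape[1]
    if n_frames:
        ent = np.apply_along_axis(_spectral_entropy, 0, sub)
        noisy = float(np.mean(ent > params.entropy_thresh)) > params.noisy_frame_frac
        sec = [
            _has_secondary_peak(sub[:, j], freqs, params) for j in range(n_frames)
        ]
        extra = float(np.mean(sec)) > params.harmonic_frame_frac
    else:
        noisy = False
        extra = False

    return CallFeatures(
        duration_ms=float(duration_ms),
        fmax_hz=fmax,
        fmin_hz=fmin,
        modulation_hz=fmax - fmin,
        n_direction_changes=n_rev,
        monotone_direction=mono,
        n_jumps=n_jumps,
        noisy=bool(noisy),
        extra_components=bool(extra),
        rise_to_peak_hz=rise,
        fall_from_peak_hz=fall,
        fall_to_trough_hz=fall_tr,
        rise_from_trough_hz=rise_tr,
    )


FEATURE_COLUMNS = [
    "onset_s", "offset_s", "duration_ms", "fmax_hz", "fmin_hz",
    "modulation_hz", "n_direction_changes", "monotone_direction",
    "n_jumps", "noisy", "extra_components",
    "rise_to_peak_hz", "fall_from_peak_hz",
    "fall_to_trough_hz", "rise_from_trough_hz",
]


def features_table(
    segments: list[CallSegment],
    spec: Spectrogram,
    params: FeatureParams | None = None,
    session_id: str = "session",
) -> pd.DataFrame:
    """Per-call feature table (one row per detected call)."""
    rows = []
    for i, seg in enumerate(segments):
        f = extract_features(seg, spec, params)
        rows.append(
            {
                "session_id": session_id,
                "call_id": i,
                "onset_s": seg.onset_s,
                "offset_s": seg.offset_s,
                "duration_ms": f.duration_ms,
                "fmax_hz": f.fmax_hz,
                "fmin_hz": f.fmin_hz,
                "modulation_hz": f.modulation_hz,
                "n_direction_changes": f.n_direction_changes,
                "monotone_direction": f.monotone_direction,
                "n_jumps": f.n_jumps,
                "noisy": f.noisy,
                "extra_components": f.extra_components,
                "rise_to_peak_hz": f.rise_to_peak_hz,
                "fall_from_peak_hz": f.fall_from_peak_hz,
                "fall_to_trough_hz": f.fall_to_trough_hz,
                "rise_from_trough_hz": f.rise_from_trough_hz,
            }
        )
    cols = ["session_id", "call_id"] + FEATURE_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def features_from_row(row: pd.Series) -> CallFeatures:
    """Rebuild a CallFeatures from one feature-table row."""
    return CallFeatures(
        duration_ms=float(row["duration_ms"]),
        fmax_hz=float(row["fmax_hz"]),
        fmin_hz=float(row["fmin_hz"]),
        modulation_hz=float(row["fmax_hz"]) - float(row["fmin_hz"]),
        n_direction_changes=int(row["n_direction_changes"]),
        monotone_direction=str(row["monotone_direction"]),
        n_jumps=int(row["n_jumps"]),
        noisy=bool(row["noisy"]),
        extra_components=bool(row["extra_components"]),
        rise_to_peak_hz=float(row.get("rise_to_peak_hz", 0.0)),
        fall_from_peak_hz=float(row.get("fall_from_peak_hz", 0.0)),
        fall_to_trough_hz=float(row.get("fall_to_trough_hz", 0.0)),
        rise_from_trough_hz=float(row.get("rise_from_trough_hz", 0.0)),
    )
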