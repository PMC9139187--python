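"""Rule-based 10-type syllable classification of mouse pup USVs.

Calls are assigned to one of ten spectrotemporal categories based on
internal pitch changes, lengths, and shapes:

=================  ====================================================
Short              duration < 5 ms and frequency modulation < 6.25 kHz
Flat               duration >= 5 ms, modulation < 6.25 kHz
Upward             frequency rises in one direction, modulation >= 6.25 kHz
Downward           frequency falls in one direction, modulation >= 6.25 kHz
Modulated          two or more direction changes, modulation >= 6.25 kHz
Complex            one or more additional spectral components (overtone /
                   nonlinear phenomenon)
One frequency jump exactly one instantaneous frequency step, no noise
Frequency jumps    multiple instantaneous frequency steps, no noise
Mixed              one or more jumps plus broadband (noisy) components
Chevron            inverse-U shape: rises >= 12.5 kHz then falls >= 6.25 kHz
=================  ====================================================

The written criteria are not mutually exclusive (a noisy jump call also
satisfies the Modulated wording), so classification evaluates a fixed
precedence order in which the most specific structural evidence wins:
jumps/noise > extra components > low-modulation classes > chevron >
monotone sweeps > modulated. Under this order the procedure is total; the
``UNCLASSIFIED`` sentinel is retained defensively but unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .calls import CallFeatures, features_from_row


class CallType(str, Enum):
    """The ten substantive syllable categories plus a defensive sentinel."""

    SHORT = "Short"
    FLAT = "Flat"
    UPWARD = "Upward"
    DOWNWARD = "Downward"
    MODULATED = "Modulated"
    COMPLEX = "Complex"
    ONE_FREQUENCY_JUMP = "OneFrequencyJump"
    FREQUENCY_JUMPS = "FrequencyJumps"
    MIXED = "Mixed"
    CHEVRON = "Chevron"
    UNCLASSIFIED = "Unclassified"


#: The 10 substantive categories, in precedence-independent display order.
CALL_TYPES: tuple[CallType, ...] = tuple(
    t for t in CallType if t is not CallType.UNCLASSIFIED
)


@dataclass(frozen=True)
class TaxonomyThresholds:
    """Numeric thresholds of the classification rules.

    short_max_ms : upper duration bound of the Short class. The written
        criteria give "< 5 ms" (Short) and "> 5 ms" (Flat), leaving 5 ms
        unassigned; resolved half-open — durations >= 5 ms are not Short.
    modulation_min_hz : minimum peak-frequency modulation separating the
        frequency-modulated classes from Short/Flat.
    chevron_rise_min_hz / chevron_fall_min_hz : minimum rise and fall of
        the inverse-U chevron shape. ``chevron_fall_then_rise`` swaps the
        reading to fall-then-rise (U shape) for sensitivity analyses.
    """

    short_max_ms: float = 5.0
    modulation_min_hz: float = 6250.0
    chevron_rise_min_hz: float = 12500.0
    chevron_fall_min_hz: float = 6250.0
    chevron_fall_then_rise: bool = False

    def __post_init__(self) -> None:
        if min(
            self.short_max_ms,
            self.modulation_min_hz,
            self.chevron_rise_min_hz,
            self.chevron_fall_min_hz,
        ) <= 0:
            raise ValueError("all thresholds must be > 0")


def classify_call(
    f: CallFeatures, t: TaxonomyThresholds | None = None
) -> CallType:
    """Assign one call to exactly one syllable category.

    Rules are evaluated in fixed precedence order (first match wins):

    1. jumps >= 1 and noisy                      -> Mixed
    2. jumps >= 2                                -> FrequencyJumps
    3. jumps == 1                                -> OneFrequencyJump
    4. extra spectral components                 -> Complex
    5. duration < 5 ms and modulation < 6.25 kHz -> Short
    6. modulation < 6.25 kHz                     -> Flat
    7. single maximum, rise >= 12.5 kHz then
       fall >= 6.25 kHz                          -> Chevron
    8. monotone up                               -> Upward
    9. monotone down                             -> Downward
    10. otherwise (>= 2 directions, modulated)   -> Modulated

    Total function: every feature vector maps to exactly one label.
    """
    t = t or TaxonomyThresholds()
    if f.n_jumps >= 1 and f.noisy:
        return CallType.MIXED
    if f.n_jumps >= 2:
        return CallType.FREQUENCY_JUMPS
    if f.n_jumps == 1:
        return CallType.ONE_FREQUENCY_JUMP
    if f.extra_components:
        return CallType.COMPLEX
    if f.modulation_hz < t.modulation_min_hz:
        if f.duration_ms < t.short_max_ms:
            return CallType.SHORT
        return CallType.FLAT
    if _is_chevron(f, t):
        return CallType.CHEVRON
    if f.n_direction_changes == 0 and f.monotone_direction == "up":
        return CallType.UPWARD
    if f.n_direction_changes == 0 and f.monotone_direction == "down":
        return CallType.DOWNWARD
    return CallType.MODULATED


def _is_chevron(f: CallFeatures, t: TaxonomyThresholds) -> bool:
    if f.n_direction_changes != 1:
        return False
    if t.chevron_fall_then_rise:
        # U reading: falls to a single interior minimum then rises.
        return (
            f.fall_to_trough_hz >= t.chevron_fall_min_hz
            and f.rise_from_trough_hz >= t.chevron_rise_min_hz
        )
    # Inverse-U reading: rises to a single interior maximum then falls.
    return (
        f.rise_to_peak_hz >= t.chevron_rise_min_hz
        and f.fall_from_peak_hz >= t.chevron_fall_min_hz
    )


def classify_table(
    features: pd.DataFrame, t: TaxonomyThresholds | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Label every row of a per-call feature table.

    Returns the table with an appended ``call_type`` column and a Series
    of per-type counts indexed by the 10 category names (counts sum to the
    number of rows; types absent from the table count 0).
    """
    labeled = features.copy()
    if len(features):
        labels = [
            classify_call(features_from_row(row), t)
            for _, row in features.iterrows()
        ]
        labeled["call_type"] = [lab.value for lab in labels]
    else:
        labeled["call_type"] = pd.Series([], dtype=str)
    counts = pd.Series(
        {ct.value: int((labeled["call_type"] == ct.value).sum()) for ct in CALL_TYPES},
        name="count",
    )
    return labeled, counts
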