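"""Directional stress scoring from before/during HRV feature pairs.

Under acute stress, sympathetic activation typically raises heart rate
and the LF/HF ratio while SDNN, RMSSD, pNN50, HF power and total power
fall.  The stress score counts how many of the seven features moved in
their stressful direction between the waiting-room (before) and
in-treatment (during) windows, expressed as a percentage of seven:

    score = 100 * k / 7   (k = number of stressful shifts)

so the only attainable scores are 0, 14.29, 28.57, 42.86, 57.14,
71.43, 85.71 and 100 (rounded half-up to two decimals).  The binary
stress call is "yes" when the score exceeds 50% — with seven features,
exactly 50 is unattainable, so the yes/no dichotomy is exhaustive.

Conventions decided here (the underlying method leaves them open):
ties (exact equality) do NOT count as stressful — a measure-zero event
for continuous features, and the conservative choice; an undefined
LF/HF ratio (zero HF power) in either phase yields a False label plus
a data-quality flag rather than a guessed direction.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .types import FEATURE_ORDER, HRVFeatures, StressAssessment

__all__ = [
    "STRESS_DIRECTIONS",
    "SCORE_BINS",
    "label_changes",
    "stress_score",
    "classify_stress",
    "assess",
]

#: Expected direction of each feature under stress: +1 increase,
#: -1 decrease.
STRESS_DIRECTIONS: dict[str, int] = {
    "hr": +1,
    "sdnn": -1,
    "rmssd": -1,
    "pnn50": -1,
    "hf": -1,
    "lf_hf": +1,
    "tp": -1,
}

#: The eight attainable stress-score bins.
SCORE_BINS = (0.0, 14.29, 28.57, 42.86, 57.14, 71.43, 85.71, 100.0)


def label_changes(
    before: HRVFeatures,
    during: HRVFeatures,
    table: Mapping[str, int] = STRESS_DIRECTIONS,
) -> tuple[dict[str, bool], tuple[str, ...]]:
    """Label each feature True iff it strictly moved stressfully.

    Returns ``(labels, flags)`` where ``flags`` records data-quality
    issues (currently only an undefined LF/HF ratio).  The direction
    ``table`` may be overridden for sensitivity analyses but must cover
    exactly the seven canonical features.
    """
    if set(table) != set(FEATURE_ORDER):
        raise ValueError("direction table must cover exactly the seven features")
    b, d = before.as_dict(), during.as_dict()
    labels: dict[str, bool] = {}
    flags: list[str] = []
    for name in FEATURE_ORDER:
        bv, dv = b[name], d[name]
        if bv is None or dv is None:
            if name != "lf_hf":
                raise ValueError(f"missing feature value: {name}")
            labels[name] = False
            flags.append("lf_hf_undefined")
            continue
        direction = table[name]
        labels[name] = (dv - bv) * direction > 0  # strict move; ties False
    return labels, tuple(flags)


def stress_score(labels: Mapping[str, bool]) -> float:
    """Quantized stress score: 100*k/7 rounded half-up to 2 decimals."""
    if len(labels) != len(FEATURE_ORDER):
        raise ValueError("exactly seven directional labels are required")
    k = sum(bool(v) for v in labels.values())
    raw = Decimal(100 * k) / Decimal(7)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_stress(score: float) -> bool:
    """Binary call: stressed iff score > 50%.

    A score of exactly 50 cannot arise from seven labels; assert so the
    >50 / <50 dichotomy stays exhaustive.
    """
    assert abs(score - 50.0) > 1e-9, "score of exactly 50 is unattainable"
    return score > 50.0


def assess(
    before: HRVFeatures,
    during: HRVFeatures,
    table: Mapping[str, int] = STRESS_DIRECTIONS,
) -> StressAssessment:
    """Full assessment: labels, quantized score and binary call."""
    labels, flags = label_changes(before, during, table)
    s = stress_score(labels)
    return StressAssessment(
        labels=labels, score=s, stressed=classify_stress(s), flags=flags
    )
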