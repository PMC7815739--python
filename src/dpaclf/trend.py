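"""Dynamic trend scores and the SDTs statistic.

Each of the four trended indicators — total bilirubin (TB), creatinine
(Cr), prothrombin activity (PTA), and hepatic-encephalopathy (HE) stage —
is scored 1/2/3 at a landmark timepoint by the direction and size of its
change from a reference panel (admission by default):

==========================  =====================  =====  =====================
indicator (adverse dir.)    score 1                2      score 3
==========================  =====================  =====  =====================
TB, Cr (worse when up)      fell by > threshold    else   rose by > threshold
PTA (worse when down)       rose by > threshold    else   fell by > threshold
HE stage (worse when up)    improved >= delta      else   aggravated >= delta
==========================  =====================  =====  =====================

Lab changes are *relative* (fraction of the reference value); a change of
exactly the threshold scores 2 (the "<= threshold" band).  The sum of the
four scores is the SDTs statistic, ranging 4 (all improving) to 12 (all
deteriorating); default thresholds are 30% for the labs and one West-Haven
stage for HE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .cohort import PatientRecord, Timepoint

DEFAULT_LAB_THRESHOLD = 0.30
DEFAULT_HE_DELTA = 1


class AdverseDirection(str, enum.Enum):
    UP = "up"      # higher is worse (TB, Cr)
    DOWN = "down"  # lower is worse (PTA)


class TrendReference(str, enum.Enum):
    ADMISSION_BASELINE = "admission_baseline"
    PREVIOUS_TIMEPOINT = "previous_timepoint"


class InsufficientDataError(ValueError):
    """The record lacks the panels needed for this assessment."""


@dataclass(frozen=True)
class TrendConfig:
    """Threshold family for the trend scores.

    ``lab_threshold_*`` are relative-change fractions in [0.05, 0.95];
    ``he_delta`` is the stage change (1–3) counted as improvement or
    aggravation; ``reference`` selects the comparison panel.
    """

    lab_threshold_tb: float = DEFAULT_LAB_THRESHOLD
    lab_threshold_cr: float = DEFAULT_LAB_THRESHOLD
    lab_threshold_pta: float = DEFAULT_LAB_THRESHOLD
    he_delta: int = DEFAULT_HE_DELTA
    reference: TrendReference = TrendReference.ADMISSION_BASELINE

    def __post_init__(self) -> None:
        for name in ("lab_threshold_tb", "lab_threshold_cr", "lab_threshold_pta"):
            v = getattr(self, name)
            if not (0.05 <= v <= 0.95):
                raise ValueError(f"{name} must be in [0.05, 0.95], got {v}")
        if self.he_delta not in (1, 2, 3):
            raise ValueError(f"he_delta must be 1, 2 or 3, got {self.he_delta}")
        object.__setattr__(self, "reference", TrendReference(self.reference))


@dataclass
class TrendAssessment:
    """Per-indicator trend scores and their sum at one landmark."""

    patient_id: str
    timepoint: Timepoint
    tb_score: int
    cr_score: int
    pta_score: int
    he_score: int

    @property
    def sdts(self) -> int:
        return self.tb_score + self.cr_score + self.pta_score + self.he_score


def lab_trend_score(
    baseline: float,
    current: float,
    threshold: float = DEFAULT_LAB_THRESHOLD,
    adverse_direction: AdverseDirection | str = AdverseDirection.UP,
) -> int:
    """Score one lab's relative change r = (current − baseline)/baseline.

    Movement in the adverse direction by more than ``threshold`` scores 3,
    in the favourable direction scores 1, and |r| <= threshold scores 2.
    Scale-invariant: depends on the labs only through r.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    if current < 0:
        raise ValueError(f"current must be nonnegative, got {current}")
    r = (current - baseline) / baseline
    if AdverseDirection(adverse_direction) == AdverseDirection.DOWN:
        r = -r
    if r > threshold:
        return 3
    if r < -threshold:
        return 1
    return 2


def he_trend_score(baseline_stage: int, current_stage: int, delta: int = DEFAULT_HE_DELTA) -> int:
    """Score the West-Haven stage change: aggravated >= delta -> 3,
    improved >= delta -> 1, else 2 (including stage 0 at both times)."""
    for s in (baseline_stage, current_stage):
        if s not in (0, 1, 2, 3, 4):
            raise ValueError(f"HE stage must be 0-4, got {s}")
    change = current_stage - baseline_stage
    if change >= delta:
        return 3
    if -change >= delta:
        return 1
    return 2


def assess_trends(
    record: PatientRecord,
    timepoint: Timepoint | str,
    config: Optional[TrendConfig] = None,
) -> TrendAssessment:
    """Trend-score TB, Cr, PTA and HE for one patient at one landmark.

    The reference panel is the admission panel (default) or the previous
    panel in the record's series, per ``config.reference``.
    """
    config = config or TrendConfig()
    tp = Timepoint.coerce(timepoint)
    if tp == Timepoint.ADMISSION:
        raise ValueError("trend assessment requires a post-admission timepoint")
    current = record.panel(tp)
    if current is None:
        raise InsufficientDataError(f"{record.patient_id}: no panel at {tp.value}")
    if config.reference == TrendReference.ADMISSION_BASELINE:
        ref = record.panel(Timepoint.ADMISSION)
    else:
        idx = record.panels.index(current)
        ref = record.panels[idx - 1] if idx > 0 else None
    if ref is None:
        raise InsufficientDataError(f"{record.patient_id}: no reference panel for {tp.value}")
    return TrendAssessment(
        patient_id=record.patient_id,
        timepoint=tp,
        tb_score=lab_trend_score(ref.tb, current.tb, config.lab_threshold_tb, AdverseDirection.UP),
        cr_score=lab_trend_score(ref.cr, current.cr, config.lab_threshold_cr, AdverseDirection.UP),
        pta_score=lab_trend_score(ref.pta, current.pta, config.lab_threshold_pta, AdverseDirection.DOWN),
        he_score=he_trend_score(ref.he_stage, current.he_stage, config.he_delta),
    )


def trend_table(cohort, timepoint, config: Optional[TrendConfig] = None):
    """Per-patient TrendAssessment table for every record carrying the panel."""
    import pandas as pd

    rows = []
    for rec in cohort:
        try:
            a = assess_trends(rec, timepoint, config)
        except InsufficientDataError:
            continue
        rows.append({
            "patient_id": a.patient_id,
            "timepoint": a.timepoint.value,
            "tb_score": a.tb_score,
            "cr_score": a.cr_score,
            "pta_score": a.pta_score,
            "he_score": a.he_score,
            "sdts": a.sdts,
        })
    return pd.DataFrame(
        rows,
        columns=["patient_id", "timepoint", "tb_score", "cr_score", "pta_score", "he_score", "sdts"],
    )


__all__ = [
    "AdverseDirection",
    "DEFAULT_HE_DELTA",
    "DEFAULT_LAB_THRESHOLD",
    "InsufficientDataError",
    "TrendAssessment",
    "TrendConfig",
    "TrendReference",
    "assess_trends",
    "he_trend_score",
    "lab_trend_score",
    "trend_table",
]
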