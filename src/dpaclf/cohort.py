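"""Domain types and long-format CSV I/O for ACLF cohorts.

A cohort is a set of patients, each with patient-level covariates, a 90-day
outcome, and an ordered series of lab panels taken at admission and at fixed
post-admission landmarks (day 3, week 1, week 2).  Two CSV files carry a
cohort on disk: a long *labs* table with one row per (patient, timepoint)
and a *patients* table with one row per patient.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

# unit conversion factors (conventional molar masses)
BILIRUBIN_UMOL_PER_MG_DL = 17.1
CREATININE_UMOL_PER_MG_DL = 88.4


class CohortFormatError(ValueError):
    """The CSV input does not have the expected columns/structure."""


class CohortValidationError(ValueError):
    """A record violates a domain invariant."""


class Timepoint(str, enum.Enum):
    """Assessment landmarks, with calendar offsets from admission in days."""

    ADMISSION = "admission"
    DAY3 = "day3"
    WEEK1 = "week1"
    WEEK2 = "week2"

    @property
    def day_offset(self) -> int:
        return {"admission": 0, "day3": 3, "week1": 7, "week2": 14}[self.value]

    @classmethod
    def coerce(cls, value: "Timepoint | str") -> "Timepoint":
        return value if isinstance(value, cls) else cls(str(value))


#: landmarks usable for trend assessment (admission is the baseline)
LANDMARKS = (Timepoint.DAY3, Timepoint.WEEK1, Timepoint.WEEK2)


class Ascites(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


@dataclass
class LabPanel:
    """One timepoint's clinical measurements.

    Units: tb (total bilirubin) mg/dL, cr (creatinine) mg/dL, pta
    (prothrombin activity) percent, na mmol/L, albumin g/dL, wbc 10^9/L,
    map mmHg.  ``he_stage`` is the West-Haven grade 0-4.
    """

    timepoint: Timepoint
    tb: float
    cr: float
    pta: float
    inr: float
    na: float
    albumin: float
    he_stage: int
    wbc: Optional[float] = None
    map: Optional[float] = None
    pao2_fio2: Optional[float] = None
    ascites: Ascites = Ascites.NONE
    on_vasopressors: bool = False
    on_renal_replacement: bool = False

    def __post_init__(self) -> None:
        self.timepoint = Timepoint.coerce(self.timepoint)
        if isinstance(self.ascites, str):
            self.ascites = Ascites(self.ascites)

    def validate(self) -> None:
        if not self.tb > 0:
            raise CohortValidationError(f"tb must be > 0, got {self.tb}")
        if not self.cr > 0:
            raise CohortValidationError(f"cr must be > 0, got {self.cr}")
        if not (0 < self.pta <= 200):
            raise CohortValidationError(f"pta must be in (0, 200], got {self.pta}")
        if not self.inr >= 0.8:
            raise CohortValidationError(f"inr must be >= 0.8, got {self.inr}")
        if self.he_stage not in (0, 1, 2, 3, 4):
            raise CohortValidationError(f"he_stage must be 0-4, got {self.he_stage}")
        if not (100 <= self.na <= 160):
            raise CohortValidationError(f"na must be in [100, 160], got {self.na}")
        if self.wbc is not None and not self.wbc > 0:
            raise CohortValidationError(f"wbc must be > 0, got {self.wbc}")


@dataclass
class PatientRecord:
    """Patient-level covariates, outcome, and the panel series."""

    patient_id: str
    age: float
    sex: str
    wgo_type: int  # 1=A (no cirrhosis), 2=B (compensated), 3=C (decompensated)
    etiology_alcohol_only: int  # 1 alcoholic liver disease alone, 0 others
    hbv: int
    panels: list[LabPanel] = field(default_factory=list)
    survival_days: float = 90.0
    death90: int = 0
    transplant90: int = 0
    complete: int = 1

    _ORDER = {tp: i for i, tp in enumerate(Timepoint)}

    def __post_init__(self) -> None:
        self.panels = sorted(self.panels, key=lambda p: self._ORDER[p.timepoint])

    def validate(self) -> None:
        tps = [p.timepoint for p in self.panels]
        if len(set(tps)) != len(tps):
            raise CohortValidationError(
                f"{self.patient_id}: duplicate panel timepoints {tps}"
            )
        if Timepoint.ADMISSION not in tps:
            raise CohortValidationError(f"{self.patient_id}: admission panel required")
        if self.wgo_type not in (1, 2, 3):
            raise CohortValidationError(
                f"{self.patient_id}: wgo_type must be 1/2/3, got {self.wgo_type}"
            )
        if self.survival_days < 0:
            raise CohortValidationError(f"{self.patient_id}: negative survival_days")
        if self.death90 == 1 and not self.survival_days < 90:
            raise CohortValidationError(
                f"{self.patient_id}: death90=1 requires survival_days < 90"
            )
        for p in self.panels:
            p.validate()

    def panel(self, timepoint: Timepoint | str) -> Optional[LabPanel]:
        tp = Timepoint.coerce(timepoint)
        for p in self.panels:
            if p.timepoint == tp:
                return p
        return None

    def has_panel(self, timepoint: Timepoint | str) -> bool:
        return self.panel(timepoint) is not None


@dataclass
class Cohort:
    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("patient_ids are not unique")
        for r in self.records:
            r.validate()

    def subset(self, keep: Iterable[PatientRecord], provenance: str) -> "Cohort":
        return Cohort(records=list(keep), provenance=provenance)


LAB_COLUMNS = [
    "patient_id", "timepoint", "tb_mg_dl", "cr_mg_dl", "pta_pct", "inr",
    "na_mmol_l", "albumin_g_dl", "he_stage", "wbc_1e9_l", "map_mmhg",
    "pao2_fio2", "ascites", "on_vasopressors", "on_renal_replacement",
]
PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "wgo_type", "etiology_alcohol_only", "hbv",
    "survival_days", "death90", "transplant90", "complete",
]


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if pd.isna(value):
        return None
    return float(value)


def read_cohort(
    labs_path,
    patients_path,
    strict: bool = True,
    lab_units: str = "mg_dl",
) -> Cohort:
    """Assemble a :class:`Cohort` from the two-file long CSV layout.

    Parameters
    ----------
    labs_path, patients_path
        Paths to the labs (long) and patients (one row per patient) CSVs.
    strict
        If True, any invariant violation raises; otherwise offending
        patients are dropped with a logged count.
    lab_units
        ``"mg_dl"`` (storage convention) or ``"umol_l"``: bilirubin and
        creatinine columns given in µmol/L are converted on load.
    """
    labs = pd.read_csv(labs_path)
    patients = pd.read_csv(patients_path)
    missing = [c for c in LAB_COLUMNS if c not in labs.columns]
    missing += [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory columns: {missing}")
    if labs.duplicated(subset=["patient_id", "timepoint"]).any():
        dupes = labs[labs.duplicated(subset=["patient_id", "timepoint"], keep=False)]
        raise CohortValidationError(
            f"duplicate (patient_id, timepoint) rows: {sorted(set(dupes.patient_id))}"
        )
    if lab_units == "mg_dl":
        tb_div, cr_div = 1.0, 1.0
    elif lab_units == "umol_l":
        tb_div, cr_div = BILIRUBIN_UMOL_PER_MG_DL, CREATININE_UMOL_PER_MG_DL
    else:
        raise ValueError(f"lab_units must be 'mg_dl' or 'umol_l', got {lab_units!r}")

    panels_by_pid: dict[str, list[LabPanel]] = {}
    for row in labs.itertuples(index=False):
        panels_by_pid.setdefault(str(row.patient_id), []).append(
            LabPanel(
                timepoint=Timepoint(row.timepoint),
                tb=float(row.tb_mg_dl) / tb_div,
                cr=float(row.cr_mg_dl) / cr_div,
                pta=float(row.pta_pct),
                inr=float(row.inr),
                na=float(row.na_mmol_l),
                albumin=float(row.albumin_g_dl),
                he_stage=int(row.he_stage),
                wbc=_opt(row.wbc_1e9_l),
                map=_opt(row.map_mmhg),
                pao2_fio2=_opt(row.pao2_fio2),
                ascites=Ascites(row.ascites),
                on_vasopressors=bool(row.on_vasopressors),
                on_renal_replacement=bool(row.on_renal_replacement),
            )
        )

    records, dropped = [], 0
    for row in patients.itertuples(index=False):
        pid = str(row.patient_id)
        rec = PatientRecord(
            patient_id=pid,
            age=float(row.age),
            sex=str(row.sex),
            wgo_type=int(row.wgo_type),
            etiology_alcohol_only=int(row.etiology_alcohol_only),
            hbv=int(row.hbv),
            panels=panels_by_pid.get(pid, []),
            survival_days=float(row.survival_days),
            death90=int(row.death90),
            transplant90=int(row.transplant90),
            complete=int(row.complete),
        )
        try:
            rec.validate()
        except CohortValidationError:
            if strict:
                raise
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.warning("read_cohort: dropped %d invalid patient record(s)", dropped)
    cohort = Cohort(records=records, provenance=f"read:{labs_path}")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise CohortValidationError("patient_ids are not unique")
    return cohort


def cohort_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long labs table and per-patient table as DataFrames."""
    lab_rows, patient_rows = [], []
    for r in cohort:
        for p in r.panels:
            lab_rows.append({
                "patient_id": r.patient_id,
                "timepoint": p.timepoint.value,
                "tb_mg_dl": p.tb,
                "cr_mg_dl": p.cr,
                "pta_pct": p.pta,
                "inr": p.inr,
                "na_mmol_l": p.na,
                "albumin_g_dl": p.albumin,
                "he_stage": p.he_stage,
                "wbc_1e9_l": p.wbc,
                "map_mmhg": p.map,
                "pao2_fio2": p.pao2_fio2,
                "ascites": p.ascites.value,
                "on_vasopressors": int(p.on_vasopressors),
                "on_renal_replacement": int(p.on_renal_replacement),
            })
        patient_rows.append({
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "wgo_type": r.wgo_type,
            "etiology_alcohol_only": r.etiology_alcohol_only,
            "hbv": r.hbv,
            "survival_days": r.survival_days,
            "death90": r.death90,
            "transplant90": r.transplant90,
            "complete": r.complete,
        })
    return (
        pd.DataFrame(lab_rows, columns=LAB_COLUMNS),
        pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS),
    )


def write_cohort(cohort: Cohort, labs_path, patients_path) -> None:
    labs, patients = cohort_frames(cohort)
    labs.to_csv(labs_path, index=False)
    patients.to_csv(patients_path, index=False)


@dataclass
class StudyFilterResult:
    cohort: Cohort
    n_incomplete: int
    n_transplanted: int


def apply_study_filters(cohort: Cohort) -> StudyFilterResult:
    """Study-flow exclusions: incomplete records, then 90-day transplants.

    A record flagged for both counts once, under the incomplete-data
    exclusion (the first gate of the screening flow).
    """
    kept, n_inc, n_tx = [], 0, 0
    for r in cohort:
        if not r.complete:
            n_inc += 1
        elif r.transplant90:
            n_tx += 1
        else:
            kept.append(r)
    logger.info(
        "study filters: %d in, %d incomplete excluded, %d transplant excluded, %d kept",
        len(cohort), n_inc, n_tx, len(kept),
    )
    return StudyFilterResult(
        cohort=cohort.subset(kept, provenance=f"{cohort.provenance}|filtered"),
        n_incomplete=n_inc,
        n_transplanted=n_tx,
    )


def landmark_filter(cohort: Cohort, timepoint: Timepoint | str) -> Cohort:
    """Keep patients alive past the landmark and assessed there.

    A patient enters the landmark-``timepoint`` analysis set if their
    survival time strictly exceeds the landmark offset (3/7/14 days), or
    they were censored alive at/beyond it, and they carry a lab panel at
    that timepoint.
    """
    tp = Timepoint.coerce(timepoint)
    if tp == Timepoint.ADMISSION:
        raise ValueError("landmark_filter requires a post-admission timepoint")
    off = tp.day_offset
    kept = [
        r
        for r in cohort
        if (r.survival_days > off or (r.death90 == 0 and r.survival_days >= off))
        and r.has_panel(tp)
    ]
    return cohort.subset(kept, provenance=f"{cohort.provenance}|landmark:{tp.value}")


__all__ = [
    "Ascites",
    "BILIRUBIN_UMOL_PER_MG_DL",
    "CREATININE_UMOL_PER_MG_DL",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "LabPanel",
    "LANDMARKS",
    "PatientRecord",
    "StudyFilterResult",
    "Timepoint",
    "apply_study_filters",
    "cohort_frames",
    "landmark_filter",
    "read_cohort",
    "write_cohort",
]
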