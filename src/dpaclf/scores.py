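"""Comparator prognostic scores for chronic liver failure.

Calculators for the six established severity scores the dynamic model is
benchmarked against: Child–Turcotte–Pugh (CTP), MELD, MELD-Na, CLIF-SOFA,
CLIF-C ACLF, and COSSH-ACLF.  Each calculator takes a
:class:`~dpaclf.cohort.LabPanel` (plus age where the formula needs it) and
returns a :class:`ScorePanel`; missing optional inputs yield a typed
"insufficient" result rather than an exception, so batch scoring never
aborts on a sparse record.

The CLIF organ band tables (0–4 CLIF-SOFA grid and 1–3 CLIF-C organ
function grid) are shipped as package data in ``organ_bands.yaml`` so the
banding is auditable and correctable without touching code.
"""

from __future__ import annotations

import bisect
import enum
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

from .cohort import (
    BILIRUBIN_UMOL_PER_MG_DL,
    Ascites,
    LabPanel,
)


class ScoreName(str, enum.Enum):
    CTP = "CTP"
    MELD = "MELD"
    MELD_NA = "MELD-Na"
    CLIF_SOFA = "CLIF-SOFA"
    CLIF_C_ACLF = "CLIF-C ACLF"
    COSSH_ACLF = "COSSH-ACLF"


COMPARATOR_SCORES = tuple(ScoreName)


@dataclass
class ScorePanel:
    """One score evaluation: value, component sub-scores, or why not."""

    score_name: ScoreName
    value: Optional[float] = None
    subscores: dict = field(default_factory=dict)
    insufficient: bool = False
    missing: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.insufficient == (self.value is None)


@lru_cache(maxsize=1)
def organ_bands() -> dict:
    text = resources.files("dpaclf").joinpath("organ_bands.yaml").read_text()
    return yaml.safe_load(text)


def _band_points(spec: dict, value: float) -> int:
    return spec["points"][bisect.bisect_right(spec["breaks"], value)]


def _insufficient(name: ScoreName, missing: list[str]) -> ScorePanel:
    return ScorePanel(score_name=name, insufficient=True, missing=missing)


# --- Child–Turcotte–Pugh -------------------------------------------------

_CTP_ASCITES = {Ascites.NONE: 1, Ascites.MILD: 2, Ascites.MODERATE_SEVERE: 3}


def ctp_score(panel: LabPanel) -> ScorePanel:
    """CTP: five 1–3 point components, total 5–15.

    Bands: bilirubin <2 / 2–3 / >3 mg/dL; albumin >3.5 / 2.8–3.5 / <2.8
    g/dL; INR <1.7 / 1.7–2.3 / >2.3; ascites none / mild / moderate-severe;
    encephalopathy absent / grade I–II / grade III–IV.
    """
    missing = [k for k in ("tb", "albumin", "inr", "he_stage") if getattr(panel, k) is None]
    if missing:
        return _insufficient(ScoreName.CTP, missing)
    sub = {
        "bilirubin": 1 if panel.tb < 2 else (2 if panel.tb <= 3 else 3),
        "albumin": 1 if panel.albumin > 3.5 else (2 if panel.albumin >= 2.8 else 3),
        "inr": 1 if panel.inr < 1.7 else (2 if panel.inr <= 2.3 else 3),
        "ascites": _CTP_ASCITES[panel.ascites],
        "encephalopathy": 1 if panel.he_stage == 0 else (2 if panel.he_stage <= 2 else 3),
    }
    return ScorePanel(ScoreName.CTP, float(sum(sub.values())), sub)


# --- MELD family ---------------------------------------------------------

def meld_from_parts(tb: float, cr: float, inr: float, on_rrt: bool = False) -> float:
    """UNOS MELD: 9.57·ln(Cr) + 3.78·ln(TB) + 11.2·ln(INR) + 6.43.

    Cr/TB/INR are floored at 1.0; Cr is capped at 4.0 and set to 4.0 on
    renal replacement therapy.  Reported unrounded.
    """
    if tb <= 0 or cr <= 0 or inr <= 0:
        raise ValueError("MELD inputs must be positive")
    cr = 4.0 if on_rrt else min(cr, 4.0)
    tb, cr, inr = max(tb, 1.0), max(cr, 1.0), max(inr, 1.0)
    return 9.57 * math.log(cr) + 3.78 * math.log(tb) + 11.2 * math.log(inr) + 6.43


def meld_score(panel: LabPanel) -> ScorePanel:
    value = meld_from_parts(panel.tb, panel.cr, panel.inr, panel.on_renal_replacement)
    return ScorePanel(ScoreName.MELD, value)


def meld_na_from_parts(meld: float, na: float) -> float:
    """MELD-Na: MELD + 1.32·(137 − Na) − 0.033·MELD·(137 − Na), Na in [125, 137]."""
    na = min(max(na, 125.0), 137.0)
    return meld + 1.32 * (137.0 - na) - 0.033 * meld * (137.0 - na)


def meld_na_score(panel: LabPanel) -> ScorePanel:
    meld = meld_from_parts(panel.tb, panel.cr, panel.inr, panel.on_renal_replacement)
    return ScorePanel(ScoreName.MELD_NA, meld_na_from_parts(meld, panel.na))


# --- CLIF organ grids ----------------------------------------------------

def _organ_subscores(panel: LabPanel, grid: dict) -> tuple[dict, list[str]]:
    """Apply one six-organ band grid; return (subscores, missing inputs)."""
    sub: dict[str, int] = {}
    missing: list[str] = []

    liver = grid["liver_tb_mg_dl"]
    sub["liver"] = _band_points(liver, panel.tb)

    kidney = grid["kidney_cr_mg_dl"]
    sub["kidney"] = (
        kidney["renal_replacement_points"]
        if panel.on_renal_replacement
        else _band_points(kidney, panel.cr)
    )

    sub["cerebral"] = _band_points(grid["cerebral_he_stage"], panel.he_stage)
    sub["coagulation"] = _band_points(grid["coagulation_inr"], panel.inr)

    circ = grid["circulation_map_mmhg"]
    if panel.on_vasopressors:
        sub["circulation"] = circ["vasopressor_points"]
    elif panel.map is None:
        missing.append("map")
    else:
        # descending variable; MAP exactly at the break counts as healthy
        sub["circulation"] = circ["points"][bisect.bisect_right(circ["breaks"], panel.map)]

    resp = grid["respiration_pao2_fio2"]
    if panel.pao2_fio2 is None:
        missing.append("pao2_fio2")
    else:
        sub["respiration"] = resp["points"][
            bisect.bisect_left(resp["breaks"], panel.pao2_fio2)
        ]
    return sub, missing


def clif_sofa_subscores(panel: LabPanel) -> tuple[dict, list[str]]:
    return _organ_subscores(panel, organ_bands()["clif_sofa"])


def clif_sofa_score(panel: LabPanel) -> ScorePanel:
    """CLIF-SOFA: sum of six 0–4 organ sub-scores (liver, kidney, brain,
    coagulation, circulation, respiration), range 0–24."""
    sub, missing = clif_sofa_subscores(panel)
    if missing:
        return _insufficient(ScoreName.CLIF_SOFA, missing)
    return ScorePanel(ScoreName.CLIF_SOFA, float(sum(sub.values())), sub)


def clif_of_subscores(panel: LabPanel) -> tuple[dict, list[str]]:
    """CLIF-C organ-function grid: six organs graded 1–3 (sum 6–18)."""
    return _organ_subscores(panel, organ_bands()["clif_of"])


def clif_c_aclf_from_parts(clif_ofs: float, age: float, wbc: float) -> float:
    """CLIF-C ACLF = 10·[0.33·CLIF-OFs + 0.04·age + 0.63·ln(WBC) − 2]."""
    if wbc <= 0:
        raise ValueError("wbc must be positive")
    return 10.0 * (0.33 * clif_ofs + 0.04 * age + 0.63 * math.log(wbc) - 2.0)


def clif_c_aclf_score(panel: LabPanel, age: float) -> ScorePanel:
    sub, missing = clif_of_subscores(panel)
    if panel.wbc is None:
        missing = missing + ["wbc"]
    if missing:
        return _insufficient(ScoreName.CLIF_C_ACLF, missing)
    ofs = sum(sub.values())
    value = clif_c_aclf_from_parts(ofs, age, panel.wbc)
    return ScorePanel(ScoreName.CLIF_C_ACLF, value, {**sub, "clif_ofs": ofs})


def cossh_aclf_from_parts(inr: float, hbv_sofa: float, age: float, tb_umol_l: float) -> float:
    """COSSH-ACLF = 0.741·INR + 0.523·HBV-SOFA + 0.026·age + 0.003·TB(µmol/L)."""
    return 0.741 * inr + 0.523 * hbv_sofa + 0.026 * age + 0.003 * tb_umol_l


def cossh_aclf_score(panel: LabPanel, age: float) -> ScorePanel:
    """COSSH-ACLF for HBV-related ACLF; TB converted mg/dL → µmol/L.

    The HBV-SOFA component reuses the six-organ 0–4 grid.
    """
    sub, missing = clif_sofa_subscores(panel)
    if missing:
        return _insufficient(ScoreName.COSSH_ACLF, missing)
    hbv_sofa = sum(sub.values())
    value = cossh_aclf_from_parts(
        panel.inr, hbv_sofa, age, panel.tb * BILIRUBIN_UMOL_PER_MG_DL
    )
    return ScorePanel(ScoreName.COSSH_ACLF, value, {**sub, "hbv_sofa": hbv_sofa})


def compute_score(name: ScoreName | str, panel: LabPanel, age: Optional[float] = None) -> ScorePanel:
    name = ScoreName(name)
    if name == ScoreName.CTP:
        return ctp_score(panel)
    if name == ScoreName.MELD:
        return meld_score(panel)
    if name == ScoreName.MELD_NA:
        return meld_na_score(panel)
    if name == ScoreName.CLIF_SOFA:
        return clif_sofa_score(panel)
    if age is None:
        raise ValueError(f"{name.value} requires patient age")
    if name == ScoreName.CLIF_C_ACLF:
        return clif_c_aclf_score(panel, age)
    return cossh_aclf_score(panel, age)


def score_cohort(cohort, scores=COMPARATOR_SCORES):
    """Batch scorer: per-patient, per-timepoint table of all requested scores."""
    import pandas as pd

    rows = []
    for rec in cohort:
        for panel in rec.panels:
            for name in scores:
                sp = compute_score(name, panel, age=rec.age)
                rows.append({
                    "patient_id": rec.patient_id,
                    "timepoint": panel.timepoint.value,
                    "score_name": ScoreName(name).value,
                    "value": sp.value,
                    "insufficient_reason": ",".join(sp.missing) if sp.insufficient else "",
                })
    return pd.DataFrame(rows)


__all__ = [
    "COMPARATOR_SCORES",
    "ScoreName",
    "ScorePanel",
    "clif_c_aclf_from_parts",
    "clif_c_aclf_score",
    "clif_of_subscores",
    "clif_sofa_score",
    "clif_sofa_subscores",
    "compute_score",
    "cossh_aclf_from_parts",
    "cossh_aclf_score",
    "ctp_score",
    "meld_from_parts",
    "meld_na_from_parts",
    "meld_na_score",
    "meld_score",
    "organ_bands",
    "score_cohort",
]
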