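"""The DP-ACLF dynamic prognostic model: formula, grading, and fitting.

DP-ACLF is a linear risk score for 90-day mortality in acute-on-chronic
liver failure, combining baseline covariates with the sum of dynamic trend
scores (SDTs) assessed at a landmark timepoint:

    DP-ACLF = 0.033*age + 0.326*WGO_type + 0.082*TB + 0.913*Cr
              + 0.817*SDTs - 0.040*PTA - 0.672*Etiology

with age in years, WGO type coded 1/2/3 (A/B/C), TB and Cr in mg/dL, PTA
in percent, and Etiology 1 for alcoholic liver disease alone.  The score
is the logistic linear predictor *without* its intercept (-10.441 in the
published fit); the grade cuts (8, 12) and reported cutoffs live on that
scale.  Grades: I < 8, II in [8, 12], III > 12.

This module also provides the two model-building procedures: a threshold
scan that picks each indicator's trend band by maximizing Harrell's C of a
univariate Cox fit, and forward likelihood-ratio logistic selection over
the seven candidate predictors.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, PatientRecord, Timepoint
from .evaluate import EstimationError, harrell_c
from .trend import InsufficientDataError, TrendConfig, assess_trends

logger = logging.getLogger(__name__)

#: coefficient order used throughout
CANDIDATE_VARIABLES = ("age", "wgo_type", "etiology_alcohol_only", "tb", "cr", "pta", "sdts")

#: per-unit weights of the published model
PUBLISHED_COEFFICIENTS = {
    "age": 0.033,
    "wgo_type": 0.326,
    "etiology_alcohol_only": -0.672,
    "tb": 0.082,
    "cr": 0.913,
    "pta": -0.040,
    "sdts": 0.817,
}
PUBLISHED_INTERCEPT = -10.441
GRADE_CUTS = (8.0, 12.0)


class Grade(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


@dataclass
class DPACLFModel:
    """Coefficient vector, optional intercept, selection trace, grade cuts."""

    coefficients: dict
    intercept: Optional[float] = None
    selection_trace: list = field(default_factory=list)
    grade_cuts: tuple = GRADE_CUTS

    @classmethod
    def published(cls) -> "DPACLFModel":
        return cls(coefficients=dict(PUBLISHED_COEFFICIENTS), intercept=PUBLISHED_INTERCEPT)

    def odds_ratios(self) -> dict:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}


def dp_aclf_score(
    age: float,
    wgo_type: int,
    etiology_alcohol_only: int,
    tb: float,
    cr: float,
    pta: float,
    sdts: int,
    model: Optional[DPACLFModel] = None,
) -> float:
    """Evaluate the DP-ACLF linear score (no intercept)."""
    model = model or DPACLFModel.published()
    values = {
        "age": age, "wgo_type": wgo_type, "etiology_alcohol_only": etiology_alcohol_only,
        "tb": tb, "cr": cr, "pta": pta, "sdts": sdts,
    }
    for k, v in values.items():
        if v is None:
            raise InsufficientDataError(f"missing input {k}")
    if wgo_type not in (1, 2, 3):
        raise ValueError(f"wgo_type must be 1/2/3, got {wgo_type}")
    return float(sum(model.coefficients.get(k, 0.0) * values[k] for k in values))


def dp_aclf_grade(score: float, cuts: tuple = GRADE_CUTS) -> Grade:
    """Grade I below the lower cut, III above the upper, II inclusive between."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    lo, hi = cuts
    if score < lo:
        return Grade.I
    if score > hi:
        return Grade.III
    return Grade.II


def score_record(
    record: PatientRecord,
    timepoint: Timepoint | str,
    config: Optional[TrendConfig] = None,
    model: Optional[DPACLFModel] = None,
) -> float:
    """DP-ACLF for one patient: landmark labs + SDTs vs. admission."""
    tp = Timepoint.coerce(timepoint)
    panel = record.panel(tp)
    if panel is None:
        raise InsufficientDataError(f"{record.patient_id}: no panel at {tp.value}")
    sdts = assess_trends(record, tp, config).sdts
    return dp_aclf_score(
        record.age, record.wgo_type, record.etiology_alcohol_only,
        panel.tb, panel.cr, panel.pta, sdts, model=model,
    )


def features_frame(
    cohort: Cohort,
    timepoint: Timepoint | str,
    config: Optional[TrendConfig] = None,
) -> pd.DataFrame:
    """Modelling table: the seven candidates plus outcome columns.

    Labs are taken from the landmark panel; SDTs is assessed against
    admission (or per ``config.reference``).  Records lacking the panel
    are skipped.
    """
    tp = Timepoint.coerce(timepoint)
    rows = []
    for rec in cohort:
        panel = rec.panel(tp)
        if panel is None:
            continue
        try:
            sdts = assess_trends(rec, tp, config).sdts
        except InsufficientDataError:
            continue
        rows.append({
            "patient_id": rec.patient_id,
            "age": rec.age,
            "wgo_type": rec.wgo_type,
            "etiology_alcohol_only": rec.etiology_alcohol_only,
            "tb": panel.tb,
            "cr": panel.cr,
            "pta": panel.pta,
            "sdts": sdts,
            "death90": rec.death90,
            "survival_days": rec.survival_days,
        })
    return pd.DataFrame(rows)


# --- threshold scan ------------------------------------------------------

DEFAULT_LAB_GRID = (0.10, 0.20, 0.30, 0.40, 0.50)
DEFAULT_HE_GRID = (1, 2, 3)


@dataclass
class ThresholdScanResult:
    indicator: str
    grid: list
    c_index_per_threshold: list
    chosen: float


def _config_with(indicator: str, value, base: TrendConfig) -> TrendConfig:
    key = {
        "tb": "lab_threshold_tb",
        "cr": "lab_threshold_cr",
        "pta": "lab_threshold_pta",
        "he": "he_delta",
    }[indicator]
    return replace(base, **{key: value})


def _cox_c_index(score: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C of a univariate Cox linear predictor of the score."""
    if np.all(score == score[0]):
        return 0.5
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"score": score, "time": time, "event": event})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["score"])
    c, _ = harrell_c(beta * score, time, event)
    return c


def scan_trend_threshold(
    cohort: Cohort,
    indicator: str,
    grid: Optional[Sequence] = None,
    timepoint: Timepoint | str = Timepoint.WEEK1,
    base_config: Optional[TrendConfig] = None,
    tie_preference: Optional[float] = None,
) -> ThresholdScanResult:
    """Pick the trend band maximizing Harrell's C of a univariate Cox fit.

    For each candidate threshold the indicator's 1/2/3 trend score is
    computed for every patient, survival is regressed on it (univariate
    proportional hazards), and the concordance of the fitted predictor is
    recorded.  Ties go to the preferred value (0.30 for labs, 1 stage for
    HE) and then to the smaller candidate.
    """
    if indicator not in ("tb", "cr", "pta", "he"):
        raise ValueError(f"indicator must be tb/cr/pta/he, got {indicator!r}")
    base_config = base_config or TrendConfig()
    if grid is None:
        grid = DEFAULT_HE_GRID if indicator == "he" else DEFAULT_LAB_GRID
    grid = list(grid)
    if tie_preference is None:
        tie_preference = 1 if indicator == "he" else 0.30

    time, event = [], []
    per_threshold_scores = {g: [] for g in grid}
    for rec in cohort:
        assessments = {}
        try:
            for g in grid:
                cfg = _config_with(indicator, g, base_config)
                a = assess_trends(rec, timepoint, cfg)
                assessments[g] = getattr(a, f"{indicator}_score")
        except InsufficientDataError:
            continue
        time.append(rec.survival_days)
        event.append(rec.death90)
        for g, s in assessments.items():
            per_threshold_scores[g].append(s)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise EstimationError("threshold scan needs at least 2 events")

    c_values = [
        _cox_c_index(np.asarray(per_threshold_scores[g], dtype=float), time, event)
        for g in grid
    ]
    best = max(c_values)
    tied = [g for g, c in zip(grid, c_values) if c >= best - 1e-12]
    chosen = tie_preference if tie_preference in tied else min(tied)
    return ThresholdScanResult(
        indicator=indicator, grid=grid, c_index_per_threshold=c_values, chosen=chosen
    )


# --- forward likelihood-ratio logistic selection -------------------------

class SeparationError(EstimationError):
    """Complete or quasi-complete separation in the logistic fit."""


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            raise SeparationError(str(exc)) from exc
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 1e3):
        raise SeparationError("degenerate logistic fit (separation suspected)")
    return res


def fit_dp_aclf(
    cohort_or_frame,
    timepoint: Timepoint | str = Timepoint.WEEK2,
    candidates: Sequence[str] = CANDIDATE_VARIABLES,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    config: Optional[TrendConfig] = None,
) -> DPACLFModel:
    """Forward stepwise logistic regression of 90-day death, LR criterion.

    At each step the candidate with the smallest likelihood-ratio p-value
    below ``entry_p`` enters; any included variable whose LR p-value rises
    above ``removal_p`` is then removed.  Returns the fitted coefficients,
    intercept, and the (step, variable, LR statistic, p, action) trace.
    """
    if isinstance(cohort_or_frame, Cohort):
        frame = features_frame(cohort_or_frame, timepoint, config)
    else:
        frame = cohort_or_frame
    candidates = list(candidates)
    y = frame["death90"].to_numpy(dtype=float)
    if len(frame) < 10 * len(candidates):
        warnings.warn(
            f"n={len(frame)} is small for {len(candidates)} candidates",
            stacklevel=2,
        )

    included: list[str] = []
    trace: list[tuple] = []
    step = 0
    ll_current = _fit_logit(y, frame[[]]).llf

    while True:
        step += 1
        # entry
        best = None
        for var in candidates:
            if var in included:
                continue
            res = _fit_logit(y, frame[included + [var]])
            lr = 2.0 * (res.llf - ll_current)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[1]:
                best = (var, p, lr, res)
        if best is None or best[1] >= entry_p:
            break
        var, p, lr, res = best
        included.append(var)
        ll_current = res.llf
        trace.append((step, var, float(lr), p, "enter"))
        # removal pass (never the variable entered this step)
        changed = True
        while changed and len(included) > 1:
            changed = False
            full = _fit_logit(y, frame[included])
            worst = None
            for v in included:
                if v == var:
                    continue
                reduced = _fit_logit(y, frame[[w for w in included if w != v]])
                lr_v = 2.0 * (full.llf - reduced.llf)
                p_v = float(stats.chi2.sf(max(lr_v, 0.0), df=1))
                if worst is None or p_v > worst[1]:
                    worst = (v, p_v, lr_v)
            if worst is not None and worst[1] > removal_p:
                included.remove(worst[0])
                trace.append((step, worst[0], float(worst[2]), worst[1], "remove"))
                ll_current = _fit_logit(y, frame[included]).llf
                changed = True

    if included:
        final = _fit_logit(y, frame[included])
        coefficients = {v: float(final.params[v]) for v in included}
        intercept = float(final.params["const"])
    else:
        coefficients, intercept = {}, float(_fit_logit(y, frame[[]]).params["const"])
    return DPACLFModel(coefficients=coefficients, intercept=intercept, selection_trace=trace)


# --- multivariable Cox ---------------------------------------------------

def cox_multivariable(
    cohort_or_frame,
    covariates: Sequence[str],
    timepoint: Timepoint | str = Timepoint.WEEK2,
    config: Optional[TrendConfig] = None,
) -> pd.DataFrame:
    """Proportional-hazards fit (Efron ties); HRs with Wald 95% CIs.

    Zero-variance covariates are excluded with a note in the returned
    table rather than failing the fit.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if isinstance(cohort_or_frame, Cohort):
        frame = features_frame(cohort_or_frame, timepoint, config)
    else:
        frame = cohort_or_frame
    covariates = list(covariates)
    usable = [c for c in covariates if frame[c].nunique() > 1]
    dropped = [c for c in covariates if c not in usable]

    df = frame[usable + ["survival_days", "death90"]]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="survival_days", event_col="death90")
    except ConvergenceError as exc:
        raise EstimationError(f"Cox fit did not converge: {exc}") from exc

    rows = []
    for c in covariates:
        if c in dropped:
            rows.append({"covariate": c, "coef": np.nan, "hr": np.nan,
                         "hr_lower": np.nan, "hr_upper": np.nan, "p": np.nan,
                         "note": "no variation"})
            continue
        beta = float(cph.params_[c])
        se = float(cph.standard_errors_[c])
        rows.append({
            "covariate": c,
            "coef": beta,
            "hr": float(np.exp(beta)),
            "hr_lower": float(np.exp(beta - 1.96 * se)),
            "hr_upper": float(np.exp(beta + 1.96 * se)),
            "p": float(cph.summary.loc[c, "p"]),
            "note": "",
        })
    return pd.DataFrame(rows)


__all__ = [
    "CANDIDATE_VARIABLES",
    "DEFAULT_HE_GRID",
    "DEFAULT_LAB_GRID",
    "DPACLFModel",
    "GRADE_CUTS",
    "Grade",
    "PUBLISHED_COEFFICIENTS",
    "PUBLISHED_INTERCEPT",
    "SeparationError",
    "ThresholdScanResult",
    "cox_multivariable",
    "dp_aclf_grade",
    "dp_aclf_score",
    "features_frame",
    "fit_dp_aclf",
    "scan_trend_threshold",
    "score_record",
]
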