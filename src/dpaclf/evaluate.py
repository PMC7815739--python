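"""Evaluation statistics for prognostic scores.

ROC/AUC with the DeLong structural-components variance and paired z-test,
Youden-index cutoffs with the usual operating-point metrics, Harrell's
concordance index and Somers' D for survival predictors, Kaplan–Meier
survival with the log-rank test, and Pearson's chi-square for contingency
tables.

AUC is the Mann–Whitney (midrank) estimator, so it is invariant under any
strictly increasing transform of the scores.  Harrell's C counts, over all
usable patient pairs (a pair is usable when the shorter follow-up ends in
death, or when exactly one of two equal follow-ups does), the fraction in
which the shorter-lived patient carries the higher risk score; predictor
ties count one half.  Somers' D = 2C − 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


class EstimationError(ValueError):
    """The requested statistic is not estimable from these data."""


# --- ROC / DeLong --------------------------------------------------------

def _structural_components(scores: np.ndarray, outcomes: np.ndarray):
    """DeLong V10/V01 placement components via midranks."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise EstimationError("both outcome classes must be present")
    combined = np.concatenate([pos, neg])
    rk_all = stats.rankdata(combined)        # midranks on the pooled sample
    rk_pos = stats.rankdata(pos)
    rk_neg = stats.rankdata(neg)
    v10 = (rk_all[:m] - rk_pos) / n          # per-positive placement values
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m    # per-negative placement values
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores: Sequence[float], outcomes: Sequence[int]) -> tuple[float, float]:
    """Tie-corrected Mann–Whitney AUC and its DeLong standard error."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    auc, v10, v01 = _structural_components(scores, outcomes)
    m, n = len(v10), len(v01)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    return auc, float(np.sqrt(var))


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[int],
) -> tuple[float, float]:
    """DeLong's z-test for two correlated (paired) AUCs; two-sided p."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != outcomes.shape:
        raise ValueError("paired scores must be given on identical cases")
    auc_a, v10_a, v01_a = _structural_components(scores_a, outcomes)
    auc_b, v10_b, v01_b = _structural_components(scores_b, outcomes)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# --- cutoff metrics ------------------------------------------------------

@dataclass
class CutoffReport:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: float
    lr_neg: float


def youden_cutoff(scores: Sequence[float], outcomes: Sequence[int]) -> CutoffReport:
    """Operating point maximizing Youden's J = sensitivity + specificity − 1.

    "Positive" means score >= cutoff predicts the event.  Candidate
    thresholds are the observed score values; the returned cutoff is the
    midpoint between the winning threshold and the next observed value
    below it, so perfectly separated classes get the gap midpoint.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if not (np.any(outcomes == 1) and np.any(outcomes == 0)):
        raise EstimationError("both outcome classes must be present")
    n_pos = int(outcomes.sum())
    n_neg = len(outcomes) - n_pos
    uniq = np.unique(scores)
    best_j, best_t = -np.inf, uniq[0]
    for t in uniq:
        pred = scores >= t
        sens = float((pred & (outcomes == 1)).sum()) / n_pos
        spec = float((~pred & (outcomes == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    below = uniq[uniq < best_t]
    cutoff = float((best_t + below[-1]) / 2.0) if len(below) else float(best_t)
    pred = scores >= best_t
    sens = float((pred & (outcomes == 1)).sum()) / n_pos
    spec = float((~pred & (outcomes == 0)).sum()) / n_neg
    acc = float((pred == (outcomes == 1)).mean())
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else np.inf
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else np.inf
    return CutoffReport(cutoff, sens, spec, acc, float(lr_pos), float(lr_neg))


# --- Harrell's C / Somers' D --------------------------------------------

def harrell_c(
    predictor: Sequence[float],
    survival_days: Sequence[float],
    event: Sequence[int],
) -> tuple[float, float]:
    """Concordance index of a risk predictor against censored survival.

    Pair rules: a pair is usable iff the patient with the strictly shorter
    time had the event, or the times are equal and exactly one had the
    event (the death counts as the shorter follow-up).  Equal times with
    two events, or a censoring that precedes the other's event, are
    unusable.  Predictor ties contribute 1/2.  Returns (C, 2C − 1).
    """
    x = np.asarray(predictor, dtype=float)
    t = np.asarray(survival_days, dtype=float)
    e = np.asarray(event, dtype=int)
    n = len(x)
    num = 0.0
    den = 0
    for i in range(n):
        if e[i] != 1:
            continue
        # j with t[j] > t[i]: i is the shorter-lived; j censored-equal also usable
        later = t > t[i]
        tied_cens = (t == t[i]) & (e == 0)
        usable = later | tied_cens
        usable[i] = False
        k = int(usable.sum())
        if k == 0:
            continue
        den += k
        num += float((x[i] > x[usable]).sum()) + 0.5 * float((x[i] == x[usable]).sum())
    if den == 0:
        raise EstimationError("no usable pairs for the concordance index")
    c = num / den
    return float(c), float(2.0 * c - 1.0)


def somers_d_from_c(c: float) -> float:
    return 2.0 * c - 1.0


# --- Kaplan–Meier / log-rank --------------------------------------------

@dataclass
class KMGroupSummary:
    group: str
    n: int
    n_events: int
    survival_at: dict = field(default_factory=dict)


@dataclass
class KMReport:
    groups: list[KMGroupSummary]
    logrank_statistic: float
    logrank_df: int
    logrank_p: float


def km_logrank(
    groups: Sequence,
    survival_days: Sequence[float],
    event: Sequence[int],
    horizons: Sequence[float] = (28.0, 90.0),
) -> KMReport:
    """Product-limit survival per group at the given horizons + log-rank test."""
    groups = np.asarray(groups)
    t = np.asarray(survival_days, dtype=float)
    e = np.asarray(event, dtype=int)
    labels = [g for g in np.unique(groups) if np.any(groups == g)]
    if len(labels) < 1:
        raise EstimationError("at least one non-empty group required")
    summaries = []
    for g in labels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        surv = {
            float(h): float(kmf.predict(h)) for h in horizons
        }
        summaries.append(
            KMGroupSummary(group=str(g), n=int(mask.sum()), n_events=int(e[mask].sum()), survival_at=surv)
        )
    if len(labels) >= 2:
        res = multivariate_logrank_test(t, groups, e)
        stat, df, p = float(res.test_statistic), len(labels) - 1, float(res.p_value)
    else:
        stat, df, p = 0.0, 0, 1.0
    return KMReport(groups=summaries, logrank_statistic=stat, logrank_df=df, logrank_p=p)


# --- contingency ---------------------------------------------------------

def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson's chi-square (no continuity correction) on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


# --- report container ----------------------------------------------------

@dataclass
class EvalReport:
    """ROC summary of one score against a binary 90-day outcome."""

    score_name: str
    auc: float
    auc_se: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    comparisons: list = field(default_factory=list)  # (other_score, z, p)


def evaluate_score(score_name: str, scores, outcomes) -> EvalReport:
    auc, se = roc_auc(scores, outcomes)
    cut = youden_cutoff(scores, outcomes)
    return EvalReport(
        score_name=score_name,
        auc=auc,
        auc_se=se,
        cutoff=cut.cutoff,
        sensitivity=cut.sensitivity,
        specificity=cut.specificity,
        accuracy=cut.accuracy,
        lr_pos=cut.lr_pos,
        lr_neg=cut.lr_neg,
    )


def compare_scores(score_table: dict, outcomes, reference: str) -> list[EvalReport]:
    """Evaluate several scores on the same cases; DeLong-compare each to
    ``reference``.  ``score_table`` maps score name -> score vector."""
    reports = []
    ref_scores = score_table[reference]
    for name, vals in score_table.items():
        rep = evaluate_score(name, vals, outcomes)
        if name != reference:
            z, p = delong_test(ref_scores, vals, outcomes)
            rep.comparisons.append((reference, z, p))
        reports.append(rep)
    return reports


__all__ = [
    "CutoffReport",
    "EstimationError",
    "EvalReport",
    "KMGroupSummary",
    "KMReport",
    "compare_scores",
    "delong_test",
    "evaluate_score",
    "harrell_c",
    "km_logrank",
    "pearson_chi2",
    "roc_auc",
    "somers_d_from_c",
    "youden_cutoff",
]
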