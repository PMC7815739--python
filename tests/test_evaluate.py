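"""Evaluation statistics against brute-force oracles and hand computations."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dpaclf.evaluate import (
    EstimationError,
    delong_test,
    harrell_c,
    km_logrank,
    pearson_chi2,
    roc_auc,
    youden_cutoff,
)


# --- independent oracles (exhaustive enumeration / direct summation) -----

def auc_by_pair_count(scores, outcomes):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(outcomes) == 1]
    neg = scores[np.asarray(outcomes) == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def concordance_by_pair_enumeration(x, t, e):
    x, t, e = map(np.asarray, (x, t, e))
    num = den = 0.0
    for i, j in itertools.combinations(range(len(x)), 2):
        ti, tj, ei, ej = t[i], t[j], e[i], e[j]
        if ti == tj:
            if ei + ej != 1:
                continue  # both events or both censored at same time: unusable
            short, long_ = (i, j) if ei == 1 else (j, i)
        elif ti < tj:
            if ei != 1:
                continue
            short, long_ = i, j
        else:
            if ej != 1:
                continue
            short, long_ = j, i
        den += 1
        if x[short] > x[long_]:
            num += 1
        elif x[short] == x[long_]:
            num += 0.5
    return num / den


def chi2_by_direct_summation(table):
    obs = np.asarray(table, float)
    row = obs.sum(1, keepdims=True)
    col = obs.sum(0, keepdims=True)
    exp = row @ col / obs.sum()
    return ((obs - exp) ** 2 / exp).sum()


def youden_by_exhaustive_search(scores, outcomes):
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes)
    best = (-np.inf, None)
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (outcomes == 1)).sum() / (outcomes == 1).sum()
        spec = (~pred & (outcomes == 0)).sum() / (outcomes == 0).sum()
        if sens + spec - 1 > best[0] + 1e-12:
            best = (sens + spec - 1, (sens, spec))
    return best


# --- roc_auc -------------------------------------------------------------

class TestRocAuc:
    def test_perfect_and_antiperfect(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[0] == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])[0] == 0.0

    def test_pair_count_example(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1])[0] == pytest.approx(0.75)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 16)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], n)  # ties likely
            assert roc_auc(s, y)[0] == pytest.approx(auc_by_pair_count(s, y))

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(np.exp(3 * s), y)
        assert a1 == pytest.approx(a2)

    def test_complement_identity_for_tie_free_scores(self, rng):
        s = rng.normal(size=25)
        y = np.r_[np.ones(10, int), np.zeros(15, int)]
        assert roc_auc(s, y)[0] + roc_auc(-s, y)[0] == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(EstimationError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_z_zero(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        z, p = delong_test(s, s, y)
        assert (z, p) == (0.0, 1.0)

    def test_antisymmetry(self, rng):
        y = np.r_[np.ones(12, int), np.zeros(18, int)]
        a, b = rng.normal(size=30) + y, rng.normal(size=30)
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_se_matches_roc_auc_variance(self, rng):
        # var of difference vs independent scores ~ sum of variances
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        a = rng.normal(size=100) + 0.8 * y
        z, p = delong_test(a, a + 1.0, y)  # shifted copy: identical ranks
        assert z == 0.0 and p == 1.0


class TestYouden:
    def test_separated_classes_midpoint(self):
        rep = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert rep.cutoff == pytest.approx(0.5)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_degenerate_constant_scores(self):
        rep = youden_cutoff([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            n = rng.integers(6, 16)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)
            rep = youden_cutoff(s, y)
            best_j, _ = youden_by_exhaustive_search(s, y)
            assert rep.sensitivity + rep.specificity - 1 == pytest.approx(best_j)

    def test_likelihood_ratios(self):
        rep = youden_cutoff([1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1])
        assert rep.lr_pos == pytest.approx(rep.sensitivity / (1 - rep.specificity))
        assert rep.lr_neg == pytest.approx((1 - rep.sensitivity) / rep.specificity)


class TestHarrellC:
    def test_monotone_and_antimonotone(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == (1.0, 1.0)
        assert harrell_c([1, 2, 3], [1, 2, 3], [1, 1, 1]) == (0.0, -1.0)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 16))
            x = rng.choice([1.0, 2.0, 3.0], n)
            t = rng.integers(1, 8, n).astype(float)  # ties in time likely
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            try:
                c, d = harrell_c(x, t, e)
            except EstimationError:
                continue
            assert c == pytest.approx(concordance_by_pair_enumeration(x, t, e))
            assert d == pytest.approx(2 * c - 1)

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        from lifelines.utils import concordance_index

        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(30, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        c, _ = harrell_c(x, t, e)
        # lifelines concordance is for a *survival-time* predictor, so flip sign
        assert c == pytest.approx(1.0 - concordance_index(t, x, e))

    def test_no_usable_pairs_errors(self):
        with pytest.raises(EstimationError):
            harrell_c([1, 2], [5, 5], [1, 1])


class TestKaplanMeier:
    def test_no_event_single_group(self):
        rep = km_logrank(["a"] * 4, [10, 20, 30, 90], [0, 0, 0, 0], horizons=(28, 90))
        assert rep.groups[0].survival_at[28.0] == 1.0
        assert rep.groups[0].survival_at[90.0] == 1.0

    def test_identical_groups_logrank_zero(self):
        t = [5, 10, 20, 40, 90] * 2
        e = [1, 1, 0, 1, 0] * 2
        g = ["a"] * 5 + ["b"] * 5
        rep = km_logrank(g, t, e)
        assert rep.logrank_statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_product_limit(self):
        # events at 2 and 5; censoring at 3, 7, 9
        rep = km_logrank(["g"] * 5, [2, 3, 5, 7, 9], [1, 0, 1, 0, 0], horizons=(2, 5, 9))
        s = rep.groups[0].survival_at
        assert s[2.0] == pytest.approx(0.8)
        assert s[5.0] == pytest.approx(0.8 * 2 / 3)
        assert s[9.0] == pytest.approx(0.8 * 2 / 3)

    def test_survival_bounded_and_nonincreasing(self):
        rep = km_logrank(["g"] * 6, [1, 4, 9, 30, 60, 90], [1, 1, 0, 1, 0, 0],
                         horizons=(1, 10, 50, 90))
        vals = [rep.groups[0].survival_at[h] for h in (1.0, 10.0, 50.0, 90.0)]
        assert all(0 <= v <= 1 for v in vals)
        assert vals == sorted(vals, reverse=True)


class TestPearsonChi2:
    def test_etiology_by_outcome_contingency(self):
        """Decompensated-cirrhosis stratum: alcohol vs HBV vs mixed etiology."""
        stat, df, p = pearson_chi2([[33, 10], [66, 66], [13, 13]])
        assert stat == pytest.approx(9.799, abs=5e-4)
        assert df == 2
        assert p == pytest.approx(0.007, abs=5e-4)

    def test_identical_rows_give_zero(self):
        stat, _, p = pearson_chi2([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0)

    def test_matches_direct_summation(self, rng):
        for _ in range(50):
            table = rng.integers(1, 30, size=(3, 2))
            stat, df, _ = pearson_chi2(table)
            assert stat == pytest.approx(chi2_by_direct_summation(table))
            assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [1, 2]])
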