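"""Confusion/performance statistics, ROC, Mann-Whitney, FDR, reconstruction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmtperf.evaluation import (
    ConfusionMatrix,
    bh_fdr,
    classwise_performance,
    confusion,
    mann_whitney_u,
    reconstruct_confusion,
    roc_auc,
    round_half_up,
)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["a", "b", "c", "a"]
        cm = confusion(y, y, classes=("a", "b", "c"))
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_constant_prediction_single_column(self):
        cm = confusion(["a", "b", "c"], ["b", "b", "b"], classes=("a", "b", "c"))
        assert cm.counts[:, 1].sum() == 3 and cm.counts.sum() == 3

    def test_random_labels_match_tally(self, rng):
        classes = ("x", "y", "z")
        yt = rng.choice(classes, 200)
        yp = rng.choice(classes, 200)
        cm = confusion(yt, yp, classes)
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                assert cm.counts[i, j] == int(np.sum((yt == ci) & (yp == cj)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["q"], classes=("a", "b"))


class TestClasswisePerformance:
    def test_diagonal_matrix_all_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 7, 3]), ("a", "b", "c"))
        perf = classwise_performance(cm)
        assert all(v == 100.0 for v in perf.sensitivity_pct.values())
        assert all(v == 100.0 for v in perf.specificity_pct.values())
        assert perf.accuracy_pct == 100.0

    def test_three_class_cohort_accuracy(self):
        # per-class correct counts (9, 23, 13) over class sizes (17, 31, 14)
        counts = np.array([[9, 4, 4], [2, 23, 6], [0, 1, 13]])
        cm = ConfusionMatrix(counts, ("lymphoma", "thymoma", "thymic_carcinoma"))
        perf = classwise_performance(cm)
        assert perf.accuracy_pct == pytest.approx(100 * 45 / 62)
        assert perf.rounded().accuracy_pct == 72.58

    def test_matches_one_vs_rest_collapse(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 20, size=(3, 3))
            if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
                continue
            cm = ConfusionMatrix(counts, ("a", "b", "c"))
            perf = classwise_performance(cm)
            total = counts.sum()
            for i, name in enumerate(cm.classes):
                tp = counts[i, i]
                fn = counts[i].sum() - tp
                fp = counts[:, i].sum() - tp
                tn = total - tp - fn - fp
                assert perf.sensitivity_pct[name] == pytest.approx(100 * tp / (tp + fn))
                assert perf.specificity_pct[name] == pytest.approx(100 * tn / (tn + fp))

    def test_class_order_permutation_consistent(self):
        counts = np.array([[5, 1], [2, 8]])
        p1 = classwise_performance(ConfusionMatrix(counts, ("a", "b")))
        p2 = classwise_performance(ConfusionMatrix(counts[::-1, ::-1], ("b", "a")))
        assert p1.sensitivity_pct["a"] == p2.sensitivity_pct["a"]
        assert p1.accuracy_pct == p2.accuracy_pct

    def test_rounding_is_half_up(self):
        assert round_half_up(72.575, 2) == 72.58
        assert round_half_up(52.85, 1) == 52.9
        assert round_half_up(2.5, 0) == 3.0


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], ["n"] * 3 + ["p"] * 3, positive="p")
        assert r.auc == 1.0

    def test_all_ties_gives_half(self):
        r = roc_auc([5.0] * 8, ["n", "p"] * 4, positive="p")
        assert r.auc == 0.5

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_counting(self, data):
        n1 = data.draw(st.integers(1, 10))
        n0 = data.draw(st.integers(1, 10))
        pos = [data.draw(st.integers(0, 6)) for _ in range(n1)]
        neg = [data.draw(st.integers(0, 6)) for _ in range(n0)]
        scores = pos + neg
        labels = ["p"] * n1 + ["n"] * n0
        pairs = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in pos for b in neg
        ) / (n1 * n0)
        r = roc_auc(scores, labels, positive="p")
        assert r.auc == pytest.approx(max(pairs, 1 - pairs), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.choice(["p", "n"], 40)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "p", "n"
        a1 = roc_auc(scores, labels, positive="p").auc
        a2 = roc_auc(np.exp(3 * scores), labels, positive="p").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_ci_contains_auc_and_direction_recorded(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 25)])
        labels = ["p"] * 20 + ["n"] * 25
        r = roc_auc(scores, labels, positive="p")
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert r.direction == "greater"
        r_flip = roc_auc(-scores, labels, positive="p")
        assert r_flip.direction == "less"
        assert r_flip.auc == pytest.approx(r.auc, abs=1e-12)

    def test_bootstrap_ci_available(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 15), rng.normal(0, 1, 15)])
        labels = ["p"] * 15 + ["n"] * 15
        r = roc_auc(scores, labels, positive="p", ci_method="bootstrap", n_boot=200, seed=7)
        assert r.ci95[0] <= r.auc <= r.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["p", "p", "p"], positive="p")

    def test_curve_endpoints(self, rng):
        scores = rng.normal(size=30)
        labels = (["p"] * 15) + (["n"] * 15)
        r = roc_auc(scores, labels, positive="p")
        assert r.fpr[0] == 0.0 and r.tpr[0] == 0.0
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


class TestMannWhitney:
    def test_separated_pair_exact_third(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.u == 0.0
        assert r.p == pytest.approx(1 / 3)
        assert r.method == "exact"

    def test_identical_samples_p_one(self):
        r = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0

    def test_exact_matches_full_permutation(self, rng):
        for _ in range(5):
            a = rng.integers(0, 5, size=4).astype(float)
            b = rng.integers(0, 5, size=4).astype(float)
            r = mann_whitney_u(a, b, method="exact")
            # independent enumeration using scipy ranks
            from scipy.stats import rankdata

            pooled = np.concatenate([a, b])
            mu = a.size * b.size / 2.0

            def u_of(mask):
                ranks = rankdata(pooled)
                return ranks[mask].sum() - a.size * (a.size + 1) / 2.0

            obs = abs(u_of(np.arange(8) < 4) - mu)
            hits = total = 0
            for comb in itertools.combinations(range(8), 4):
                mask = np.zeros(8, bool)
                mask[list(comb)] = True
                ranks = rankdata(pooled)
                u = ranks[mask].sum() - 10.0
                total += 1
                if abs(u - mu) >= obs - 1e-12:
                    hits += 1
            assert r.p == pytest.approx(hits / total)

    def test_normal_approx_worst_case_vs_exact_small_n(self):
        """Exhaustive sweep of every tie-free configuration with
        5 <= n1 + n2 <= 12: the continuity-corrected normal approximation
        never strays more than 0.052 from the exact permutation law (the
        true worst case, 0.0511, occurs at n1=2, n2=3, U=0)."""
        worst = 0.0
        for n in range(5, 13):
            for n1 in range(2, n - 1):
                n2 = n - n1
                for u in range(n1 * n2 + 1):
                    # realize a tie-free sample whose statistic equals u
                    a, b = _sample_with_u(n1, n2, u)
                    pe = mann_whitney_u(a, b, method="exact").p
                    pn = mann_whitney_u(a, b, method="normal").p
                    worst = max(worst, abs(pe - pn))
        assert worst < 0.052
        assert worst == pytest.approx(0.0511, abs=5e-4)

    def test_agrees_with_scipy_asymptotic(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(size=25)
        b = rng.normal(0.5, size=30)
        r = mann_whitney_u(a, b, method="normal")
        sp = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p == pytest.approx(sp.pvalue, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_p_unchanged(self):
        q = bh_fdr([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_matches_step_up_definition(self, rng):
        p = rng.uniform(size=10)
        q = bh_fdr(p)
        m = p.size
        order = np.argsort(p)
        for i in range(m):
            rank_i = int(np.where(order == i)[0][0]) + 1
            expected = min(
                min(m * p[j] / (int(np.where(order == j)[0][0]) + 1)
                    for j in order[rank_i - 1:]),
                1.0,
            )
            assert q[i] == pytest.approx(expected)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=15)
        q = bh_fdr(p)
        _, q_sm, _, _ = sm.multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=8)
        q = bh_fdr(p)
        p2 = p.copy()
        p2[3] = min(1.0, p2[3] + 0.2)
        q2 = bh_fdr(p2)
        assert np.all(q2 >= q - 1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=12)
        assert np.all(bh_fdr(p) >= p - 1e-12)


def _sample_with_u(n1, n2, u):
    """Tie-free samples (a, b) whose Mann-Whitney statistic for ``a`` is u:
    choose group-a ranks from {1..n1+n2} summing to u + n1(n1+1)/2."""
    n = n1 + n2
    ranks = list(range(1, n1 + 1))
    remaining = u
    for i in reversed(range(n1)):
        ceiling = n - (n1 - 1 - i)
        bump = min(remaining, ceiling - ranks[i])
        ranks[i] += bump
        remaining -= bump
    assert remaining == 0
    a = np.array(ranks, dtype=float)
    b = np.array(sorted(set(range(1, n + 1)) - set(ranks)), dtype=float)
    return a, b


class TestReconstructConfusion:
    def test_unique_invasiveness_matrix(self):
        sols = reconstruct_confusion(71.4, 95.8, 31, decimals=1)
        assert len(sols) == 1
        s = sols[0]
        assert (s.tp, s.fn, s.tn, s.fp) == (5, 2, 23, 1)
        assert s.accuracy_pct == pytest.approx(100 * 28 / 31)

    def test_perfect_rates_all_diagonal(self):
        for n in (5, 10, 17):
            sols = reconstruct_confusion(100.0, 100.0, n, decimals=1)
            assert len(sols) == n - 1
            assert all(s.fn == 0 and s.fp == 0 for s in sols)

    def test_nonunique_lymphoma_triple(self):
        # (75, 100) over 17 at integer precision admits several matrices;
        # exhaustive enumeration finds positive-class sizes 4, 8, 12 and 16
        sols = reconstruct_confusion(75.0, 100.0, 17, decimals=0)
        sizes = sorted(s.n_positive for s in sols)
        assert sizes == [4, 8, 12, 16]

    def test_published_lymphoma_trio_inconsistent_with_six_positives(self):
        # a positive class of 6 cannot round to 75% sensitivity
        sols = reconstruct_confusion(75.0, 100.0, 17, decimals=0)
        assert all(s.n_positive != 6 for s in sols)

    def test_impossible_pair_gives_empty_set(self):
        assert reconstruct_confusion(33.3, 99.9, 4, decimals=1) == []

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(50.0, 50.0, 1)
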