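import numpy as np
import pytest

from mixedclr import GoldStandard, RankedEdgeList, causality_fraction, error_vs_degree, pr_curve, roc_curve
from mixedclr.evaluation import degree_error_correlation


def ranked_from_pairs(n, ordered_pairs):
    scores = np.linspace(1.0, 0.1, len(ordered_pairs))
    return RankedEdgeList(
        n_genes=n, edges=[(j, i, s) for (j, i), s in zip(ordered_pairs, scores)]
    )


def all_pairs(n):
    return [(j, i) for j in range(n) for i in range(n) if i != j]


def prefix_counting_oracle(ranked, gold):
    """O(K^2) recomputation of precision/recall/AUPR and ROC from raw counts."""
    precision, recall, tpr, fpr = [], [], [], []
    n_pos = gold.n_edges
    n_neg = len(ranked.edges) - n_pos
    for k in range(1, len(ranked.edges) + 1):
        prefix = ranked.edges[:k]
        tp = sum((j, i) in gold.edges for j, i, _ in prefix)
        precision.append(tp / k)
        recall.append(tp / n_pos)
        tpr.append(tp / n_pos)
        fpr.append((k - tp) / n_neg)
    aupr = 0.0
    prev_recall = 0.0
    for p, r in zip(precision, recall):
        if r > prev_recall:
            aupr += (r - prev_recall) * p
            prev_recall = r
    auroc = np.trapezoid([0.0] + tpr, [0.0] + fpr)
    return np.array(precision), np.array(recall), aupr, auroc


class TestPRCurve:
    def test_perfect_ranking_has_unit_aupr(self):
        pairs = all_pairs(3)
        gold = GoldStandard(3, frozenset(pairs[:2]))
        result = pr_curve(ranked_from_pairs(3, pairs), gold)
        assert result.aupr == pytest.approx(1.0)

    def test_single_top_ranked_tp(self):
        pairs = all_pairs(3)
        gold = GoldStandard(3, frozenset(pairs[:1]))
        result = pr_curve(ranked_from_pairs(3, pairs), gold, recall_points=(1.0,))
        assert result.precision_at_recall[1.0] == pytest.approx(1.0)

    def test_interleaved_fixture_matches_counting_oracle(self, rng):
        n = 4
        pairs = all_pairs(n)
        rng.shuffle(pairs)
        gold = GoldStandard(n, frozenset(tuple(p) for p in pairs[::3]))
        ranked = ranked_from_pairs(n, pairs)
        precision, recall, aupr, _ = prefix_counting_oracle(ranked, gold)
        result = pr_curve(ranked, gold)
        np.testing.assert_allclose(result.precision, precision)
        np.testing.assert_allclose(result.recall, recall)
        assert result.aupr == pytest.approx(aupr, abs=1e-12)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(ranked_from_pairs(3, all_pairs(3)), GoldStandard(3, frozenset()))


class TestROCCurve:
    def test_perfect_and_reversed_rankings(self):
        pairs = all_pairs(3)
        gold = GoldStandard(3, frozenset(pairs[:2]))
        assert roc_curve(ranked_from_pairs(3, pairs), gold).auroc == pytest.approx(1.0)
        reversed_gold = GoldStandard(3, frozenset(pairs[-2:]))
        assert roc_curve(ranked_from_pairs(3, pairs), reversed_gold).auroc == pytest.approx(0.0)

    def test_matches_counting_oracle(self, rng):
        n = 5
        pairs = all_pairs(n)
        rng.shuffle(pairs)
        gold = GoldStandard(n, frozenset(tuple(p) for p in pairs[::4]))
        ranked = ranked_from_pairs(n, pairs)
        _, _, _, auroc = prefix_counting_oracle(ranked, gold)
        assert roc_curve(ranked, gold).auroc == pytest.approx(auroc, abs=1e-12)

    def test_random_ranking_near_half(self, rng):
        n = 15
        pairs = all_pairs(n)
        gold = GoldStandard(n, frozenset(tuple(p) for p in pairs[:: 7]))
        n_pos = gold.n_edges
        n_neg = len(pairs) - n_pos
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        rng.shuffle(pairs)
        auroc = roc_curve(ranked_from_pairs(n, pairs), gold).auroc
        assert abs(auroc - 0.5) < 3 * se


class TestCausality:
    def test_antisymmetric_scores_fully_resolved(self):
        scores = np.array([[0.0, 0.1], [0.9, 0.0]])
        gold = GoldStandard(2, frozenset({(0, 1)}))  # G1 -> G2, stored at [1, 0]
        result = causality_fraction(scores, gold)
        assert result.fraction == 1.0 and result.n_identified == 1

    def test_symmetric_scores_resolve_nothing(self):
        scores = np.full((3, 3), 0.5)
        gold = GoldStandard(3, frozenset({(0, 1), (1, 2)}))
        result = causality_fraction(scores, gold)
        assert result.fraction == 0.0
        assert result.n_identified == 2 and result.n_correct == 0

    def test_counts_three_of_four_resolved(self):
        n = 4
        scores = np.zeros((n, n))
        gold_edges = {(0, 1), (1, 2), (2, 3), (3, 0)}
        for j, i in gold_edges:
            scores[i, j] = 0.8
            scores[j, i] = 0.2
        scores[3, 0] = 0.9  # the reversal of (3, 0) outranks the true edge
        result = causality_fraction(scores, GoldStandard(n, frozenset(gold_edges)))
        assert result.n_identified == 4
        assert result.fraction == pytest.approx(0.75)

    def test_unidentified_edges_excluded_from_denominator(self):
        scores = np.zeros((2, 2))
        gold = GoldStandard(2, frozenset({(0, 1)}))
        result = causality_fraction(scores, gold)
        assert result.n_identified == 0 and result.fraction == 0.0


class TestErrorVsDegree:
    def test_relative_rank_of_extremes(self):
        n = 10
        pairs = all_pairs(n)
        gold = GoldStandard(n, frozenset({pairs[0], pairs[-1]}))
        ranked = ranked_from_pairs(n, pairs)
        result = error_vs_degree(ranked, gold)
        errors = sorted(result["errors"])
        assert errors[0] == pytest.approx(1 / 90)
        assert errors[-1] == pytest.approx(1.0)

    def test_grouping_matches_bruteforce(self, rng):
        n = 6
        pairs = all_pairs(n)
        rng.shuffle(pairs)
        gold_edges = frozenset(tuple(p) for p in pairs[::4])
        gold = GoldStandard(n, gold_edges)
        ranked = ranked_from_pairs(n, pairs)
        result = error_vs_degree(ranked, gold)
        total = n * (n - 1)
        rank_of = {(j, i): r + 1 for r, (j, i, _) in enumerate(ranked.edges)}
        in_deg = {g: sum(1 for _, i in gold_edges if i == g) for g in range(n)}
        for degree, errs in result["by_in_degree"].items():
            expected = sorted(
                rank_of[(j, i)] / total for j, i in gold_edges if in_deg[i] == degree
            )
            np.testing.assert_allclose(sorted(errs), expected)

    def test_ensemble_correlation_sign(self):
        fake = [
            {"median_error": 0.1, "median_in_degree": 1, "median_out_degree": 3},
            {"median_error": 0.2, "median_in_degree": 2, "median_out_degree": 2},
            {"median_error": 0.3, "median_in_degree": 3, "median_out_degree": 1},
        ]
        assert degree_error_correlation(fake, "in") == pytest.approx(1.0)
        assert degree_error_correlation(fake, "out") == pytest.approx(-1.0)
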