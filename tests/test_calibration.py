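import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddiminer import (CalibrationError, LearningSet, build_learning_set,
                      filter_matrix, precision_recall_f1, select_threshold_cv,
                      shuffle_negatives, threshold_grid)


def degree_multiset(edges):
    """Endpoint multiplicities; a self-edge contributes 2 to its node."""
    deg = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return sorted(deg.items())


class TestShuffleNegatives:
    def test_two_disjoint_edges_fully_rewired(self):
        pos = {("a", "b"), ("c", "d")}
        out = shuffle_negatives(pos, seed=5)
        assert out in ({("a", "c"), ("b", "d")}, {("a", "d"), ("b", "c")})

    def test_single_edge_is_degenerate(self):
        with pytest.raises(CalibrationError):
            shuffle_negatives({("a", "b")}, seed=0)

    def test_no_swap_possible_raises(self):
        # any rewiring of a shared-endpoint pair recreates originals or self-edges
        with pytest.raises(CalibrationError):
            shuffle_negatives({("a", "b"), ("a", "c")}, seed=0)

    def test_deterministic_given_seed(self):
        pos = {(f"x{i}", f"y{i}") for i in range(10)}
        assert shuffle_negatives(pos, seed=3) == shuffle_negatives(pos, seed=3)

    def test_degrees_preserved_and_originals_excluded(self):
        rng = np.random.default_rng(17)
        nodes = [f"n{i:02d}" for i in range(12)]
        for _ in range(50):
            edges = set()
            while len(edges) < 15:
                a, b = (nodes[i] for i in rng.choice(12, size=2, replace=False))
                edges.add((a, b) if a <= b else (b, a))
            out = shuffle_negatives(edges, seed=int(rng.integers(0, 2 ** 31)))
            assert not out & edges
            if len(out) == len(edges):  # no drops: exact degree preservation
                assert degree_multiset(out) == degree_multiset(edges)

    def test_homo_edge_degree_budget(self):
        # a self-edge counts 2 toward its node; rewiring must conserve that
        pos = {("a", "a"), ("b", "c"), ("d", "e"), ("f", "g")}
        for seed in range(20):
            out = shuffle_negatives(pos, seed=seed)
            if len(out) == len(pos):
                assert degree_multiset(out) == degree_multiset(pos)
                # no brand-new self-edges beyond the recombined budget
                new_selfs = {e for e in out if e[0] == e[1]}
                assert not new_selfs - pos


class TestBuildLearningSet:
    def test_unscored_members_dropped(self):
        pos = {("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")}
        neg = {("a", "c"), ("b", "d"), ("e", "g"), ("f", "h")}
        scores = {k: 0.5 for k in pos} | {k: 0.1 for k in list(neg)[:3]}
        ls = build_learning_set(pos, neg, scores)
        assert len(ls.positives) == 4 and len(ls.negatives) == 3

    def test_overlap_with_positives_removed(self):
        pos = {("a", "b"), ("c", "d")}
        ls = build_learning_set(pos, {("a", "b"), ("x", "y")},
                                {("a", "b"): 1.0, ("c", "d"): 1.0, ("x", "y"): 0.2})
        assert ls.negatives == {("x", "y")}

    def test_empty_shuffled_set_raises(self):
        with pytest.raises(CalibrationError):
            build_learning_set({("a", "b")}, set(), {("a", "b"): 1.0})

    def test_no_scored_positive_raises(self):
        with pytest.raises(CalibrationError):
            build_learning_set({("a", "b")}, {("x", "y")}, {("x", "y"): 0.5})


class TestPrecisionRecallF1:
    @pytest.mark.parametrize("pos,neg,t,expected", [
        ({"p1": 0.9, "p2": 0.8}, {"n1": 0.1}, 0.5, (1.0, 1.0, 1.0)),
        ({"p1": 0.9, "p2": 0.4}, {"n1": 0.6, "n2": 0.1}, 0.5, (0.5, 0.5, 0.5)),
        ({"p1": 0.9}, {"n1": 0.1}, 1.0, (0.0, 0.0, 0.0)),
    ], ids=["perfect-split", "mixed", "nothing-predicted"])
    def test_counting(self, pos, neg, t, expected):
        labels = {k: "pos" for k in pos} | {k: "neg" for k in neg}
        assert precision_recall_f1(labels, pos | neg, t) == pytest.approx(expected)


class TestThresholdGrid:
    def test_three_phase_union(self):
        grid = threshold_grid()
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert np.all(np.diff(grid) > 0)
        for t in (0.0158, 0.0159, 0.5, 0.003):
            assert np.isclose(grid, t).any()
        # 101 + 41 + 101 minus shared points
        assert len(grid) == len({round(t, 4) for t in grid})


def separable_learning_set(n, seed):
    rng = np.random.default_rng(seed)
    pos = {("A", f"p{i:03d}"): 0.6 + 0.4 * rng.random() for i in range(n // 2)}
    neg = {("B", f"n{i:03d}"): 0.2 * rng.random() for i in range(n // 2)}
    return LearningSet(positives=set(pos), negatives=set(neg), scores=pos | neg)


class TestSelectThresholdCv:
    def test_separable_recovers_gap_threshold(self):
        ls = separable_learning_set(300, seed=0)
        res = select_threshold_cv(ls, seed=42)
        assert 0.2 <= res.t_m < 0.6
        assert res.f1_test == 1.0 and res.f1_train == 1.0
        assert res.t_m == pytest.approx(np.mean(res.fold_thresholds))

    def test_deterministic_and_order_invariant(self):
        ls = separable_learning_set(100, seed=1)
        r1 = select_threshold_cv(ls, seed=7)
        shuffled = LearningSet(positives=set(ls.positives), negatives=set(ls.negatives),
                               scores=dict(reversed(list(ls.scores.items()))))
        r2 = select_threshold_cv(shuffled, seed=7)
        assert r1 == r2

    def test_too_small_learning_set_raises(self):
        ls = separable_learning_set(8, seed=0)
        with pytest.raises(CalibrationError):
            select_threshold_cv(ls, k=5)

    def test_random_labels_f1_near_class_balance(self):
        # with score-independent labels, F1 at a low threshold -> 2p/(1+p)
        rng = np.random.default_rng(0)
        keys = [("K", f"{i:04d}") for i in range(3000)]
        scores = {k: rng.random() for k in keys}
        is_pos = rng.random(len(keys)) < 0.5
        pos = {k for k, f in zip(keys, is_pos) if f}
        ls = LearningSet(positives=pos, negatives=set(keys) - pos, scores=scores)
        res = select_threshold_cv(ls, seed=1)
        assert res.f1_test == pytest.approx(2 * 0.5 / 1.5, abs=0.07)


class TestFilterMatrix:
    def test_strict_inequality(self):
        scores = {("a", "b"): 0.5, ("c", "d"): 0.0158}
        assert filter_matrix(scores, 0.01586) == {("a", "b"): 0.5}

    def test_exact_threshold_removed(self):
        assert filter_matrix({("a", "b"): 0.3}, 0.3) == {}

    def test_zero_threshold_keeps_positive_scores(self):
        scores = {("a", "b"): 0.5, ("c", "d"): 1e-9}
        assert filter_matrix(scores, 0.0) == scores
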