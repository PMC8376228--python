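import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddiminer import (ValidationError, bonferroni_flags, build_source_graph,
                      cosine_score, hypergeom_pvalue, score_source)
from ddiminer.scoring import CandidateMatrix, SourceScore


def enumerate_tail_probability(k_xy, n_x, n_y, n_z):
    """Independent oracle: exhaustive enumeration over all C(n_z, n_y) draws."""
    hits = total = 0
    population = range(n_z)
    marked = set(range(n_x))
    for draw in itertools.combinations(population, n_y):
        total += 1
        if len(marked.intersection(draw)) >= k_xy:
            hits += 1
    return hits / total


class TestCosineScore:
    def test_identical_rows(self):
        assert cosine_score([1, 1, 0], [1, 1, 0]) == pytest.approx(1.0)

    def test_orthogonal_rows(self):
        assert cosine_score([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_toy_d3_vs_d2(self):
        # the inferred (d3, d2) edge must score below the structural (d1, d2) edge
        s = cosine_score([1, 1, 1], [1, 1, 0])
        assert s == pytest.approx(2 / math.sqrt(6), abs=1e-12)
        assert s < 1.0

    def test_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            cosine_score([0, 0], [1, 0])


class TestHypergeomPvalue:
    def test_zero_common_neighbors_certain(self):
        assert hypergeom_pvalue(0, 3, 4, 10) == pytest.approx(1.0)

    def test_known_tail_values(self):
        assert hypergeom_pvalue(2, 3, 4, 10) == pytest.approx(1 / 3, abs=1e-12)
        assert hypergeom_pvalue(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_pvalue(3, 2, 5, 6)
        with pytest.raises(ValidationError):
            hypergeom_pvalue(1, 7, 2, 6)

    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        n_z = data.draw(st.integers(1, 10))
        n_x = data.draw(st.integers(1, n_z))
        n_y = data.draw(st.integers(1, n_z))
        k = data.draw(st.integers(0, min(n_x, n_y)))
        expected = enumerate_tail_probability(k, n_x, n_y, n_z)
        assert hypergeom_pvalue(k, n_x, n_y, n_z) == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_in_k(self):
        for n_x, n_y, n_z in [(3, 4, 10), (5, 5, 12), (2, 7, 9)]:
            tail = [hypergeom_pvalue(k, n_x, n_y, n_z)
                    for k in range(min(n_x, n_y) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(tail, tail[1:]))


class TestScoreSource:
    def test_toy_candidate_set(self, toy_graph):
        m = score_source(toy_graph)
        c = 2 / math.sqrt(6)
        expected = {("d1", "d2"): 1.0, ("d2", "d3"): c, ("d3", "d4"): c,
                    ("d1", "d4"): 0.5}
        assert set(m.scores) == set(expected)
        for key, cos in expected.items():
            assert m.scores[key].cosine == pytest.approx(cos, abs=1e-12)

    def test_toy_counts_and_pvalues(self, toy_graph):
        m = score_source(toy_graph)
        s = m.scores[("d2", "d3")]
        assert (s.k_xy, s.n_x, s.n_y, s.n_z) == (2, 3, 2, 3)
        assert s.p_value == pytest.approx(
            enumerate_tail_probability(2, 3, 2, 3), abs=1e-12)
        assert s.significant is None

    def test_cosine_consistent_with_counts(self, toy_graph):
        for s in score_source(toy_graph).scores.values():
            assert s.cosine == pytest.approx(s.k_xy / math.sqrt(s.n_x * s.n_y),
                                             abs=1e-12)
            assert s.k_xy <= min(s.n_x, s.n_y) <= s.n_z

    def test_single_ppi_source(self):
        g = build_source_graph("s", [("A", "B")], {"A": {"PF1"}, "B": {"PF2"}})
        m = score_source(g)
        s = m.scores[("PF1", "PF2")]
        assert (s.cosine, s.k_xy, s.n_x, s.n_y, s.n_z) == (1.0, 1, 1, 1, 1)

    def test_homo_pair_candidate(self):
        g = build_source_graph("s", [("A", "B")], {"A": {"PF1"}, "B": {"PF1"}})
        m = score_source(g)
        assert m.scores[("PF1", "PF1")].cosine == pytest.approx(1.0)

    def test_orientation_keeps_larger_cosine(self):
        # dX occurs on both sides with different neighborhood sizes
        ann = {"A1": {"dX"}, "A2": {"dX"}, "B1": {"dY"}, "B2": {"dY"}, "B3": {"dX"}}
        pairs = [("A1", "B1"), ("A2", "B2"), ("A2", "B3")]
        m = score_source(build_source_graph("s", pairs, ann))
        s = m.scores[("dX", "dY")]
        # orientation dX-left (n=3) vs dY-right (n=2): k=2 -> 2/sqrt(6)
        # orientation dY-left impossible (dY never on the left)
        assert s.cosine == pytest.approx(2 / math.sqrt(6), abs=1e-12)


class TestBonferroniFlags:
    def _matrix(self, name, pvals):
        scores = {(f"PF{i}", f"PF{i + 1}"): SourceScore(0.5, 1, 1, 1, 10, p)
                  for i, p in enumerate(pvals)}
        return CandidateMatrix(source=name, scores=scores)

    def test_single_matrix_threshold(self):
        m = self._matrix("a", [0.01, 0.01, 0.01, 0.01])
        n = bonferroni_flags([m], alpha=0.05)
        assert n == 4  # threshold 0.0125
        assert all(s.significant for s in m.scores.values())

    def test_boundary_is_strict(self):
        m = self._matrix("a", [0.0125, 0.0124, 0.9, 0.5])
        bonferroni_flags([m], alpha=0.05)
        flags = [m.scores[(f"PF{i}", f"PF{i + 1}")].significant for i in range(4)]
        assert flags == [False, True, False, False]

    def test_family_is_union_across_sources(self):
        m1 = self._matrix("a", [0.02, 0.02])
        m2 = self._matrix("b", [0.02, 0.02, 0.02])  # keys overlap m1 on 2 pairs
        n = bonferroni_flags([m1, m2], alpha=0.05)
        assert n == 3  # merged candidate union, not the sum of sizes
        assert all(not s.significant for s in m1.scores.values())

    def test_empty_union_warns(self, caplog):
        m = CandidateMatrix(source="a", scores={})
        with caplog.at_level("WARNING"):
            assert bonferroni_flags([m]) == 0


@given(st.randoms(use_true_random=False))
def test_cosine_from_counts_matches_raw_rows(rnd):
    """Oracle equivalence: cosine via (k, n_x, n_y) vs via the raw vectors."""
    n = rnd.randint(2, 12)
    x = [rnd.randint(0, 1) for _ in range(n)]
    y = [rnd.randint(0, 1) for _ in range(n)]
    if sum(x) == 0 or sum(y) == 0:
        return
    k = sum(a & b for a, b in zip(x, y))
    from_counts = k / math.sqrt(sum(x) * sum(y))
    assert cosine_score(np.array(x), np.array(y)) == pytest.approx(from_counts,
                                                                   abs=1e-12)
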