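"""Evaluation of DDI sets against interactomes and against each other.

*Coverage*: a PPI (L, R) — both proteins carrying at least one domain — is
covered by a DDI set when some cross pair {dA in domains(L), dB in
domains(R)} is in the set; a *useful* DDI covers at least one PPI.
*Overlap*: three-way Venn region counts between DDI sets.
*Network statistics*: connected components, giant-component share, degree
distribution, the 99th-percentile degree and homo-DDI counts of a DDI graph.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field

import networkx as nx

from .core import DDIKey, OrderedPPI, canonical_ddi
from .errors import EvaluationError


@dataclass
class CoverageReport:
    n_ppis_total: int
    n_ppis_covered: int
    n_useful_ddis: int
    per_ddi_cover_counts: dict[DDIKey, int] = field(repr=False)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_ccs: int
    giant_cc_size: int
    pct_nodes_in_giant: float
    n_1node_ccs: int
    n_2node_ccs: int
    degree_histogram: dict[int, int]
    pct_degree_gt3: float
    degree_sup_99: int
    degree_max: int
    argmax_node: str
    n_homo_ddis: int


def coverage(ppis: Sequence[OrderedPPI], annotations: Mapping[str, Set[str]],
             ddis: Set[DDIKey]) -> CoverageReport:
    """Count PPIs explained by the DDI set and the DDIs doing the explaining.

    PPIs with an unannotated protein on either side are excluded from the
    total.  Only inter-protein domain pairs (left x right cross product) can
    mediate a binary PPI; a homo-DDI therefore requires its domain on both
    sides.  A covered PPI increments the count of every DDI covering it.
    """
    counts: dict[DDIKey, int] = {}
    n_total = 0
    n_covered = 0
    for left, right in ppis:
        dl = annotations.get(left)
        dr = annotations.get(right)
        if not dl or not dr:
            continue
        n_total += 1
        hits = {canonical_ddi(a, b) for a in dl for b in dr} & ddis
        if hits:
            n_covered += 1
            for key in hits:
                counts[key] = counts.get(key, 0) + 1
    return CoverageReport(n_ppis_total=n_total, n_ppis_covered=n_covered,
                          n_useful_ddis=len(counts), per_ddi_cover_counts=counts)


def overlap3(a: Set[DDIKey], b: Set[DDIKey], c: Set[DDIKey]) -> dict[str, int]:
    """Counts of the 7 Venn regions of three DDI sets (canonical keys)."""
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
    }


def network_stats(ddis: Set[DDIKey]) -> NetworkStats:
    """Connected-component and degree statistics of the DDI graph.

    Homo-DDIs are self-loops; a domain interacting only with itself forms a
    1-node component.  A node's degree is its number of distinct partners,
    a self-loop adding 1.  The 99th-percentile degree is read at rank
    ceil(0.99 * n) when nodes are sorted by increasing degree.
    """
    if not ddis:
        raise EvaluationError("network_stats requires a non-empty DDI set")
    g = nx.Graph()
    g.add_edges_from(ddis)
    # len(adj) counts a self-loop neighbor once: distinct partners incl. self
    degree = {v: len(g.adj[v]) for v in g.nodes}
    ccs = [len(cc) for cc in nx.connected_components(g)]
    n_nodes = g.number_of_nodes()
    giant = max(ccs)
    degs = sorted(degree.values())
    rank = math.ceil(0.99 * n_nodes)
    deg_sup = degs[rank - 1]
    deg_max = degs[-1]
    argmax = min(v for v, d in degree.items() if d == deg_max)
    hist: dict[int, int] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=len(ddis),
        n_ccs=len(ccs),
        giant_cc_size=giant,
        pct_nodes_in_giant=100.0 * giant / n_nodes,
        n_1node_ccs=sum(s == 1 for s in ccs),
        n_2node_ccs=sum(s == 2 for s in ccs),
        degree_histogram=hist,
        pct_degree_gt3=100.0 * sum(d > 3 for d in degs) / n_nodes,
        degree_sup_99=deg_sup,
        degree_max=deg_max,
        argmax_node=argmax,
        n_homo_ddis=sum(a == b for a, b in ddis),
    )
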