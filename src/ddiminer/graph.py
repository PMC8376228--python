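"""Per-source tripartite structure.

Each PPI source is cast as a tripartite graph: a middle layer Z of ordered
protein pairs, a left domain set D_L (domains of left proteins) and a right
domain set D_R (domains of right proteins).  The two binary incidence
matrices M_X (|D_L| x |Z|) and M_Y (|D_R| x |Z|) record which PPIs each
domain touches through its carrier protein on that side.  D_L and D_R are
overlapping but distinct sets and are never merged at this layer.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Set
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import OrderedPPI, canonical_ppi
from .errors import EmptySourceError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SourceGraph:
    """One PPI source instantiated as domain-PPI incidence structure.

    ``m_left[d, k] == 1`` iff domain ``d_left[d]`` annotates the left protein
    of ``ppis[k]``; symmetrically for ``m_right``.  Every row has at least one
    nonzero entry (domains with no incident PPI are not rows).
    """

    name: str
    ppis: tuple[OrderedPPI, ...]
    d_left: tuple[str, ...]
    d_right: tuple[str, ...]
    m_left: sparse.csr_matrix = field(repr=False)
    m_right: sparse.csr_matrix = field(repr=False)

    @property
    def n_z(self) -> int:
        """Number of distinct ordered PPIs in the source."""
        return len(self.ppis)


def _incidence(domains: tuple[str, ...], column_domains: list[Set[str]],
               n_cols: int) -> sparse.csr_matrix:
    index = {d: i for i, d in enumerate(domains)}
    rows: list[int] = []
    cols: list[int] = []
    for k, ds in enumerate(column_domains):
        for d in ds:
            rows.append(index[d])
            cols.append(k)
    data = np.ones(len(rows), dtype=np.int8)
    return sparse.csr_matrix((data, (rows, cols)),
                             shape=(len(domains), n_cols), dtype=np.int8)


def build_source_graph(name: str, pairs: Iterable[tuple[str, str]],
                       annotations: Mapping[str, Set[str]]) -> SourceGraph:
    """Canonicalize, deduplicate and index a source's PPI list.

    PPIs whose two proteins both lack annotations are dropped (with a logged
    count); a PPI with one annotated side is kept and contributes incidence
    rows on that side only.
    """
    if not annotations:
        raise ValidationError("annotation map is empty")
    seen: set[OrderedPPI] = set()
    ppis: list[OrderedPPI] = []
    n_dropped = 0
    for a, b in pairs:
        ppi = canonical_ppi(a, b)
        if ppi in seen:
            continue
        if ppi[0] not in annotations and ppi[1] not in annotations:
            n_dropped += 1
            continue
        seen.add(ppi)
        ppis.append(ppi)
    if n_dropped:
        logger.info("%s: dropped %d PPI(s) with no annotated protein on either side",
                    name, n_dropped)
    if not ppis:
        raise EmptySourceError(f"source {name!r}: no PPIs survived annotation filtering")

    left_doms = [frozenset(annotations.get(l, ())) for l, _ in ppis]
    right_doms = [frozenset(annotations.get(r, ())) for _, r in ppis]
    d_left = tuple(sorted(set().union(*left_doms)))
    d_right = tuple(sorted(set().union(*right_doms)))
    return SourceGraph(
        name=name,
        ppis=tuple(ppis),
        d_left=d_left,
        d_right=d_right,
        m_left=_incidence(d_left, left_doms, len(ppis)),
        m_right=_incidence(d_right, right_doms, len(ppis)),
    )
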