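"""Per-source candidate DDI scoring.

For a source graph, every (left-domain, right-domain) pair sharing at least
one PPI column becomes a candidate DDI.  Its evidence is the cosine
similarity of the two binary incidence rows,

    cos(x, y) = K_xy / sqrt(N_x * N_y),

where K_xy is the number of common neighbor PPIs and N_x, N_y the row sums.
Chance overlap is assessed with a one-sided hypergeometric test,

    p = P(K >= K_xy)  for K ~ Hypergeom(N_z, N_x, N_y),

and a Bonferroni correction over the merged candidate family across all
sources flags significant pairs (p < alpha / n_tests, strictly).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DDIKey
from .errors import ValidationError
from .graph import SourceGraph

logger = logging.getLogger(__name__)


@dataclass
class SourceScore:
    """Evidence for one candidate DDI from one source.

    ``significant`` stays ``None`` until Bonferroni flags are applied.
    """

    cosine: float
    k_xy: int
    n_x: int
    n_y: int
    n_z: int
    p_value: float
    significant: bool | None = None


@dataclass
class CandidateMatrix:
    """Sparse per-source score matrix: only pairs with K_xy >= 1 are present."""

    source: str
    scores: dict[DDIKey, SourceScore] = field(default_factory=dict)

    @property
    def n_candidates(self) -> int:
        return len(self.scores)


def cosine_score(row_x: np.ndarray, row_y: np.ndarray) -> float:
    """Cosine similarity of two binary incidence rows; in [0, 1]."""
    x = np.asarray(row_x, dtype=float).ravel()
    y = np.asarray(row_y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("incidence rows differ in length")
    nx = float(np.dot(x, x))
    ny = float(np.dot(y, y))
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("cosine is undefined for an all-zero incidence row")
    return float(np.dot(x, y)) / float(np.sqrt(nx * ny))


def hypergeom_pvalue(k_xy: int, n_x: int, n_y: int, n_z: int) -> float:
    """One-sided tail P(K >= k_xy) for K ~ Hypergeom(n_z, n_x, n_y)."""
    if not (0 <= k_xy <= min(n_x, n_y)) or n_x > n_z or n_y > n_z or min(n_x, n_y) < 0:
        raise ValidationError(
            f"invalid hypergeometric arguments: k={k_xy}, n_x={n_x}, n_y={n_y}, n_z={n_z}")
    # sf(k-1) = P(K >= k); survival function is evaluated in log-space by scipy
    p = float(stats.hypergeom.sf(k_xy - 1, n_z, n_x, n_y))
    return min(1.0, max(0.0, p))


def score_source(g: SourceGraph) -> CandidateMatrix:
    """Score every domain pair of a source with at least one common PPI.

    Keys are canonical (sorted) domain pairs.  When both orientations of a
    pair are scoreable — a domain can occur in both D_L and D_R — the
    orientation with the larger cosine wins (ties: larger common-neighbor
    count, then the orientation whose left-role domain is the smaller id).
    """
    common = (g.m_left.astype(np.int32) @ g.m_right.T.astype(np.int32)).tocoo()
    n_x = np.asarray(g.m_left.sum(axis=1)).ravel()
    n_y = np.asarray(g.m_right.sum(axis=1)).ravel()
    n_z = g.n_z

    # key -> (cosine, k, n_left_role, n_right_role, left_role_domain)
    best: dict[DDIKey, tuple[float, int, int, int, str]] = {}
    for i, j, k in zip(common.row, common.col, common.data):
        x, y = g.d_left[i], g.d_right[j]
        k = int(k)
        nx_i, ny_j = int(n_x[i]), int(n_y[j])
        cos = k / float(np.sqrt(nx_i * ny_j))
        key: DDIKey = (x, y) if x <= y else (y, x)
        cand = (cos, k, nx_i, ny_j, x)
        cur = best.get(key)
        if cur is None:
            best[key] = cand
        elif (cand[0], cand[1]) > (cur[0], cur[1]):
            best[key] = cand
        elif (cand[0], cand[1]) == (cur[0], cur[1]) and cand[4] < cur[4]:
            best[key] = cand

    keys = list(best)
    ks = np.array([best[k][1] for k in keys], dtype=np.int64)
    nxs = np.array([best[k][2] for k in keys], dtype=np.int64)
    nys = np.array([best[k][3] for k in keys], dtype=np.int64)
    pvals = np.clip(stats.hypergeom.sf(ks - 1, n_z, nxs, nys), 0.0, 1.0)

    scores = {
        key: SourceScore(cosine=best[key][0], k_xy=int(ks[i]), n_x=int(nxs[i]),
                         n_y=int(nys[i]), n_z=n_z, p_value=float(pvals[i]))
        for i, key in enumerate(keys)
    }
    return CandidateMatrix(source=g.name, scores=scores)


def bonferroni_flags(matrices: Iterable[CandidateMatrix], alpha: float = 0.05) -> int:
    """Set significance flags across all sources with one global Bonferroni family.

    The family size is the merged candidate union across sources (the enriched
    edge set E3*); each score is significant iff p < alpha / n_tests, strictly.
    Returns the family size.
    """
    mats = list(matrices)
    if not mats:
        raise ValidationError("bonferroni_flags requires at least one candidate matrix")
    union: set[DDIKey] = set()
    for m in mats:
        union.update(m.scores)
    n_tests = len(union)
    if n_tests == 0:
        logger.warning("no candidates in any source; significance flags unchanged")
        return 0
    threshold = alpha / n_tests
    for m in mats:
        for s in m.scores.values():
            s.significant = s.p_value < threshold
    return n_tests
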