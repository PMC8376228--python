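"""Multi-source consensus scoring and ROC-based weight optimization.

Per-source cosine matrices are fused into a single consensus matrix by a
non-zero weighted average: for a domain pair present in at least one source,

    CS = sum_d w_d * C_d  /  sum_{d : C_d > 0} w_d,

i.e. sources with a zero (absent) score contribute to neither numerator nor
denominator.  Source weights are chosen on the grid {0.01, 0.02, ..., 1.00}
to maximize the ROC AUC of the consensus ranking, with the gold-standard
DDIs as positives and all other scored pairs as background.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Mapping, Set
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import DDIKey
from .errors import ConfigurationError, EvaluationError, ValidationError
from .scoring import CandidateMatrix

logger = logging.getLogger(__name__)

#: The weight search grid: 0.01 * i for i in 1..100.
WEIGHT_GRID = np.round(np.arange(1, 101) * 0.01, 2)


@dataclass
class ConsensusMatrix:
    scores: dict[DDIKey, float]
    weights_used: dict[str, float]
    auc: float | None = field(default=None)


def combine(per_source: Mapping[str, CandidateMatrix],
            weights: Mapping[str, float]) -> ConsensusMatrix:
    """Fuse per-source cosine scores into the consensus matrix."""
    if not per_source:
        raise ValidationError("combine requires at least one source")
    missing = set(per_source) - set(weights)
    if missing:
        raise ValidationError(f"no weight configured for source(s): {sorted(missing)}")
    num: dict[DDIKey, float] = {}
    den: dict[DDIKey, float] = {}
    for name, mat in per_source.items():
        w = float(weights[name])
        for key, s in mat.scores.items():
            if s.cosine <= 0.0:
                continue
            num[key] = num.get(key, 0.0) + w * s.cosine
            den[key] = den.get(key, 0.0) + w
    scores = {key: num[key] / den[key] for key in num}
    return ConsensusMatrix(scores=scores, weights_used=dict(weights))


def roc_auc(scores: Mapping[DDIKey, float], positives: Set[DDIKey]) -> float:
    """AUC of the score ranking, positives vs all other scored pairs.

    Midrank tie convention: equals P(s_pos > s_neg) + 0.5 * P(s_pos == s_neg).
    """
    keys = list(scores)
    y = np.fromiter((k in positives for k in keys), dtype=bool, count=len(keys))
    n_pos = int(y.sum())
    n_neg = len(keys) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"AUC undefined: {n_pos} positive(s) and {n_neg} background pair(s) scored")
    s = np.fromiter((scores[k] for k in keys), dtype=float, count=len(keys))
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


class _AucEvaluator:
    """Vectorized consensus AUC as a function of the weight vector."""

    def __init__(self, per_source: Mapping[str, CandidateMatrix],
                 positives: Set[DDIKey]):
        self.sources = sorted(per_source)
        keys = sorted({k for m in per_source.values() for k in m.scores})
        if not keys:
            raise EvaluationError("no candidate pairs in any source")
        index = {k: i for i, k in enumerate(keys)}
        S = np.zeros((len(keys), len(self.sources)))
        for j, name in enumerate(self.sources):
            for key, s in per_source[name].scores.items():
                S[index[key], j] = s.cosine
        self.S = S
        self.M = (S > 0).astype(float)
        self.y = np.fromiter((k in positives for k in keys), dtype=bool, count=len(keys))
        self.n_pos = int(self.y.sum())
        self.n_neg = len(keys) - self.n_pos
        if self.n_pos == 0 or self.n_neg == 0:
            raise EvaluationError("weight optimization needs scored positives and background")

    def auc(self, w: np.ndarray) -> float:
        cs = (self.S @ w) / (self.M @ w)
        ranks = rankdata(cs)
        return float((ranks[self.y].sum() - self.n_pos * (self.n_pos + 1) / 2.0)
                     / (self.n_pos * self.n_neg))


def optimize_weights(per_source: Mapping[str, CandidateMatrix],
                     positives: Set[DDIKey],
                     strategy: str = "coordinate_ascent",
                     seed: int = 0,
                     restarts: int = 3) -> tuple[dict[str, float], float]:
    """Search the weight grid for the AUC-maximizing source weights.

    ``exhaustive`` enumerates every grid combination and is only permitted for
    up to three sources; ``coordinate_ascent`` sweeps one source at a time
    from seeded random grid starts until a full sweep yields no improvement.
    Ties between equal-AUC weight vectors break toward the lexicographically
    smallest tuple in sorted source order.  Deterministic given ``seed``.
    """
    if not per_source:
        raise ValidationError("optimize_weights requires at least one source")
    ev = _AucEvaluator(per_source, positives)
    d = len(ev.sources)

    if strategy == "exhaustive":
        if d > 3:
            raise ConfigurationError(
                f"exhaustive search over {d} sources needs 100^{d} evaluations; "
                "use coordinate_ascent")
        best_w: tuple[float, ...] | None = None
        best_auc = -np.inf
        for combo in itertools.product(WEIGHT_GRID, repeat=d):
            a = ev.auc(np.array(combo))
            if a > best_auc:  # first (lexicographically smallest) combo wins ties
                best_auc, best_w = a, combo
        assert best_w is not None
        return dict(zip(ev.sources, best_w)), float(best_auc)

    if strategy != "coordinate_ascent":
        raise ConfigurationError(f"unknown weight-search strategy: {strategy!r}")

    rng = np.random.default_rng(seed)
    best_w = None
    best_auc = -np.inf
    for _ in range(max(1, restarts)):
        w = rng.choice(WEIGHT_GRID, size=d)
        cur = ev.auc(w)
        improved = True
        while improved:
            improved = False
            for j in range(d):
                trial = w.copy()
                cand_auc, cand_val = cur, w[j]
                for g in WEIGHT_GRID:
                    trial[j] = g
                    a = ev.auc(trial)
                    if a > cand_auc or (a == cand_auc and g < cand_val):
                        cand_auc, cand_val = a, g
                if cand_auc > cur or (cand_auc == cur and cand_val < w[j]):
                    w[j] = cand_val
                    cur = cand_auc
                    improved = True
        wt = tuple(float(x) for x in w)
        if cur > best_auc or (cur == best_auc and (best_w is None or wt < best_w)):
            best_auc, best_w = cur, wt
    assert best_w is not None
    logger.info("weight search (%s): AUC %.6f with weights %s", strategy, best_auc,
                dict(zip(ev.sources, best_w)))
    return dict(zip(ev.sources, best_w)), float(best_auc)
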