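"""Gold/Silver/Bronze category assignment.

A filtered DDI is *Gold* when it has a nonzero score in at least half of the
configured sources and a significant p-value in every source where it is
scored; *Silver* when it is scored in fewer than half of the sources but all
its p-values are significant; *Bronze* otherwise (at least one scored source
is not significant).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Set
from dataclasses import dataclass

from .core import DDIKey
from .errors import ClassificationError
from .scoring import CandidateMatrix, SourceScore

logger = logging.getLogger(__name__)

GOLD = "Gold"
SILVER = "Silver"
BRONZE = "Bronze"


@dataclass
class ScoredDDI:
    key: DDIKey
    per_source: dict[str, SourceScore]
    consensus: float
    category: str
    in_gold_standard: bool


def classify(per_source: Mapping[str, SourceScore], n_sources_total: int,
             min_sources: int | None = None) -> str:
    """Category from the nonzero-score pattern and significance flags.

    ``min_sources`` overrides the default breadth cutoff ceil(D/2).
    """
    if not per_source:
        raise ClassificationError("cannot classify a DDI with no per-source scores")
    if n_sources_total < len(per_source):
        raise ClassificationError(
            f"{len(per_source)} scored sources exceed n_sources_total={n_sources_total}")
    cutoff = math.ceil(n_sources_total / 2) if min_sources is None else min_sources
    all_significant = all(bool(s.significant) for s in per_source.values())
    if not all_significant:
        return BRONZE
    return GOLD if len(per_source) >= cutoff else SILVER


def classify_all(filtered_consensus: Mapping[DDIKey, float],
                 per_source: Mapping[str, CandidateMatrix],
                 gold_standard: Set[DDIKey],
                 n_sources_total: int | None = None,
                 min_sources: int | None = None) -> list[ScoredDDI]:
    """Build one ScoredDDI per filtered consensus entry.

    Logs the category-by-gold-standard breakdown of the result.
    """
    total = len(per_source) if n_sources_total is None else n_sources_total
    out: list[ScoredDDI] = []
    for key, cs in filtered_consensus.items():
        present = {name: mat.scores[key]
                   for name, mat in per_source.items() if key in mat.scores}
        cat = classify(present, total, min_sources=min_sources)
        out.append(ScoredDDI(key=key, per_source=present, consensus=float(cs),
                             category=cat, in_gold_standard=key in gold_standard))
    out.sort(key=lambda d: (-d.consensus, d.key))
    for cat in (GOLD, SILVER, BRONZE):
        n = sum(d.category == cat for d in out)
        n_gs = sum(d.category == cat and d.in_gold_standard for d in out)
        logger.info("category %s: %d DDIs (%d in gold standard)", cat, n, n_gs)
    return out
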