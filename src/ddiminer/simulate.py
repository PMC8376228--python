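"""Planted-truth synthetic worlds.

A world consists of a domain universe, randomly annotated proteins, a hidden
set of true DDIs, and several PPI "sources" whose interactions are a mixture
of signal (protein pairs drawn so that they carry a true DDI across the
interaction) and uniform-random noise pairs.  A configurable fraction of the
true DDIs is exposed as the gold standard for calibration, leaving the rest
as held-out targets for recovery assessment.

Defaults describe a world of 50 domains, 200 proteins (each carrying
1 + Poisson(2) domains), 30 true DDIs (10% homo-DDIs), and 3 sources of 500
PPIs at 80% signal — small enough to run in seconds, structured enough that
the inference pipeline must separate signal from noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Set
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import DDIKey, OrderedPPI, canonical_ddi, canonical_ppi
from .errors import GenerationError

_MAX_RETRIES = 10_000


@dataclass
class WorldConfig:
    n_domains: int = 50
    n_proteins: int = 200
    domains_per_protein_mean: float = 2.0
    n_true_ddis: int = 30
    gold_fraction: float = 0.5
    homo_ddi_fraction: float = 0.1
    n_sources: int = 3
    ppis_per_source: int = 500
    signal_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.gold_fraction, self.homo_ddi_fraction, self.signal_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise GenerationError("all fractions must lie in [0, 1]")
        counts = (self.n_domains, self.n_proteins, self.n_sources, self.ppis_per_source)
        if any(c <= 0 for c in counts) or self.n_true_ddis < 0:
            raise GenerationError("counts must be positive")
        max_pairs = self.n_domains * (self.n_domains + 1) // 2
        if self.n_true_ddis > max_pairs:
            raise GenerationError(
                f"{self.n_true_ddis} true DDIs exceed the {max_pairs} possible pairs")


@dataclass
class PlantedWorld:
    domains: list[str]
    annotations: dict[str, set[str]]
    true_ddis: set[DDIKey]
    gold_standard: set[DDIKey]
    sources: dict[str, list[OrderedPPI]]
    signal_ppis: dict[str, set[OrderedPPI]] = field(repr=False)
    config_echo: dict = field(repr=False, default_factory=dict)
    seed: int = 0


def generate_world(cfg: WorldConfig) -> PlantedWorld:
    """Draw a complete world reproducibly from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    domains = [f"PF{i:04d}" for i in range(1, cfg.n_domains + 1)]

    annotations: dict[str, set[str]] = {}
    for p in range(1, cfg.n_proteins + 1):
        k = min(int(rng.poisson(cfg.domains_per_protein_mean)) + 1, cfg.n_domains)
        picked = rng.choice(cfg.n_domains, size=k, replace=False)
        annotations[f"P{p:04d}"] = {domains[i] for i in picked}

    n_homo = round(cfg.homo_ddi_fraction * cfg.n_true_ddis)
    true_ddis: set[DDIKey] = set()
    if n_homo:
        homo_doms = rng.choice(cfg.n_domains, size=n_homo, replace=False)
        true_ddis.update((domains[i], domains[i]) for i in homo_doms)
    retries = 0
    while len(true_ddis) < cfg.n_true_ddis:
        i, j = rng.integers(0, cfg.n_domains, size=2)
        if i == j:
            continue
        key = canonical_ddi(domains[int(i)], domains[int(j)])
        if key in true_ddis:
            retries += 1
            if retries > _MAX_RETRIES:
                raise GenerationError("could not draw enough distinct true DDIs")
            continue
        true_ddis.add(key)

    n_gold = math.ceil(cfg.gold_fraction * len(true_ddis))
    true_sorted = sorted(true_ddis)
    gold_idx = rng.choice(len(true_sorted), size=n_gold, replace=False) if n_gold else []
    gold_standard = {true_sorted[int(i)] for i in gold_idx}

    carriers = {d: sorted(p for p, ds in annotations.items() if d in ds)
                for d in domains}
    proteins = sorted(annotations)

    def sample_signal_pair() -> OrderedPPI:
        for _ in range(_MAX_RETRIES):
            da, db = true_sorted[int(rng.integers(0, len(true_sorted)))]
            ca, cb = carriers[da], carriers[db]
            if not ca or not cb:
                continue
            pa = ca[int(rng.integers(0, len(ca)))]
            pb = cb[int(rng.integers(0, len(cb)))]
            return canonical_ppi(pa, pb)
        raise GenerationError("no true DDI has carrier proteins on both sides")

    sources: dict[str, list[OrderedPPI]] = {}
    signal_ppis: dict[str, set[OrderedPPI]] = {}
    n_signal = round(cfg.signal_fraction * cfg.ppis_per_source)
    for s in range(1, cfg.n_sources + 1):
        name = f"source{s}"
        raw: list[OrderedPPI] = []
        sig: set[OrderedPPI] = set()
        if true_sorted:
            for _ in range(n_signal):
                ppi = sample_signal_pair()
                raw.append(ppi)
                sig.add(ppi)
        for _ in range(cfg.ppis_per_source - (len(raw))):
            i, j = rng.integers(0, cfg.n_proteins, size=2)
            raw.append(canonical_ppi(proteins[int(i)], proteins[int(j)]))
        seen: set[OrderedPPI] = set()
        dedup = [p for p in raw if not (p in seen or seen.add(p))]
        sources[name] = dedup
        signal_ppis[name] = sig
    return PlantedWorld(domains=domains, annotations=annotations, true_ddis=true_ddis,
                        gold_standard=gold_standard, sources=sources,
                        signal_ppis=signal_ppis,
                        config_echo=dataclasses.asdict(cfg), seed=cfg.seed)


def recovery_metrics(inferred: Set[DDIKey], planted: Set[DDIKey],
                     exclude: Set[DDIKey] = frozenset()) -> tuple[float, float]:
    """Precision/recall of inferred vs planted DDIs after removing ``exclude``.

    Excluding the gold standard used for calibration makes this a held-out
    assessment of the pipeline's ability to discover unseen true DDIs.
    """
    inf = set(inferred) - set(exclude)
    tru = set(planted) - set(exclude)
    hit = len(inf & tru)
    precision = hit / len(inf) if inf else 0.0
    recall = hit / len(tru) if tru else 0.0
    return precision, recall


def write_world(world: PlantedWorld, outdir: str | Path) -> None:
    """Write the world as standard input files plus truth and config echo."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, ppis in world.sources.items():
        with open(out / f"{name}.ppis.tsv", "w", encoding="utf-8") as fh:
            for a, b in ppis:
                fh.write(f"{a}\t{b}\n")
    with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
        for protein in sorted(world.annotations):
            fh.write(f"{protein}\t{','.join(sorted(world.annotations[protein]))}\n")
    with open(out / "gold_standard.tsv", "w", encoding="utf-8") as fh:
        for a, b in sorted(world.gold_standard):
            fh.write(f"{a}\t{b}\n")
    with open(out / "true_ddis.tsv", "w", encoding="utf-8") as fh:
        for a, b in sorted(world.true_ddis):
            fh.write(f"{a}\t{b}\n")
    with open(out / "world_config.json", "w", encoding="utf-8") as fh:
        json.dump(world.config_echo, fh, indent=2, sort_keys=True)
        fh.write("\n")
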