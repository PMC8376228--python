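"""End-to-end orchestration: score → weights → consensus → calibrate → classify.

`run_inference` is the in-memory pipeline used by the library, the CLI and
the test-suite alike; `run_pipeline` wraps it with file I/O, a run manifest
and idempotent re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from .calibration import (LearningSet, ThresholdResult, build_learning_set,
                          filter_matrix, select_threshold_cv,
                          select_threshold_simple, shuffle_negatives)
from .classify import ScoredDDI, classify_all
from .consensus import ConsensusMatrix, combine, optimize_weights, roc_auc
from .core import DDIKey
from .errors import CalibrationError, ConfigurationError, DDIMinerError
from .graph import build_source_graph
from .scoring import CandidateMatrix, bonferroni_flags, score_source

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sources: dict[str, Path]
    annotations: Path
    gold_standard: Path
    outdir: Path
    alpha: float = 0.05
    min_sources: int | None = None
    weight_strategy: str = "coordinate_ascent"
    restarts: int = 3
    fixed_weights: dict[str, float] | None = None
    cv_folds: int = 5
    train_fraction: float = 2 / 3
    seed_shuffle: int = 0
    seed_cv: int = 1
    seed_optimizer: int = 2
    shuffle_max_tries: int = 100_000
    force: bool = False

    @classmethod
    def from_config_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = dio.read_config(path)
        base = Path(path).parent
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            sources = {name: base / p if not Path(p).is_absolute() else Path(p)
                       for name, p in raw["sources"].items()}
            cfg = cls(
                sources=sources,
                annotations=base / raw["annotations"],
                gold_standard=base / raw["gold_standard"],
                outdir=Path(raw.get("outdir", "ddiminer_out")),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing config key: {exc}") from exc
        for key in ("alpha", "min_sources", "weight_strategy", "restarts",
                    "fixed_weights", "cv_folds", "train_fraction", "seed_shuffle",
                    "seed_cv", "seed_optimizer", "shuffle_max_tries", "force"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for name, p in cfg.sources.items():
            if not p.exists():
                raise ConfigurationError(f"source {name!r}: file not found: {p}")
        for p in (cfg.annotations, cfg.gold_standard):
            if not p.exists():
                raise ConfigurationError(f"file not found: {p}")
        return cfg


@dataclass
class InferenceResult:
    matrices: dict[str, CandidateMatrix]
    n_tests: int
    weights: dict[str, float]
    auc: float
    consensus: ConsensusMatrix
    learning_set: LearningSet
    threshold: ThresholdResult
    filtered: dict[DDIKey, float]
    scored_ddis: list[ScoredDDI] = field(repr=False)


def run_inference(source_pairs: Mapping[str, Sequence[tuple[str, str]]],
                  annotations: Mapping[str, Set[str]],
                  gold_standard: Set[DDIKey],
                  *,
                  alpha: float = 0.05,
                  min_sources: int | None = None,
                  weight_strategy: str = "coordinate_ascent",
                  restarts: int = 3,
                  fixed_weights: Mapping[str, float] | None = None,
                  cv_folds: int = 5,
                  train_fraction: float = 2 / 3,
                  seed_shuffle: int = 0,
                  seed_cv: int = 1,
                  seed_optimizer: int = 2,
                  shuffle_max_tries: int = 100_000) -> InferenceResult:
    """Run the complete inference chain on in-memory inputs."""
    matrices: dict[str, CandidateMatrix] = {}
    for name in sorted(source_pairs):
        g = build_source_graph(name, source_pairs[name], annotations)
        matrices[name] = score_source(g)
        logger.info("stage score [%s]: %d PPIs -> %d candidate DDIs",
                    name, g.n_z, matrices[name].n_candidates)
    n_tests = bonferroni_flags(matrices.values(), alpha=alpha)
    logger.info("stage significance: %d merged candidates, threshold %.3g",
                n_tests, alpha / n_tests if n_tests else float("nan"))

    if fixed_weights is not None:
        weights = dict(fixed_weights)
        cm = combine(matrices, weights)
        auc = roc_auc(cm.scores, gold_standard)
    else:
        weights, auc = optimize_weights(matrices, gold_standard,
                                        strategy=weight_strategy,
                                        seed=seed_optimizer, restarts=restarts)
        cm = combine(matrices, weights)
    cm.auc = auc
    logger.info("stage consensus: %d scored pairs, AUC %.4f, weights %s",
                len(cm.scores), auc, weights)

    negatives = shuffle_negatives(gold_standard, seed=seed_shuffle,
                                  max_tries=shuffle_max_tries)
    ls = build_learning_set(gold_standard, negatives, cm.scores)
    try:
        thr = select_threshold_cv(ls, k=cv_folds, train_fraction=train_fraction,
                                  seed=seed_cv)
    except CalibrationError as exc:
        logger.warning("falling back to single-grid threshold selection: %s", exc)
        thr = select_threshold_simple(ls)
    filtered = filter_matrix(cm.scores, thr.t_m)
    logger.info("stage filter: T_m=%.5f keeps %d/%d pairs",
                thr.t_m, len(filtered), len(cm.scores))

    scored = classify_all(filtered, matrices, gold_standard,
                          min_sources=min_sources)
    return InferenceResult(matrices=matrices, n_tests=n_tests, weights=weights,
                           auc=auc, consensus=cm, learning_set=ls, threshold=thr,
                           filtered=filtered, scored_ddis=scored)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_OUTPUTS = ("scored_ddis.tsv", "calibration_report.yaml", "weights_report.yaml",
            "category_summary.yaml", "manifest.json")


def run_pipeline(cfg: RunConfig) -> Path:
    """File-level pipeline; returns the output directory.

    Re-running with the same output directory skips the computation when all
    outputs already exist, unless ``cfg.force`` is set.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.force and all((out / f).exists() for f in _OUTPUTS):
        logger.info("outputs already present in %s; skipping (use force to re-run)", out)
        return out

    source_pairs = {name: dio.read_ppi_table(p) for name, p in cfg.sources.items()}
    annotations = dio.read_annotations(cfg.annotations)
    gold = dio.read_ddi_table(cfg.gold_standard)

    try:
        res = run_inference(
            source_pairs, annotations, gold,
            alpha=cfg.alpha, min_sources=cfg.min_sources,
            weight_strategy=cfg.weight_strategy, restarts=cfg.restarts,
            fixed_weights=cfg.fixed_weights, cv_folds=cfg.cv_folds,
            train_fraction=cfg.train_fraction, seed_shuffle=cfg.seed_shuffle,
            seed_cv=cfg.seed_cv, seed_optimizer=cfg.seed_optimizer,
            shuffle_max_tries=cfg.shuffle_max_tries)
    except DDIMinerError as exc:
        raise type(exc)(f"pipeline aborted: {exc}") from exc

    names = sorted(cfg.sources)
    dio.write_scored_ddis(res.scored_ddis, out / "scored_ddis.tsv", source_names=names)
    for name, mat in res.matrices.items():
        dio.write_source_scores(mat, out / f"{name}.scores.tsv")
    dio.write_consensus_scores(res.consensus.scores, out / "consensus_scores.tsv")
    with open(out / "calibration_report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({
            "fold_thresholds": [float(t) for t in res.threshold.fold_thresholds],
            "fold_f1s": [float(f) for f in res.threshold.fold_f1s],
            "t_m": float(res.threshold.t_m),
            "f1_train": float(res.threshold.f1_train),
            "f1_test": float(res.threshold.f1_test),
            "precision_test": float(res.threshold.precision_test),
            "recall_test": float(res.threshold.recall_test),
        }, fh, sort_keys=False)
    with open(out / "weights_report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"weights": {k: float(v) for k, v in res.weights.items()},
                        "auc": float(res.auc)}, fh, sort_keys=False)
    summary = {cat: {"total": sum(d.category == cat for d in res.scored_ddis),
                     "in_gold_standard": sum(d.category == cat and d.in_gold_standard
                                             for d in res.scored_ddis)}
               for cat in ("Gold", "Silver", "Bronze")}
    summary["all"] = {"total": len(res.scored_ddis),
                      "in_gold_standard": sum(d.in_gold_standard
                                              for d in res.scored_ddis)}
    with open(out / "category_summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    manifest = {
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(cfg).items()
                   if k != "sources"},
        "sources": {name: str(p) for name, p in cfg.sources.items()},
        "input_checksums": {str(p): _sha256(p)
                            for p in [*cfg.sources.values(), cfg.annotations,
                                      cfg.gold_standard]},
        "n_tests": res.n_tests,
        "n_filtered": len(res.filtered),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
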