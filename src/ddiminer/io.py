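"""Readers and writers for the package's tab-separated file formats.

Formats
-------
PPI source file
    two columns of protein identifiers; ``#`` starts a comment line.
Annotation file
    ``protein<TAB>comma-separated domain accessions``.
DDI file
    two columns of domain accessions; pairs are canonicalized on read.
Scored-DDI file
    one row per inferred DDI with per-source scores/p-values, the consensus
    score and the Gold/Silver/Bronze category.
Run config
    a flat YAML mapping of parameter names to values.

No numerical logic lives here.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path
from typing import Any

import yaml

from .core import DDIKey, canonical_ddi
from .errors import ParseError

logger = logging.getLogger(__name__)


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and # comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r ")  # keep tabs: they delimit fields
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_ppi_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column PPI file; returns raw pairs in file order, unvalidated."""
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read protein→domain annotations; duplicate protein lines merge by union.

    Proteins whose domain field is empty are dropped with a logged warning, so
    every returned set is non-empty.
    """
    out: dict[str, set[str]] = {}
    n_empty = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        protein = fields[0].strip()
        domains = {d.strip() for d in fields[1].split(",") if d.strip()}
        if not protein:
            raise ParseError(f"{path}: line {lineno}: empty protein identifier")
        if not domains:
            n_empty += 1
            continue
        out.setdefault(protein, set()).update(domains)
    if n_empty:
        logger.warning("%s: dropped %d annotation line(s) with an empty domain set", path, n_empty)
    return out


def read_ddi_table(path: str | Path) -> set[DDIKey]:
    """Read a two-column DDI file; pairs are canonicalized and deduplicated."""
    ddis: set[DDIKey] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        ddis.add(canonical_ddi(fields[0].strip(), fields[1].strip()))
    return ddis


def write_ddi_table(ddis: Iterable[DDIKey], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(ddis):
            fh.write(f"{a}\t{b}\n")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_scored_ddis(ddis: Sequence[Any], path: str | Path,
                      source_names: Sequence[str] | None = None) -> None:
    """Write the scored-DDI table.

    One score column and one p-value column per source; absent per-source
    scores are written as ``0`` and absent p-values as ``NA``.  Rows are
    sorted by descending consensus score, ties by (domain_a, domain_b).
    """
    if source_names is None:
        names: list[str] = sorted({s for d in ddis for s in d.per_source})
    else:
        names = list(source_names)
    header = ["domain_a", "domain_b"]
    for name in names:
        header += [f"{name}_score", f"{name}_pvalue"]
    header += ["consensus_score", "category"]
    rows = sorted(ddis, key=lambda d: (-d.consensus, d.key))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for d in rows:
            fields = [d.key[0], d.key[1]]
            for name in names:
                s = d.per_source.get(name)
                if s is None:
                    fields += ["0", "NA"]
                else:
                    fields += [_fmt(s.cosine), _fmt(s.p_value)]
            fields += [_fmt(d.consensus), d.category]
            fh.write("\t".join(fields) + "\n")


def write_consensus_scores(scores: Mapping[DDIKey, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("domain_a\tdomain_b\tscore\n")
        for (a, b), s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{a}\t{b}\t{_fmt(s)}\n")


def read_consensus_scores(path: str | Path) -> dict[DDIKey, float]:
    out: dict[DDIKey, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("domain_a"):
            raise ParseError(f"{path}: missing consensus-score header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            out[canonical_ddi(fields[0], fields[1])] = float(fields[2])
    return out


def write_source_scores(matrix: Any, path: str | Path) -> None:
    """Per-source candidate dump: one row per scored domain pair."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("domain_a\tdomain_b\tcosine\tk\tn_x\tn_y\tn_z\tp_value\tsignificant\n")
        for (a, b), s in sorted(matrix.scores.items()):
            sig = "NA" if s.significant is None else str(int(s.significant))
            fh.write(f"{a}\t{b}\t{_fmt(s.cosine)}\t{s.k_xy}\t{s.n_x}\t{s.n_y}\t"
                     f"{s.n_z}\t{_fmt(s.p_value)}\t{sig}\n")


def read_source_scores(path: str | Path, name: str) -> Any:
    """Read a per-source candidate dump back into a CandidateMatrix."""
    from .scoring import CandidateMatrix, SourceScore

    scores: dict[DDIKey, SourceScore] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("domain_a"):
            raise ParseError(f"{path}: missing source-score header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            sig = None if fields[8] == "NA" else bool(int(fields[8]))
            scores[canonical_ddi(fields[0], fields[1])] = SourceScore(
                cosine=float(fields[2]), k_xy=int(fields[3]), n_x=int(fields[4]),
                n_y=int(fields[5]), n_z=int(fields[6]), p_value=float(fields[7]),
                significant=sig)
    return CandidateMatrix(source=name, scores=scores)


def read_config(path: str | Path) -> dict[str, Any]:
    """Read the flat YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: run config must be a flat key/value mapping")
    return cfg
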