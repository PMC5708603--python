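"""Readers and writers for the external formats the pipeline touches.

All formats are plain text: a 3-column weighted edge list (TSV), GMT gene
sets, a gene x sample expression TSV, and a gene-level statistics TSV
(mutation / copy-number frequencies).  Gene identifiers are plain symbols,
case-sensitive; no identifier mapping is performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeList",
    "ExpressionMatrix",
    "GeneSetCollection",
    "GeneStatTable",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_gene_stats",
    "write_gene_stats",
]


@dataclass(frozen=True)
class EdgeList:
    """Undirected weighted edges with confidence weights in (0, 1].

    Duplicate undirected pairs are collapsed keeping the maximum weight and
    self-loops are dropped; edges are stored with endpoints sorted so each
    undirected pair appears exactly once.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, weight

    def __post_init__(self) -> None:
        w = self.edges["weight"].to_numpy()
        if len(w) and (w <= 0).any():
            bad = self.edges.loc[w <= 0].iloc[0]
            raise ValueError(
                f"non-positive edge weight {bad['weight']!r} on edge "
                f"({bad['gene_a']}, {bad['gene_b']})"
            )

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "EdgeList":
        """Canonicalize raw records: drop self-loops, collapse duplicates (max weight)."""
        best: dict[tuple[str, str], float] = {}
        n_loops = 0
        n_dups = 0
        for a, b, w in records:
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in best:
                n_dups += 1
                best[key] = max(best[key], float(w))
            else:
                best[key] = float(w)
        if n_loops or n_dups:
            logger.info(
                "edge list canonicalization: dropped %d self-loops, collapsed %d duplicates",
                n_loops,
                n_dups,
            )
        rows = sorted(best.items())
        df = pd.DataFrame(
            [(a, b, w) for (a, b), w in rows],
            columns=["gene_a", "gene_b", "weight"],
        )
        return cls(df)


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample expression with a condition label per sample.

    ``platform`` is ``"rnaseq"`` (values in RPKM) or ``"array"`` (arbitrary
    intensities); it decides how the expressed/not-expressed threshold is set.
    """

    values: pd.DataFrame  # index = genes, columns = samples
    condition: pd.Series  # index = samples, values = condition labels
    platform: str = "rnaseq"

    def __post_init__(self) -> None:
        if self.platform not in ("rnaseq", "array"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene row: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.condition = self.condition.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def conditions(self) -> list[str]:
        return sorted(self.condition.unique())

    def samples_of(self, label: str) -> list[str]:
        return list(self.condition.index[self.condition == label])


@dataclass
class GeneSetCollection:
    """Mapping from function ID to (description, annotated gene set A_f)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {fid!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, fid: str) -> set[str]:
        return self.sets[fid]

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        ids = list(ids)
        return GeneSetCollection(
            {f: set(self.sets[f]) for f in ids},
            {f: self.descriptions.get(f, "") for f in ids},
        )


@dataclass
class GeneStatTable:
    """Per-gene nonnegative event frequencies (fractions of samples in [0, 1]).

    Canonical columns are ``missense_freq``, ``nonsense_freq``,
    ``cnv_del_freq`` and ``cnv_amp_freq`` but any named frequency column is
    accepted.
    """

    table: pd.DataFrame  # index = genes, columns = stat names

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("gene statistic frequencies must lie in [0, 1]")

    def column(self, name: str) -> pd.Series:
        return self.table[name]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a whitespace/tab-delimited edge list (gene_a, gene_b, weight).

    Lines starting with ``#`` are ignored.  Duplicate undirected pairs keep
    the maximum weight; self-loops are dropped.
    """
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable weight {parts[2]!r}") from exc
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            records.append((parts[0], parts[1], w))
    if not records:
        raise ValueError(f"{path}: empty edge list")
    return EdgeList.from_records(records)


def write_edge_list(edges: EdgeList, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for _, row in edges.edges.iterrows():
            fh.write(f"{row['gene_a']}\t{row['gene_b']}\t{row['weight']:g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated ID, description, genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            fid, desc = parts[0], parts[1]
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {fid!r} is empty")
            if fid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set ID {fid!r}")
            sets[fid] = genes
            descriptions[fid] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fid in sorted(collection.sets):
            desc = collection.descriptions.get(fid, "")
            genes = "\t".join(sorted(collection.sets[fid]))
            fh.write(f"{fid}\t{desc}\t{genes}\n")


def read_expression(
    path: str | Path,
    condition_map: Mapping[str, str],
    platform: str = "rnaseq",
) -> ExpressionMatrix:
    """Read a gene x sample TSV (header row of sample IDs, genes in rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene row {dup!r}")
    missing = [s for s in df.columns if s not in condition_map]
    if missing:
        raise ValueError(f"{path}: samples without condition label: {missing}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression value")
    cond = pd.Series({s: condition_map[s] for s in df.columns})
    return ExpressionMatrix(df, cond, platform=platform)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_gene_stats(path: str | Path) -> GeneStatTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneStatTable(df)


def write_gene_stats(stats: GeneStatTable, path: str | Path) -> None:
    stats.table.to_csv(path, sep="\t", index_label="gene")
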