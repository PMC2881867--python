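"""Readers, writers and containers for the file formats the pipeline touches.

Expression matrices are probe-by-sample tables of normalized, linear-scale
intensities (MAS5-style magnitudes) stored as tab-delimited text. Gene sets
use the Broad GMT dialect. Sample annotations are plain CSV. All readers
validate hard: duplicate identifiers, non-numeric cells and negative
linear-scale values are errors, not warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("sample_id", "group_label", "pair_id")


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """Probe-by-sample grid of expression intensities.

    Parameters
    ----------
    values
        DataFrame with probe IDs as the index and sample IDs as columns.
        NaN marks a missing measurement; infinities are rejected.
    scale
        ``"linear"`` (non-negative intensities, the default for
        MAS5-normalized data) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        dup_probes = _find_duplicates(self.values.index)
        if dup_probes:
            raise ValueError(f"duplicate probe IDs: {dup_probes}")
        dup_samples = _find_duplicates(self.values.columns)
        if dup_samples:
            raise ValueError(f"duplicate sample IDs: {dup_samples}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and np.nanmin(vals, initial=0.0) < 0:
            bad = np.argwhere(np.nan_to_num(vals) < 0)[0]
            raise ValueError(
                "negative value on linear scale at probe "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        self.values = self.values.astype(float)
        self.values.index.name = "probe_id"
        self.values.columns.name = None

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.scale == other.scale and self.values.equals(other.values)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of probe identifiers (GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SampleAnnotation:
    """Sample-level design table: group labels and optional pairing IDs."""

    table: pd.DataFrame  # columns: sample_id, group_label, pair_id

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        dups = _find_duplicates(self.table["sample_id"])
        if dups:
            raise ValueError(f"duplicate sample IDs in annotation: {dups}")
        pair_counts = self.table["pair_id"].dropna().value_counts()
        orphans = pair_counts[pair_counts < 2].index.tolist()
        if orphans:
            raise ValueError(f"pair IDs occurring on a single sample: {orphans}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def samples_in_group(self, group_label: str) -> list[str]:
        mask = self.table["group_label"] == group_label
        return self.table.loc[mask, "sample_id"].tolist()


def read_expression_tsv(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a tab-delimited probe-by-sample expression table.

    First row is the sample header (first field is the probe-ID column
    label), first column holds probe IDs. The token ``NA`` marks a missing
    value. Row and column order are preserved verbatim.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        na_values=["NA"],
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    dups = _find_duplicates(df.index)
    if dups:
        raise ValueError(f"{path}: duplicate probe IDs: {dups}")
    dups = _find_duplicates(df.columns)
    if dups:
        raise ValueError(f"{path}: duplicate sample IDs: {dups}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    # astype goes through the correctly-rounded parser (full round-trip
    # precision); to_numeric's fast path may be off by one ulp
    return ExpressionMatrix(values=df.astype(float), scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full float precision (round-trip safe)."""
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then tab-separated members.

    Duplicate members within a line are collapsed with a logged warning;
    a line with fewer than three fields is an error.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                log.warning(
                    "gene set %r (line %d): %d duplicate members collapsed",
                    name, lineno, len(members) - len(unique),
                )
            sets.append(GeneSet(name=name, description=description, members=unique))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def read_annotation_csv(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, dtype={"sample_id": str, "group_label": str, "pair_id": str})
    return SampleAnnotation(table=df)


def write_annotation_csv(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, index=False)


def subset_matrix(matrix: ExpressionMatrix, gene_set: GeneSet) -> ExpressionMatrix:
    """Restrict a matrix to the probes of a gene set.

    Matrix row order is preserved; gene-set members absent from the matrix
    are counted and reported via a logged warning. Zero overlap is an error.
    """
    mask = matrix.probe_ids.isin(gene_set.members)
    n_present = int(mask.sum())
    if n_present == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no probes with the matrix"
        )
    n_missing = len(gene_set.members) - n_present
    if n_missing:
        log.warning(
            "gene set %r: %d of %d members absent from the matrix",
            gene_set.name, n_missing, len(gene_set.members),
        )
    return ExpressionMatrix(values=matrix.values.loc[mask], scale=matrix.scale)
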