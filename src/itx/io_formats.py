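"""Readers and writers for the plain-text artifacts the pipeline exchanges.

All tabular formats are tab-separated by default, following the convention
of GEO supplementary tables; a different delimiter must be requested
explicitly.  Gene identity is the bare symbol string, case-sensitive, with
no aliasing: cross-table comparisons match symbols exactly.

Parsers here are strict by design — they never silently drop or coerce a
row.  Every malformed input is rejected with an error that names the
offending symbol, line or cell, because a silently mangled count table
invalidates everything downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_count_table",
    "read_group_file",
    "read_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_deg_table",
    "read_deg_table",
    "write_table",
]

#: float format used for all statistics tables; 8 significant digits so a
#: round-trip through text preserves at least 6.
FLOAT_FMT = "%.8g"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw gene-by-sample integer counts with optional group labels.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``groups`` maps sample id -> condition label.  The mapping may cover a
    subset of the samples — contrasts validate coverage for the samples
    they actually use.
    """

    counts: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene symbol {dup!r}")
        cols = self.counts.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. a GMT collection of GO/KEGG terms."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene set name {gs.name!r}")
        if not gs.members:
            raise FormatError(f"gene set {gs.name!r} has no members")
        self.sets[gs.name] = gs


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _rows(path: str | Path, sep: str) -> Iterator[list[str]]:
    with open(path, newline="") as fh:
        yield from csv.reader(fh, delimiter=sep)


def read_count_table(path: str | Path, sep: str = "\t") -> CountMatrix:
    """Parse a gene-by-sample count table.

    Layout: header row of sample ids (first cell is a corner label and is
    ignored), then one row per gene: symbol followed by one integer count
    per sample.  Row and column order are preserved.
    """
    rows = _rows(path, sep)
    try:
        header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty count table") from None
    sample_ids = [c.strip() for c in header[1:]]
    if not sample_ids:
        raise FormatError(f"{path}: header has no sample columns")
    n = len(sample_ids)
    genes: list[str] = []
    seen: set[str] = set()
    data: list[list[int]] = []
    for lineno, row in enumerate(rows, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != n + 1:
            raise FormatError(
                f"{path}:{lineno}: ragged row — expected {n + 1} fields, "
                f"found {len(row)}"
            )
        gene = row[0].strip()
        if not gene:
            raise FormatError(f"{path}:{lineno}: empty gene symbol")
        if gene in seen:
            raise FormatError(f"{path}: duplicate gene symbol {gene!r}")
        seen.add(gene)
        parsed: list[int] = []
        for sample, cell in zip(sample_ids, row[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(gene {gene!r}, sample {sample!r})"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count {value} "
                    f"(gene {gene!r}, sample {sample!r})"
                )
            parsed.append(value)
        genes.append(gene)
        data.append(parsed)
    if not genes:
        raise FormatError(f"{path}: no gene rows")
    counts = pd.DataFrame(
        np.asarray(data, dtype=np.int64), index=genes, columns=sample_ids
    )
    return CountMatrix(counts)


def read_group_file(
    path: str | Path, sep: str = "\t", header: bool = False
) -> dict[str, str]:
    """Read a two-column sample -> group assignment file.

    A sample listed twice with the same label is tolerated; conflicting
    labels are an error.  The mapping may cover only a subset of the count
    table's samples — missing samples surface when a contrast is built.
    """
    mapping: dict[str, str] = {}
    rows = _rows(path, sep)
    if header:
        next(rows, None)
    for lineno, row in enumerate(rows, start=2 if header else 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise FormatError(
                f"{path}:{lineno}: expected sample and group columns"
            )
        sample, label = row[0].strip(), row[1].strip()
        if not sample or not label:
            raise FormatError(f"{path}:{lineno}: empty sample id or label")
        if sample in mapping and mapping[sample] != label:
            raise FormatError(
                f"{path}: sample {sample!r} assigned to both "
                f"{mapping[sample]!r} and {label!r}"
            )
        mapping[sample] = label
    if not mapping:
        raise FormatError(f"{path}: empty group file")
    return mapping


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file: name, description, then member symbols.

    Member lists are de-duplicated; lines with fewer than three fields and
    duplicate set names are rejected.
    """
    collection = GeneSetCollection()
    for lineno, row in enumerate(_rows(path, "\t"), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f"at least one member ({len(row)} field(s) found)"
            )
        name, description = row[0].strip(), row[1].strip()
        members = frozenset(m.strip() for m in row[2:] if m.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
        collection.add(GeneSet(name, description, members))
    if not collection:
        raise FormatError(f"{path}: empty GMT file")
    return collection


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list, de-duplicated, order kept."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and sym not in seen:
                seen.add(sym)
                out.append(sym)
    if not out:
        raise FormatError(f"{path}: empty gene list")
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

DEG_COLUMNS = ["gene", "t", "lmr", "p_t", "p_lmr", "overall_p", "adj_p", "call"]


def write_deg_table(result, path: str | Path) -> None:
    """Write per-gene statistics and calls as TSV.

    Row order is deterministic: descending ``|lmr|``, ties broken
    lexicographically by gene symbol.  Floats carry 8 significant digits
    so re-reading reproduces values to at least 6.
    """
    stats = result.statistics
    df = stats.reset_index(names="gene")[DEG_COLUMNS[1:-1] + ["call"]].copy()
    df.insert(0, "gene", stats.index)
    order = np.lexsort((df["gene"].to_numpy(), -df["lmr"].abs().to_numpy()))
    df = df.iloc[order]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_deg_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "call": str})
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Generic TSV writer used for enrichment and overlap tables."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
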