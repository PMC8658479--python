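"""Directional comparison and subsetting of differential-expression calls.

These operations answer the bookkeeping questions that follow any
multi-contrast differential analysis: which genes respond the same way in
two contrasts, which reverse direction (e.g. down with age at room
temperature but up again under cold exposure), and what the exclusive
Venn region counts are.  Gene symbols match exactly and case-sensitively
unless the case-insensitive escape hatch is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Sequence

import pandas as pd

from .deg_stats import DegResult

logger = logging.getLogger(__name__)

__all__ = [
    "DegList",
    "overlap",
    "venn_regions",
    "cross_contrast_reversal",
    "filter_by_gene_list",
]

Direction = Literal["up", "down", "any"]


@dataclass
class DegList:
    """Named up/down gene sets from one contrast."""

    name: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        both = self.up & self.down
        if both:
            raise ValueError(
                f"{self.name}: genes in both directions: {sorted(both)[:5]}"
            )

    @classmethod
    def from_deg_result(cls, result: DegResult, name: str | None = None) -> "DegList":
        label = name or f"{result.contrast.label_a}_vs_{result.contrast.label_b}"
        return cls(label, result.genes("up"), result.genes("down"))

    @classmethod
    def from_table(cls, table: pd.DataFrame, name: str) -> "DegList":
        """Build from a DEG table DataFrame (gene + call columns)."""
        up = set(table.loc[table["call"] == "up", "gene"])
        down = set(table.loc[table["call"] == "down", "gene"])
        return cls(name, up, down)

    def genes(self, direction: Direction) -> set[str]:
        if direction == "up":
            return set(self.up)
        if direction == "down":
            return set(self.down)
        if direction == "any":
            return self.up | self.down
        raise ValueError(f"unknown direction {direction!r}")


def overlap(
    a: DegList, b: DegList, direction: Direction = "any"
) -> tuple[set[str], set[str], set[str]]:
    """Partition a ∪ b (for one direction) into common / only-a / only-b."""
    sa, sb = a.genes(direction), b.genes(direction)
    return sa & sb, sa - sb, sb - sa


def venn_regions(
    lists: Sequence[DegList], direction: Direction = "any"
) -> dict[str, int]:
    """Exclusive region counts for 2 or 3 DEG lists.

    Region keys are membership masks in list order ("10" = only first,
    "11" = both, "111" = all three, ...); counts sum to the union size.
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("venn_regions handles 2 or 3 lists")
    sets = [l.genes(direction) for l in lists]
    regions: dict[str, int] = {}
    for mask in product((1, 0), repeat=len(sets)):
        if not any(mask):
            continue
        region = set.intersection(*(s for s, m in zip(sets, mask) if m))
        for s, m in zip(sets, mask):
            if not m:
                region = region - s
        regions["".join(map(str, mask))] = len(region)
    return regions


def cross_contrast_reversal(
    first: DegList, second: DegList
) -> tuple[set[str], set[str]]:
    """Genes whose direction flips between two contrasts.

    Returns (down-then-up, up-then-down): genes down in the first
    contrast but up in the second, and vice versa.
    """
    return first.down & second.up, first.up & second.down


def filter_by_gene_list(
    result: DegResult,
    genes: Iterable[str],
    list_name: str,
    case_insensitive: bool = False,
) -> DegResult:
    """Restrict a DEG result to members of a gene list (e.g. a
    mitochondrial inventory), keeping statistics and calls unchanged.

    Zero overlap is an error — it almost always means a symbol-convention
    mismatch rather than a biologically empty intersection.
    """
    members = list(genes)
    if not members:
        raise ValueError(f"gene list {list_name!r} is empty")
    index = result.statistics.index
    if case_insensitive:
        lookup = {g.lower() for g in members}
        keep = index[[g.lower() in lookup for g in index]]
        present = {g.lower() for g in index}
        absent = [g for g in members if g.lower() not in present]
    else:
        lookup = set(members)
        keep = index[index.isin(lookup)]
        present = set(index)
        absent = [g for g in members if g not in present]
    if len(keep) == 0:
        raise ValueError(
            f"no member of gene list {list_name!r} is present in the data "
            "(symbol convention mismatch?)"
        )
    if absent:
        logger.info(
            "gene list %r: %d member(s) absent from the data", list_name, len(absent)
        )
    return DegResult(
        result.statistics.loc[keep].copy(),
        result.lmr_cutoff,
        result.contrast,
        result.null_t,
        result.null_lmr,
    )
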