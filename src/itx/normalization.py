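"""Counts-per-million, log2 and quantile normalization.

The expression surface the differential statistics operate on is built in
a fixed order: cpm -> (optional low-expression filter) -> log2(x + 1) ->
quantile normalization.  Each stage records itself in the matrix's
provenance and refuses to run out of order, because e.g. quantile
normalizing linear-scale cpm produces a different (and unintended)
surface than normalizing log2 cpm.

Quantile normalization maps every sample onto a common reference
distribution: the reference value at rank r is the mean across samples of
each sample's r-th order statistic, and tied values within a sample
receive the mean of the reference values over the tied rank span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "compute_cpm",
    "log2_transform",
    "quantile_normalize",
    "filter_low_expression",
]


class PipelineOrderError(RuntimeError):
    """Raised when a normalization stage is applied out of order."""


@dataclass
class NormalizedMatrix:
    """Gene-by-sample expression values plus the transforms applied so far."""

    values: pd.DataFrame
    provenance: tuple[str, ...]
    groups: dict[str, str] | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def _require(self, present: tuple[str, ...], absent: tuple[str, ...], stage: str) -> None:
        for p in present:
            if p not in self.provenance:
                raise PipelineOrderError(
                    f"{stage} requires {p!r} first (provenance: {self.provenance})"
                )
        for a in absent:
            if a in self.provenance:
                raise PipelineOrderError(
                    f"{stage} cannot follow {a!r} (provenance: {self.provenance})"
                )


def compute_cpm(cm: CountMatrix) -> NormalizedMatrix:
    """Counts per million: counts / library size * 1e6, per sample."""
    colsums = cm.counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero library size")
    values = cm.counts / colsums * 1e6
    return NormalizedMatrix(values.astype(float), ("cpm",), dict(cm.groups or {}) or None)


def log2_transform(m: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """log2(value + pseudocount); monotone within each sample."""
    m._require(("cpm",), ("log2", "quantile"), "log2 transform")
    arr = m.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("log2 transform requires non-negative values")
    if pseudocount <= 0 and (arr == 0).any():
        raise ValueError("pseudocount must be > 0 when zeros are present")
    return NormalizedMatrix(
        np.log2(m.values + pseudocount), m.provenance + ("log2",), m.groups
    )


def quantile_normalize(m: NormalizedMatrix) -> NormalizedMatrix:
    """Force every sample onto the mean-of-order-statistics reference.

    A single-sample matrix is returned value-unchanged with a warning —
    there is nothing to equalize.
    """
    m._require(("log2",), ("quantile",), "quantile normalization")
    values = m.values.to_numpy(dtype=float)
    if values.shape[1] < 2:
        logger.warning("quantile normalization skipped: single sample")
        return NormalizedMatrix(m.values.copy(), m.provenance + ("quantile",), m.groups)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires complete values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        by_rank = np.empty_like(col)
        by_rank[order] = reference
        # ties get the mean reference value over their shared rank span
        out[:, j] = pd.Series(by_rank).groupby(col).transform("mean").to_numpy()
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return NormalizedMatrix(df, m.provenance + ("quantile",), m.groups)


def filter_low_expression(
    m: NormalizedMatrix,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> NormalizedMatrix:
    """Drop genes expressed below ``min_cpm`` in fewer than ``min_samples``.

    Operates on the linear cpm surface (before log2).  The default
    ``min_samples`` is half the samples, rounded up.
    """
    m._require(("cpm",), ("log2", "quantile"), "low-expression filter")
    n_samples = m.values.shape[1]
    if min_samples is None:
        min_samples = math.ceil(n_samples / 2)
    keep = (m.values >= min_cpm).sum(axis=1) >= min_samples
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"low-expression filter (min_cpm={min_cpm}, "
            f"min_samples={min_samples}) would remove every gene"
        )
    if n_removed:
        logger.info("low-expression filter removed %d gene(s)", n_removed)
    return NormalizedMatrix(
        m.values.loc[keep], m.provenance + ("low-expression-filter",), m.groups
    )
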