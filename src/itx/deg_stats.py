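"""Integrative resampling statistics for two-group differential expression.

For every gene two effect measures are computed on the normalized log2
expression surface:

* ``t`` — the two-sample Student t statistic (pooled variance), oriented
  as mean(group a) - mean(group b);
* ``lmr`` — the log2-median-ratio, the difference of group medians on the
  log2 scale (equivalently the log2 ratio of linear-scale medians).

Significance is assessed against empirical nulls built by randomly
re-assigning the group labels across the pooled samples (group sizes
preserved) and recomputing both statistics for every gene.  The null
values are pooled across genes and resamples into a single vector per
statistic: with only 3-6 replicates per group a per-gene permutation null
cannot resolve p-values below ~1/20, whereas the pooled null borrows the
exchangeable permutation variation across all genes.  When the number of
distinct label assignments does not exceed the requested resample count,
exhaustive enumeration replaces random sampling (and the observed
assignment plus, for equal group sizes, its mirror image are excluded
from the null).

Two-tailed empirical p-values for t and lmr are combined into an overall
p per gene with Stouffer's method on signed normal quantiles, so that
concordant evidence reinforces and discordant evidence cancels.  A gene
is called differentially expressed when its overall (or BH-adjusted)
p-value falls below ``alpha`` *and* its absolute lmr exceeds a cutoff
derived from the lmr null: the mean of the magnitudes of the null's 2.5th
and 97.5th percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "NullDistribution",
    "DegResult",
    "compute_t",
    "compute_lmr",
    "build_null",
    "empirical_p",
    "stouffer_combine",
    "lmr_cutoff",
    "call_degs",
]


# ---------------------------------------------------------------------------
# specifications and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison: ``label_a`` versus reference ``label_b``."""

    label_a: str
    label_b: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]
    n_resamples: int = 1000
    seed: int = 0
    alpha: float = 0.05
    adjust: Literal["none", "BH"] = "BH"

    def __post_init__(self) -> None:
        if self.label_a == self.label_b:
            raise ValueError("contrast labels must be distinct")
        if len(self.samples_a) < 2 or len(self.samples_b) < 2:
            raise ValueError("each group needs at least 2 samples")
        overlap = set(self.samples_a) & set(self.samples_b)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")

    @classmethod
    def from_groups(
        cls, groups: dict[str, str], label_a: str, label_b: str, **kwargs
    ) -> "ContrastSpec":
        """Build a contrast from a sample -> label mapping."""
        samples_a = tuple(s for s, g in groups.items() if g == label_a)
        samples_b = tuple(s for s, g in groups.items() if g == label_b)
        if not samples_a or not samples_b:
            missing = label_a if not samples_a else label_b
            raise ValueError(f"no samples labelled {missing!r}")
        return cls(label_a, label_b, samples_a, samples_b, **kwargs)


@dataclass
class NullDistribution:
    """Pooled empirical null for one statistic (all genes x all resamples)."""

    statistic: str
    values: np.ndarray
    n_resamples_effective: int
    scheme: Literal["exhaustive", "random"]
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("empty null distribution")
        self._abs_sorted = np.sort(np.abs(self.values))

    @property
    def median(self) -> float:
        """Symmetry diagnostic; should sit near 0 under exchangeability."""
        return float(np.median(self.values))

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DegResult:
    """Per-gene statistics, the lmr cutoff, and the up/down/ns calls."""

    statistics: pd.DataFrame
    lmr_cutoff: float
    contrast: ContrastSpec
    null_t: NullDistribution | None = None
    null_lmr: NullDistribution | None = None

    @property
    def calls(self) -> pd.Series:
        return self.statistics["call"]

    @property
    def counts(self) -> tuple[int, int]:
        c = self.statistics["call"]
        return int((c == "up").sum()), int((c == "down").sum())

    def genes(self, direction: Literal["up", "down"]) -> set[str]:
        return set(self.statistics.index[self.statistics["call"] == direction])


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def compute_t(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Pooled-variance two-sample t, oriented mean(a) - mean(b).

    Degenerate variance is resolved deterministically: both groups
    constant and equal means -> 0; zero pooled variance with unequal means
    -> signed infinity (callers operating across many genes cap it to one
    more than the largest finite ``|t|`` so ranking survives).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = a.mean() - b.mean()
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    se = math.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    if se == 0.0:
        if diff == 0.0:
            return 0.0
        return math.inf if diff > 0 else -math.inf
    return float(diff / se)


def compute_lmr(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Log2-median-ratio: difference of group medians on the log2 scale."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return float(np.median(a) - np.median(b))


def _stats_for_split(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene (t, lmr) for one label assignment.

    ``values`` is genes x pooled-samples.  Infinite t sentinels (zero
    pooled variance, unequal means) are capped to max finite |t| + 1,
    keeping the sign, so the pooled null never contains infinities.
    """
    a = values[:, idx_a]
    b = values[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    pooled = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    degenerate = ~ok & (diff != 0)
    if degenerate.any():
        cap = (np.max(np.abs(t[ok])) if ok.any() else 0.0) + 1.0
        t[degenerate] = np.sign(diff[degenerate]) * cap
    lmr = np.median(a, axis=1) - np.median(b, axis=1)
    return t, lmr


# ---------------------------------------------------------------------------
# empirical nulls
# ---------------------------------------------------------------------------


def _null_assignments(
    n_a: int, n_b: int, n_resamples: int, seed: int
) -> tuple[list[np.ndarray], str, int]:
    """Label assignments used for the null, as index arrays into the pooled
    sample order (observed order: the ``n_a`` group-a samples first).

    Exhaustive mode triggers when C(n_a + n_b, n_a) <= n_resamples; it
    drops the observed assignment and, when group sizes are equal, its
    mirror image (which reproduces the observed statistics with flipped
    sign).  Random mode draws ``n_resamples`` independent permutations.
    """
    n = n_a + n_b
    total = math.comb(n, n_a)
    if total < 2:
        raise ValueError("fewer than 2 distinct label assignments")
    observed = tuple(range(n_a))
    mirror = tuple(range(n_b, n)) if n_a == n_b else None
    if total <= n_resamples:
        assignments = [
            np.asarray(combo, dtype=np.intp)
            for combo in combinations(range(n), n_a)
            if combo != observed and combo != mirror
        ]
        return assignments, "exhaustive", len(assignments)
    rng = np.random.default_rng(seed)
    assignments = [
        np.sort(rng.permutation(n)[:n_a]).astype(np.intp)
        for _ in range(n_resamples)
    ]
    return assignments, "random", n_resamples


def build_null(
    matrix: NormalizedMatrix, contrast: ContrastSpec
) -> tuple[NullDistribution, NullDistribution]:
    """Pooled empirical nulls for t and lmr under label re-assignment."""
    values = _contrast_values(matrix, contrast)
    n_a, n_b = len(contrast.samples_a), len(contrast.samples_b)
    assignments, scheme, n_eff = _null_assignments(
        n_a, n_b, contrast.n_resamples, contrast.seed
    )
    n = n_a + n_b
    all_idx = np.arange(n, dtype=np.intp)
    t_chunks: list[np.ndarray] = []
    lmr_chunks: list[np.ndarray] = []
    for idx_a in assignments:
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        t, lmr = _stats_for_split(values, idx_a, all_idx[~mask])
        t_chunks.append(t)
        lmr_chunks.append(lmr)
    null_t = NullDistribution(
        "t", np.concatenate(t_chunks), n_eff, scheme, contrast.seed
    )
    null_lmr = NullDistribution(
        "lmr", np.concatenate(lmr_chunks), n_eff, scheme, contrast.seed
    )
    logger.info(
        "null built: scheme=%s, %d effective resamples, pooled size %d, "
        "t-null median %.4g",
        scheme,
        n_eff,
        len(null_t),
        null_t.median,
    )
    return null_t, null_lmr


def empirical_p(observed: float | np.ndarray, null: NullDistribution) -> float | np.ndarray:
    """Two-tailed empirical p with add-one smoothing.

    p = (#{|null| >= |observed|} + 1) / (N + 1), so the smallest
    attainable value is 1/(N+1) and p is never zero.
    """
    obs = np.asarray(observed, dtype=float)
    if np.isnan(obs).any():
        raise ValueError("observed statistic is NaN")
    n = null._abs_sorted.size
    ge = n - np.searchsorted(null._abs_sorted, np.abs(obs), side="left")
    p = (ge + 1.0) / (n + 1.0)
    return float(p) if np.isscalar(observed) or obs.ndim == 0 else p


def stouffer_combine(
    p_t: float | np.ndarray,
    sign_t: float | np.ndarray,
    p_lmr: float | np.ndarray,
    sign_lmr: float | np.ndarray,
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Combine two signed two-tailed p-values into an overall p and Z.

    Each component becomes a signed normal quantile
    ``z_i = sign_i * Phi^-1(1 - p_i/2)``; the combined score is
    ``Z = (z_t + z_lmr) / sqrt(2)`` and the overall p is the two-tailed
    normal tail ``2 * (1 - Phi(|Z|))``.  Concordant signs reinforce,
    discordant signs cancel.
    """
    pt = np.asarray(p_t, dtype=float)
    pl = np.asarray(p_lmr, dtype=float)
    for name, p in (("p_t", pt), ("p_lmr", pl)):
        if ((p <= 0) | (p > 1)).any():
            raise ValueError(f"{name} must lie in (0, 1]")
    zt = np.sign(sign_t) * ndtri(1.0 - pt / 2.0)
    zl = np.sign(sign_lmr) * ndtri(1.0 - pl / 2.0)
    z = (zt + zl) / math.sqrt(2.0)
    overall = 2.0 * (1.0 - ndtr(np.abs(z)))
    # two-tailed tail can round to 0 for extreme z; keep p strictly positive
    overall = np.maximum(overall, np.finfo(float).tiny)
    if np.isscalar(p_t):
        return float(overall), float(z)
    return overall, z


def lmr_cutoff(null_lmr: NullDistribution) -> float:
    """Fold-change cutoff: mean magnitude of the null's 2.5th and 97.5th
    percentiles (linear-interpolation percentile definition)."""
    lo, hi = np.percentile(null_lmr.values, [2.5, 97.5])
    return float((abs(lo) + abs(hi)) / 2.0)


# ---------------------------------------------------------------------------
# the full per-contrast computation
# ---------------------------------------------------------------------------


def _contrast_values(matrix: NormalizedMatrix, contrast: ContrastSpec) -> np.ndarray:
    pooled = list(contrast.samples_a) + list(contrast.samples_b)
    missing = [s for s in pooled if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"samples absent from matrix: {missing}")
    return matrix.values[pooled].to_numpy(dtype=float)


def call_degs(matrix: NormalizedMatrix, contrast: ContrastSpec) -> DegResult:
    """Run the full integrative statistic for one contrast.

    Returns per-gene t, lmr, component empirical p-values, signed z's,
    Stouffer overall p, BH-adjusted p, and the up/down/ns call under the
    two selection criteria (p below ``alpha`` on the scale chosen by
    ``adjust``, and |lmr| above the null-derived cutoff).
    """
    values = _contrast_values(matrix, contrast)
    n_a, n_b = len(contrast.samples_a), len(contrast.samples_b)
    idx_a = np.arange(n_a, dtype=np.intp)
    idx_b = np.arange(n_a, n_a + n_b, dtype=np.intp)
    t_obs, lmr_obs = _stats_for_split(values, idx_a, idx_b)

    null_t, null_lmr = build_null(matrix, contrast)
    p_t = empirical_p(t_obs, null_t)
    p_lmr = empirical_p(lmr_obs, null_lmr)
    overall_p, z = stouffer_combine(p_t, np.sign(t_obs), p_lmr, np.sign(lmr_obs))
    adj_p = multipletests(overall_p, method="fdr_bh")[1]
    cutoff = lmr_cutoff(null_lmr)

    selector = adj_p if contrast.adjust == "BH" else overall_p
    passed = (selector < contrast.alpha) & (np.abs(lmr_obs) > cutoff)
    call = np.where(passed & (lmr_obs > 0), "up", np.where(passed, "down", "ns"))

    stats = pd.DataFrame(
        {
            "t": t_obs,
            "lmr": lmr_obs,
            "p_t": p_t,
            "p_lmr": p_lmr,
            "z_t": np.sign(t_obs) * ndtri(1.0 - np.asarray(p_t) / 2.0),
            "z_lmr": np.sign(lmr_obs) * ndtri(1.0 - np.asarray(p_lmr) / 2.0),
            "combined_z": z,
            "overall_p": overall_p,
            "adj_p": adj_p,
            "call": call,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    result = DegResult(stats, cutoff, contrast, null_t, null_lmr)
    n_up, n_down = result.counts
    logger.info(
        "contrast %s vs %s: %d up, %d down (alpha=%g on %s p, lmr cutoff %.4g)",
        contrast.label_a,
        contrast.label_b,
        n_up,
        n_down,
        contrast.alpha,
        "BH-adjusted" if contrast.adjust == "BH" else "overall",
        cutoff,
    )
    return result
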