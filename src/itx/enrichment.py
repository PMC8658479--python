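"""Over-representation analysis and preranked gene set enrichment.

Two complementary enrichment stages over GMT collections:

* **ORA** — the hypergeometric tail test of a query list (e.g. the up- or
  downregulated DEGs) against each set, with the classic annotation-tool
  reporting filter: a set is flagged only when its p-value is below 0.05
  *and* it contributes more than 3 query genes.  An EASE-style variant
  (the tail computed on k-1 hits) is available behind a flag.

* **GSEA** — the weighted Kolmogorov-Smirnov running-sum statistic on a
  ranked gene list.  Hits advance the running sum by |score|^weight
  normalized over the set; misses retreat by 1/(N - N_H).  The enrichment
  score is the maximum signed deviation, and significance comes from
  gene-label permutations: null scores for same-size random sets drawn
  from the ranked universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_p",
    "run_ora",
    "gsea_es",
    "run_gsea",
    "rank_genes_for_gsea",
]

ORA_P_CUTOFF = 0.05
#: minimum query hits for the reporting filter; strictly more than this
ORA_MIN_COUNT = 3


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) drawing ``n`` from ``N``
    with ``K`` marked."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe first; query genes outside the
    universe are trimmed with a logged count.  ``passes_filter`` applies
    the reporting filter (p < 0.05 and hit count > 3).  With ``ease`` the
    tail is computed on k-1 hits (the conservative EASE score variant).
    Rows are ordered by set name for determinism.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    q = set(query)
    outside = q - uni
    if outside:
        logger.info("trimmed %d query gene(s) outside the universe", len(outside))
        q &= uni
    N, n = len(uni), len(q)
    rows = []
    for name in sorted(collection.sets):
        gs = collection[name]
        members = gs.members & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        k_test = max(k - 1, 0) if ease else k
        p = hypergeom_p(k_test, K, n, N)
        rows.append((name, k, K, n, N, p))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(
        rows, columns=["set_name", "hit_count", "set_size", "query_size",
                       "universe_size", "p"]
    )
    df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1]
    df["passes_filter"] = (df["p"] < ORA_P_CUTOFF) & (df["hit_count"] > ORA_MIN_COUNT)
    return df


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def gsea_es(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    members: Iterable[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score with its running profile.

    ``ranked_genes`` must be sorted by decreasing score.  Returns
    (ES, running profile of length N, leading-edge genes).  The leading
    edge is the member genes at or before the positive extremum (for
    ES > 0) or at or after the negative extremum (for ES < 0).
    """
    genes = list(ranked_genes)
    s = np.asarray(scores, dtype=float)
    if len(genes) != s.size:
        raise ValueError("ranked_genes and scores differ in length")
    if np.any(np.diff(s) > 0):
        raise ValueError("scores must be sorted in decreasing order")
    member_set = set(members) & set(genes)
    if not member_set:
        raise ValueError("no set member present in the ranked list")
    hit = np.fromiter((g in member_set for g in genes), dtype=bool, count=len(genes))
    n_hit = int(hit.sum())
    n = len(genes)
    if n_hit == n:
        raise ValueError("set covers the entire ranked list; misses undefined")
    w = np.abs(s) ** weight
    hit_sum = w[hit].sum()
    if hit_sum == 0:
        # all member scores are zero: fall back to equal hit increments
        increments = np.where(hit, 1.0 / n_hit, 0.0)
    else:
        increments = np.where(hit, w / hit_sum, 0.0)
    decrements = np.where(hit, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(increments - decrements)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_min:], hit[i_min:]) if h]
    return float(es), running, leading


def _es_batch(
    abs_w: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Enrichment scores for many same-size sets given by hit positions.

    ``positions`` is (batch, m), sorted ascending along axis 1.  The
    running sum attains its positive extremum at a hit and its negative
    extremum immediately before a hit, so only hit positions need
    evaluating.
    """
    m = positions.shape[1]
    w = abs_w[positions]  # (batch, m)
    denom = w.sum(axis=1, keepdims=True)
    # degenerate all-zero weights: equal increments
    safe = np.where(denom == 0, 1.0, denom)
    cum_hit = np.cumsum(np.where(denom == 0, 1.0 / m, w / safe), axis=1)
    miss_inc = 1.0 / (n - m)
    ranks = np.arange(1, m + 1)
    # after processing hit i (0-based): misses so far = pos+1-(i+1)
    at_hit = cum_hit - (positions + 1 - ranks) * miss_inc
    before_hit = np.concatenate(
        [np.zeros((positions.shape[0], 1)), cum_hit[:, :-1]], axis=1
    ) - (positions - (ranks - 1)) * miss_inc
    pos_ext = at_hit.max(axis=1)
    neg_ext = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(pos_ext >= -neg_ext, pos_ext, neg_ext)


def run_gsea(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    collection: GeneSetCollection,
    n_perm: int = 10000,
    min_size: int = 3,
    max_size: int = 800,
    p_cutoff: float = 0.05,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection with gene-label permutation nulls.

    Sets are restricted to those whose intersection with the ranked
    universe has between ``min_size`` and ``max_size`` members.  The null
    for each set size is the ES of ``n_perm`` uniformly drawn same-size
    subsets; perm_p = (#{|ES_null| >= |ES|} + 1)/(n_perm + 1) and NES
    divides ES by the mean |null ES| of matching sign.  ``significant``
    flags BH-adjusted p below ``p_cutoff``.
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n = len(genes)
    eligible: list[tuple[str, frozenset[str]]] = []
    for name in sorted(collection.sets):
        members = collection[name].members & set(genes)
        if min_size <= len(members) <= max_size and len(members) < n:
            eligible.append((name, frozenset(members)))
    if not eligible:
        raise ValueError(
            f"no gene set within [{min_size}, {max_size}] after intersection "
            "with the ranked universe"
        )
    abs_w = np.abs(s) ** weight
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_for_size(m: int) -> np.ndarray:
        if m not in null_cache:
            # sample n_perm subsets of size m without replacement, vectorized
            keys = rng.random((n_perm, n))
            positions = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
            null_cache[m] = _es_batch(abs_w, positions, n)
        return null_cache[m]

    pos_index = {g: i for i, g in enumerate(genes)}
    rows = []
    leading_edges = []
    for name, members in eligible:
        es, _, leading = gsea_es(genes, s, members, weight)
        null = null_for_size(len(members))
        perm_p = (np.count_nonzero(np.abs(null) >= abs(es)) + 1.0) / (n_perm + 1.0)
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        rows.append((name, len(members), es, nes, perm_p))
        leading_edges.append("|".join(sorted(leading)))
    df = pd.DataFrame(
        rows, columns=["set_name", "set_size", "ES", "NES", "perm_p"]
    )
    df["adj_p"] = multipletests(df["perm_p"], method="fdr_bh")[1]
    df["significant"] = df["adj_p"] < p_cutoff
    df["leading_edge"] = leading_edges
    return df


def rank_genes_for_gsea(statistics: pd.DataFrame) -> pd.Series:
    """Rank genes for preranked GSEA: score = sign(lmr) * -log10(overall p).

    Ties break by lmr, then by gene symbol (ascending), so the ordering
    is fully deterministic.  Returns a score Series sorted descending.
    """
    score = np.sign(statistics["lmr"]) * (-np.log10(statistics["overall_p"]))
    df = pd.DataFrame(
        {
            "score": score.to_numpy(),
            "lmr": statistics["lmr"].to_numpy(),
            "gene": statistics.index.to_numpy(),
        }
    )
    df = df.sort_values(
        ["score", "lmr", "gene"], ascending=[False, False, True], kind="stable"
    )
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy(), name="score")
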