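"""Synthetic RNA-seq count generator with planted differential signal.

The generator emulates the structure of the small two-group bulk BAT
contrasts the pipeline is aimed at (young vs. old, cold vs. room
temperature, diet or drug vs. control): a few thousand genes, 3-6
replicates per group, negative-binomial counts, and a minority of genes
carrying a known symmetric log2 effect.  Because the true status of every
gene is returned alongside the counts, the generator doubles as the ground
truth for sensitivity / false-discovery measurements.

Counts for gene *g* in sample *s* of group *k* are drawn as

    counts ~ NB(mean = w_g(k) / sum_g' w_g'(k) * L_s,  dispersion = phi)

where ``w_g(k) = 2**(baseline_g + effect_g * [k is the second group])``,
``L_s`` is the sample's library size, and the NB is parameterised so that
``var = mean + phi * mean**2`` (phi = 0 degenerates to Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["DesignSpec", "simulate_experiment", "make_oracle_fixture"]


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one simulated two-group experiment.

    Defaults mirror typical bulk RNA-seq: baseline log2 means uniform on
    (3, 10), NB dispersion 0.1, library sizes between 0.5 and 2 million
    reads.  ``de_log2fc`` is the magnitude of the planted effect; signs are
    split half positive / half negative.  Effects apply to the second group
    label in lexicographic order.
    """

    n_genes: int
    group_sizes: Mapping[str, int]
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    dispersion: float = 0.1
    de_fraction: float = 0.0
    de_log2fc: float = 2.0
    library_size_range: tuple[float, float] = (5e5, 2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.group_sizes) != 2:
            raise ValueError("exactly two groups are required")
        for label, size in self.group_sizes.items():
            if size < 2:
                raise ValueError(
                    f"group {label!r} has {size} sample(s); at least 2 are "
                    "required for a two-sample test"
                )
        for low, high in (self.baseline_log2_mean_range, self.library_size_range):
            if low > high:
                raise ValueError("range low must not exceed high")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


def simulate_experiment(spec: DesignSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one experiment; returns the counts plus a per-gene truth table.

    The truth table has columns ``is_de`` (bool), ``sign`` (+1/-1/0) and
    ``log2fc`` (signed planted effect).  A fixed seed yields bit-identical
    output: all randomness flows through one generator stream in a fixed
    draw order (baselines, planted-gene choice, library sizes, counts).
    """
    rng = np.random.default_rng(spec.seed)
    labels = sorted(spec.group_sizes)
    gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]

    baseline = rng.uniform(*spec.baseline_log2_mean_range, size=spec.n_genes)

    effect = np.zeros(spec.n_genes)
    n_de = spec.n_de
    de_idx = np.sort(rng.choice(spec.n_genes, size=n_de, replace=False))
    signs = np.ones(n_de)
    signs[(n_de + 1) // 2 :] = -1.0  # ceil(n/2) positive, floor(n/2) negative
    effect[de_idx] = signs * spec.de_log2fc

    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for label in labels:
        second = label == labels[1]
        weights = np.exp2(baseline + (effect if second else 0.0))
        props = weights / weights.sum()
        n_samples = spec.group_sizes[label]
        lib_sizes = rng.uniform(*spec.library_size_range, size=n_samples)
        for i in range(n_samples):
            mean = props * lib_sizes[i]
            if spec.dispersion == 0:
                draw = rng.poisson(mean)
            else:
                shape = 1.0 / spec.dispersion
                p = shape / (shape + mean)
                draw = rng.negative_binomial(shape, p)
            sid = f"{label}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = label
            columns.append(draw.astype(np.int64))

    counts = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=sample_ids
    )
    truth = pd.DataFrame(
        {
            "is_de": np.zeros(spec.n_genes, dtype=bool),
            "sign": np.zeros(spec.n_genes, dtype=np.int64),
            "log2fc": np.zeros(spec.n_genes),
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth.loc[truth.index[de_idx], "is_de"] = True
    truth["sign"] = np.sign(effect).astype(np.int64)
    truth["log2fc"] = effect
    return CountMatrix(counts, groups), truth


# ---------------------------------------------------------------------------
# deterministic oracle fixture
# ---------------------------------------------------------------------------

# 6 genes x 6 samples, two groups of three.  Column sums are all equal
# (1000) so cpm is an exact rescaling, and gene OR3 holds the strictly
# smallest value of every column so its rank — hence its quantile-normalized
# value — is identical in every sample: its t and lmr are exactly zero.
_ORACLE_COUNTS = {
    "grpA_1": [150, 210, 5, 340, 100, 195],
    "grpA_2": [205, 160, 5, 330, 110, 190],
    "grpA_3": [140, 215, 5, 300, 130, 210],
    "grpB_1": [80, 300, 5, 260, 170, 185],
    "grpB_2": [95, 260, 5, 280, 200, 160],
    "grpB_3": [70, 310, 5, 240, 155, 220],
}
_ORACLE_GENES = ["OR1", "OR2", "OR3", "OR4", "OR5", "OR6"]


def make_oracle_fixture() -> tuple[CountMatrix, pd.DataFrame]:
    """Return the fixed 6x6 (3 vs 3) matrix plus its frozen statistics.

    With three samples per group there are C(6,3) = 20 distinct label
    assignments, so the permutation null is enumerated exhaustively and
    every statistic is exactly reproducible.  The companion table (packaged
    as ``data/oracle_expected.tsv``) holds t, lmr and the empirical
    p-values as enumerated once by an independent brute-force oracle.
    """
    counts = pd.DataFrame(_ORACLE_COUNTS, index=_ORACLE_GENES, dtype=np.int64)
    groups = {s: s.split("_")[0] for s in counts.columns}
    ref = resources.files("itx").joinpath("data/oracle_expected.tsv")
    with resources.as_file(ref) as fp:
        expected = pd.read_csv(
            fp, sep="\t", index_col="gene", float_precision="round_trip"
        )
    return CountMatrix(counts, groups), expected
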