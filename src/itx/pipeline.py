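"""Configuration-driven orchestration of the full analysis.

A single YAML config describes one or more datasets (each either a count
table on disk or a synthetic-data design), the contrast to run per
dataset, and the normalization / differential / enrichment parameters.
``run_pipeline`` executes simulate-or-load -> cpm -> filter -> log2 ->
quantile -> DEG calling per dataset, directional overlap tables for every
dataset pair, and ORA + preranked GSEA per DEG list, writing every output
as TSV plus a JSON manifest of seeds, parameters and input checksums.
Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import deg_stats, enrichment, io_formats, normalization, set_ops
from .io_formats import CountMatrix, write_table
from .synthetic_data import DesignSpec, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with the complete list of config violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid config:\n  - " + "\n  - ".join(violations))


_TOP_KEYS = {
    "seed", "output_dir", "datasets", "normalization", "deg",
    "enrichment", "gene_lists", "plots",
}
_DATASET_KEYS = {"simulate", "counts", "groups", "contrast"}
_NORM_KEYS = {"pseudocount", "min_cpm", "min_samples", "filter"}
_DEG_KEYS = {"n_resamples", "alpha", "adjust"}
_ENRICH_KEYS = {"gmt", "n_perm", "min_size", "max_size", "p_cutoff", "weight", "ease"}
_SIM_KEYS = {
    "n_genes", "group_sizes", "baseline_log2_mean_range", "dispersion",
    "de_fraction", "de_log2fc", "library_size_range",
}


@dataclass
class DatasetConfig:
    name: str
    contrast: tuple[str, str]  # (a, b); b is the reference
    simulate: dict[str, Any] | None = None
    counts: Path | None = None
    groups: Path | None = None


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    datasets: list[DatasetConfig]
    normalization: dict[str, Any] = field(default_factory=dict)
    deg: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    gene_lists: dict[str, Path] = field(default_factory=dict)
    plots: bool = False


def _dataset_seed(base: int, index: int) -> int:
    """Deterministic per-dataset child seed, kept below 2**31."""
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline config, reporting *all* violations."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"unparseable YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    base = path.parent
    errors: list[str] = []

    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    if "seed" not in raw or not isinstance(raw.get("seed"), int):
        errors.append("an integer 'seed' is required")
    if "output_dir" not in raw:
        errors.append("'output_dir' is required")

    datasets: list[DatasetConfig] = []
    raw_datasets = raw.get("datasets")
    if not isinstance(raw_datasets, dict) or not raw_datasets:
        errors.append("'datasets' must be a non-empty mapping")
        raw_datasets = {}
    for name, ds in raw_datasets.items():
        if not isinstance(ds, dict):
            errors.append(f"dataset {name!r} must be a mapping")
            continue
        for key in ds:
            if key not in _DATASET_KEYS:
                errors.append(f"dataset {name!r}: unknown key {key!r}")
        contrast = ds.get("contrast")
        if (
            not isinstance(contrast, dict)
            or set(contrast) != {"a", "b"}
            or contrast["a"] == contrast["b"]
        ):
            errors.append(
                f"dataset {name!r}: 'contrast' must map distinct labels to 'a' and 'b'"
            )
            contrast = {"a": "?", "b": "??"}
        sim = ds.get("simulate")
        counts_path = groups_path = None
        labels_available: set[str] | None = None
        if sim is not None and "counts" in ds:
            errors.append(f"dataset {name!r}: give either 'simulate' or 'counts'")
        elif sim is not None:
            if not isinstance(sim, dict):
                errors.append(f"dataset {name!r}: 'simulate' must be a mapping")
                sim = {}
            for key in sim:
                if key not in _SIM_KEYS:
                    errors.append(f"dataset {name!r}: unknown simulate key {key!r}")
            gs = sim.get("group_sizes")
            if not isinstance(gs, dict) or len(gs) != 2:
                errors.append(
                    f"dataset {name!r}: simulate.group_sizes must map exactly "
                    "two labels to sizes"
                )
            else:
                labels_available = set(gs)
        elif "counts" in ds:
            counts_path = base / ds["counts"]
            if not counts_path.is_file():
                errors.append(f"dataset {name!r}: counts file not found: {counts_path}")
            if "groups" not in ds:
                errors.append(f"dataset {name!r}: 'groups' required with 'counts'")
            else:
                groups_path = base / ds["groups"]
                if not groups_path.is_file():
                    errors.append(
                        f"dataset {name!r}: groups file not found: {groups_path}"
                    )
                else:
                    labels_available = set(
                        io_formats.read_group_file(groups_path).values()
                    )
        else:
            errors.append(f"dataset {name!r}: needs 'simulate' or 'counts'+'groups'")
        if labels_available is not None:
            for side in ("a", "b"):
                if contrast[side] not in labels_available:
                    errors.append(
                        f"dataset {name!r}: contrast label {contrast[side]!r} "
                        f"not among group labels {sorted(labels_available)}"
                    )
        datasets.append(
            DatasetConfig(
                str(name), (contrast["a"], contrast["b"]), sim, counts_path, groups_path
            )
        )

    for section, allowed in (
        ("normalization", _NORM_KEYS),
        ("deg", _DEG_KEYS),
        ("enrichment", _ENRICH_KEYS),
    ):
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            errors.append(f"{section!r} must be a mapping")
            continue
        for key in sub:
            if key not in allowed:
                errors.append(f"{section}: unknown key {key!r}")
    adjust = raw.get("deg", {}).get("adjust", "BH")
    if adjust not in ("none", "BH"):
        errors.append(f"deg.adjust must be 'none' or 'BH', got {adjust!r}")

    enrich = raw.get("enrichment", {}) if isinstance(raw.get("enrichment", {}), dict) else {}
    gmt_path = None
    if "gmt" in enrich:
        gmt_path = base / enrich["gmt"]
        if not gmt_path.is_file():
            errors.append(f"enrichment GMT not found: {gmt_path}")

    gene_lists: dict[str, Path] = {}
    for lname, lpath in (raw.get("gene_lists") or {}).items():
        p = base / lpath
        if not p.is_file():
            errors.append(f"gene list {lname!r} not found: {p}")
        gene_lists[str(lname)] = p

    if errors:
        raise ConfigError(errors)

    enrich_resolved = dict(enrich)
    if gmt_path is not None:
        enrich_resolved["gmt"] = gmt_path
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=base / str(raw["output_dir"]),
        datasets=datasets,
        normalization=dict(raw.get("normalization", {})),
        deg=dict(raw.get("deg", {})),
        enrichment=enrich_resolved,
        gene_lists=gene_lists,
        plots=bool(raw.get("plots", False)),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_simulate(
    ds: DatasetConfig, seed: int, outdir: Path
) -> tuple[CountMatrix, Path]:
    if ds.simulate is not None:
        sim = dict(ds.simulate)
        for key in ("baseline_log2_mean_range", "library_size_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        spec = DesignSpec(seed=seed, **sim)
        cm, truth = simulate_experiment(spec)
        counts_path = outdir / "counts.tsv"
        cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
        with open(outdir / "groups.tsv", "w") as fh:
            for s, g in cm.groups.items():
                fh.write(f"{s}\t{g}\n")
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        return cm, counts_path
    cm = io_formats.read_count_table(ds.counts)
    cm.groups = io_formats.read_group_file(ds.groups)
    return cm, ds.counts


def _normalize(cm: CountMatrix, params: dict[str, Any]):
    m = normalization.compute_cpm(cm)
    if params.get("filter", True):
        m = normalization.filter_low_expression(
            m,
            min_cpm=params.get("min_cpm", 1.0),
            min_samples=params.get("min_samples"),
        )
    m = normalization.log2_transform(m, pseudocount=params.get("pseudocount", 1.0))
    return normalization.quantile_normalize(m)


def _volcano(result: deg_stats.DegResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    st = result.statistics
    colors = st["call"].map({"up": "tab:red", "down": "tab:blue", "ns": "0.7"})
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(st["lmr"], -np.log10(st["overall_p"]), s=6, c=colors, linewidths=0)
    ax.axvline(result.lmr_cutoff, ls="--", lw=0.8, c="k")
    ax.axvline(-result.lmr_cutoff, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2-median-ratio")
    ax.set_ylabel("-log10 overall p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis described by ``config``.

    Returns the output directory.  Layout: one subdirectory per dataset
    (counts/normalized/DEG/enrichment tables), a ``comparisons``
    subdirectory for the pairwise overlap tables, and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "normalization": config.normalization,
            "deg": config.deg,
            "enrichment": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in config.enrichment.items()
            },
        },
        "datasets": {},
        "inputs": {},
        "outputs": [],
    }

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    gmt = None
    if "gmt" in config.enrichment:
        gmt = io_formats.read_gmt(config.enrichment["gmt"])
        manifest["inputs"][str(config.enrichment["gmt"])] = _sha256(
            Path(config.enrichment["gmt"])
        )

    results: dict[str, deg_stats.DegResult] = {}
    for index, ds in enumerate(config.datasets):
        ds_dir = out / ds.name
        ds_dir.mkdir(exist_ok=True)
        seed = _dataset_seed(config.seed, index)
        cm, counts_path = _load_or_simulate(ds, seed, ds_dir)
        if ds.simulate is None:
            manifest["inputs"][str(counts_path)] = _sha256(counts_path)
        m = _normalize(cm, config.normalization)
        write_table(
            m.values.round(8), record(ds_dir / "normalized.tsv"), index=True
        )
        contrast = deg_stats.ContrastSpec.from_groups(
            m.groups,
            ds.contrast[0],
            ds.contrast[1],
            n_resamples=config.deg.get("n_resamples", 1000),
            seed=seed,
            alpha=config.deg.get("alpha", 0.05),
            adjust=config.deg.get("adjust", "BH"),
        )
        result = deg_stats.call_degs(m, contrast)
        results[ds.name] = result
        io_formats.write_deg_table(result, record(ds_dir / "deg.tsv"))
        n_up, n_down = result.counts
        manifest["datasets"][ds.name] = {
            "seed": seed,
            "contrast": list(ds.contrast),
            "n_genes": int(m.shape[0]),
            "n_resamples_effective": result.null_t.n_resamples_effective,
            "null_scheme": result.null_t.scheme,
            "lmr_cutoff": round(result.lmr_cutoff, 8),
            "n_up": n_up,
            "n_down": n_down,
        }
        if config.plots:
            _volcano(result, record(ds_dir / "volcano.png"))

        for list_name, list_path in config.gene_lists.items():
            members = io_formats.read_gene_list(list_path)
            manifest["inputs"].setdefault(str(list_path), _sha256(list_path))
            try:
                sub = set_ops.filter_by_gene_list(result, members, list_name)
            except ValueError as exc:
                logger.warning("dataset %s, list %s: %s", ds.name, list_name, exc)
                continue
            io_formats.write_deg_table(
                sub, record(ds_dir / f"deg_{list_name}.tsv")
            )

        if gmt is not None:
            universe = list(m.gene_ids)
            ease = bool(config.enrichment.get("ease", False))
            for direction in ("up", "down"):
                query = result.genes(direction)
                if not query:
                    logger.info(
                        "dataset %s: no %sregulated DEGs; ORA skipped",
                        ds.name,
                        direction,
                    )
                    continue
                try:
                    ora = enrichment.run_ora(query, universe, gmt, ease=ease)
                except ValueError as exc:
                    logger.warning("dataset %s ORA (%s): %s", ds.name, direction, exc)
                    continue
                write_table(ora, record(ds_dir / f"ora_{direction}.tsv"))
            ranks = enrichment.rank_genes_for_gsea(result.statistics)
            try:
                gsea = enrichment.run_gsea(
                    list(ranks.index),
                    ranks.to_numpy(),
                    gmt,
                    n_perm=config.enrichment.get("n_perm", 10000),
                    min_size=config.enrichment.get("min_size", 3),
                    max_size=config.enrichment.get("max_size", 800),
                    p_cutoff=config.enrichment.get("p_cutoff", 0.05),
                    weight=config.enrichment.get("weight", 1.0),
                    seed=seed,
                )
            except ValueError as exc:
                logger.warning("dataset %s GSEA: %s", ds.name, exc)
            else:
                write_table(gsea, record(ds_dir / "gsea.tsv"))

    # pairwise directional comparisons
    if len(results) > 1:
        cmp_dir = out / "comparisons"
        cmp_dir.mkdir(exist_ok=True)
        names = list(results)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = set_ops.DegList.from_deg_result(results[names[i]], names[i])
                b = set_ops.DegList.from_deg_result(results[names[j]], names[j])
                rows = []
                for direction in ("up", "down", "any"):
                    common, only_a, only_b = set_ops.overlap(a, b, direction)
                    regions = set_ops.venn_regions([a, b], direction)
                    rows.append(
                        {
                            "direction": direction,
                            "common": len(common),
                            f"only_{names[i]}": len(only_a),
                            f"only_{names[j]}": len(only_b),
                            "union": sum(regions.values()),
                            "common_genes": "|".join(sorted(common)),
                        }
                    )
                down_up, up_down = set_ops.cross_contrast_reversal(a, b)
                rows.append(
                    {
                        "direction": "reversal",
                        "common": len(down_up) + len(up_down),
                        f"only_{names[i]}": 0,
                        f"only_{names[j]}": 0,
                        "union": len(down_up) + len(up_down),
                        "common_genes": "|".join(
                            sorted(f"{g}:down_then_up" for g in down_up)
                            + sorted(f"{g}:up_then_down" for g in up_down)
                        ),
                    }
                )
                write_table(
                    pd.DataFrame(rows),
                    record(cmp_dir / f"overlap_{names[i]}_vs_{names[j]}.tsv"),
                )

    manifest["outputs"] = sorted(manifest["outputs"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished: %d dataset(s) -> %s", len(results), out)
    return out
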