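"""End-to-end analysis pipeline with a reproducible run manifest.

Stage order: data (generate or load) -> min-count filter -> distance
matrices -> embedding sweeps -> trajectory metrics -> dimension diagnostics
-> inference (global/soil-wise PERMANOVA, dimension-swept PERMANOVA on
RPCA-reconstructed distances, inoculant-exclusion reanalysis, alpha
diversity).  Every numeric artifact is written as TSV/JSON and recorded in
the manifest with a sha256 checksum, so identical config + seed implies
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from . import io as oio
from ._seeding import substream_seed
from .diagnostics import sweep_diagnostics
from .distances import bray_curtis, rclr_transform, weighted_unifrac
from .inference import (
    alpha_diversity_table,
    exclude_feature_and_renormalize,
    permanova,
    permanova_sweep,
)
from .ordination import DEFAULT_DIMENSIONS, sweep_embeddings
from .synthetic import (
    DesignSpec,
    EffectSpec,
    apply_min_count_filter,
    generate_counts,
    generate_metadata,
    generate_tree,
)
from .trajectory import sweep_trajectory_metrics

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs"]

_KNOWN_METHODS = ("pcoa", "sammon", "nmds", "rpca", "umap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults reproduce the emulated study design."""

    design: DesignSpec = field(default_factory=DesignSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    table_path: str | None = None      # load instead of simulate when set
    metadata_path: str | None = None
    tree_path: str | None = None
    min_count: int = 10
    metrics: tuple[str, ...] = ("braycurtis", "wunifrac")
    unifrac_normalized: bool = True
    methods: tuple[str, ...] = ("pcoa", "sammon", "nmds", "rpca")
    dimensions: tuple[int, ...] = DEFAULT_DIMENSIONS
    reference_metric: str = "wunifrac"   # trajectory/diagnostic source
    reference_method: str = "sammon"
    nmds_starts: int = 20
    knn_k: int = 5
    hopkins_m: int = 50
    n_perm: int = 999
    seed: int = 0
    outdir: str = "ordgeom_run"

    def validate(self) -> None:
        for m in self.methods:
            if m not in _KNOWN_METHODS:
                raise ValueError(f"unknown embedding method {m!r}")
        for m in self.metrics:
            if m not in ("braycurtis", "wunifrac"):
                raise ValueError(f"unknown distance metric {m!r}")
        if not self.dimensions:
            raise ValueError("empty dimension list")
        if any(b <= a for a, b in zip(self.dimensions, self.dimensions[1:])):
            raise ValueError("dimensions must be strictly increasing")
        if self.reference_metric not in self.metrics:
            raise ValueError("reference_metric not among metrics")
        if self.reference_method not in self.methods:
            raise ValueError("reference_method not among methods")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(
    table: pd.DataFrame, metadata: pd.DataFrame, tree: TreeNode | None = None
) -> dict:
    """Cross-check table/metadata/tree agreement; fatal vs warning report."""
    fatal, warn = [], []
    missing_meta = [s for s in table.index if s not in metadata.index]
    if missing_meta:
        fatal.append(f"samples missing from metadata: {missing_meta}")
    extra_meta = [s for s in metadata.index if s not in table.index]
    if extra_meta:
        warn.append(f"metadata rows without table samples: {extra_meta}")
    for col in ("soil", "treatment", "day", "replicate"):
        if col not in metadata.columns:
            fatal.append(f"metadata lacks required column {col!r}")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        nonzero = set(table.columns[(table.sum(axis=0) > 0).to_numpy()])
        zero = set(table.columns) - nonzero
        miss_nz = sorted(nonzero - tips)
        if miss_nz:
            fatal.append(f"nonzero features absent from tree: {miss_nz[:10]}")
        miss_z = sorted(zero - tips)
        if miss_z:
            warn.append(f"zero-count features absent from tree: {miss_z[:10]}")
    return {"fatal": fatal, "warnings": warn}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the manifest (also written to the outdir).

    Any stage error aborts with the stage name; artifacts of completed
    stages persist in the output directory.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "package": "ordgeom",
        "seed": config.seed,
        "config": _config_dict(config),
        "artifacts": {},
        "skipped_dimensions": {},
        "stages": [],
    }

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    stage = "data"
    try:
        if config.table_path:
            table = oio.read_count_table(config.table_path)
            metadata = oio.read_metadata(config.metadata_path)
            tree = oio.read_tree(config.tree_path) if config.tree_path else None
        else:
            design, effects = config.design, config.effects
            metadata = generate_metadata(design)
            table = generate_counts(design, effects)
            tree = generate_tree(design.n_features, seed=design.seed)
        report = validate_inputs(table, metadata, tree)
        if report["fatal"]:
            raise ValueError("; ".join(report["fatal"]))
        oio.write_count_table(table, out / "counts.tsv")
        oio.write_metadata(metadata, out / "metadata.tsv")
        record("counts", out / "counts.tsv")
        record("metadata", out / "metadata.tsv")
        if tree is not None:
            oio.write_tree(tree, out / "tree.nwk")
            record("tree", out / "tree.nwk")
        manifest["stages"].append(stage)

        stage = "filter"
        filtered = apply_min_count_filter(table, config.min_count)
        oio.write_count_table(filtered, out / "counts.filtered.tsv")
        record("counts_filtered", out / "counts.filtered.tsv")
        manifest["stages"].append(stage)

        stage = "distances"
        dms = {}
        for metric in config.metrics:
            if metric == "braycurtis":
                dms[metric] = bray_curtis(filtered)
            else:
                if tree is None:
                    raise ValueError("weighted UniFrac requires a tree")
                dms[metric] = weighted_unifrac(
                    filtered, tree, normalized=config.unifrac_normalized
                )
            p = out / f"distance.{metric}.tsv"
            oio.write_distance_matrix(dms[metric], p)
            record(f"distance_{metric}", p)
        manifest["stages"].append(stage)

        stage = "embeddings"
        sweeps = {}  # (metric_or_table, method) -> EmbeddingSweep
        for method in config.methods:
            if method == "rpca":
                key = ("table", "rpca")
                sweeps[key] = sweep_embeddings(
                    filtered, "rpca", config.dimensions,
                    seed=substream_seed(config.seed, "embed-rpca"),
                )
                _write_sweep(sweeps[key], out, "rpca.table", record, manifest)
            else:
                for metric in config.metrics:
                    key = (metric, method)
                    params = {}
                    if method in ("sammon", "nmds", "umap"):
                        params["seed"] = substream_seed(
                            config.seed, f"embed-{method}-{metric}"
                        )
                    if method == "nmds":
                        params["n_starts"] = config.nmds_starts
                    sweeps[key] = sweep_embeddings(
                        dms[metric], method, config.dimensions, **params
                    )
                    _write_sweep(
                        sweeps[key], out, f"{method}.{metric}", record, manifest
                    )
        manifest["stages"].append(stage)

        stage = "trajectory"
        ref = sweeps[(config.reference_metric, config.reference_method)]
        days = sorted(metadata["day"].unique().tolist())
        segments = list(zip(days[:-1], days[1:]))
        intervals = [(days[0], days[-1])] + segments
        traj = sweep_trajectory_metrics(ref.embeddings, metadata, intervals)
        traj.to_csv(out / "trajectory_metrics.tsv", sep="\t", index=False)
        record("trajectory_metrics", out / "trajectory_metrics.tsv")
        manifest["stages"].append(stage)

        stage = "diagnostics"
        diag = sweep_diagnostics(
            ref.embeddings, metadata, k=config.knn_k, m=config.hopkins_m,
            seed=substream_seed(config.seed, "hopkins"),
        )
        diag.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        record("diagnostics", out / "diagnostics.tsv")
        manifest["stages"].append(stage)

        stage = "inference"
        rows = []
        for metric, D in dms.items():
            res = permanova(D, metadata, ["soil", "day", "treatment"],
                            n_perm=config.n_perm,
                            seed=substream_seed(config.seed, f"perm-{metric}"))
            for term in ("soil", "day", "treatment"):
                rows.append(dict(metric=metric, scope="global", term=term,
                                 R2=res.r2(term), F=res.f(term),
                                 p=res.p_value(term)))
            for soil, grp in metadata.groupby("soil", sort=True):
                sub = D.filter(grp.index.tolist())
                r = permanova(sub, grp, ["treatment"], n_perm=config.n_perm,
                              seed=substream_seed(config.seed, f"perm-{metric}-{soil}"))
                rows.append(dict(metric=metric, scope=str(soil),
                                 term="treatment", R2=r.r2("treatment"),
                                 F=r.f("treatment"), p=r.p_value("treatment")))
        pd.DataFrame(rows).to_csv(out / "permanova.tsv", sep="\t", index=False)
        record("permanova", out / "permanova.tsv")

        if ("table", "rpca") in sweeps:
            sweep_tab = permanova_sweep(
                sweeps[("table", "rpca")].embeddings, metadata,
                n_perm=config.n_perm,
                seed=substream_seed(config.seed, "perm-sweep"),
            )
            sweep_tab.to_csv(out / "permanova_sweep.rpca.tsv", sep="\t",
                             index=False)
            record("permanova_sweep_rpca", out / "permanova_sweep.rpca.tsv")

        # inoculant-exclusion reanalysis (soil-wise treatment R2, Bray-Curtis)
        ino = config.effects.inoculant_feature_id
        if not config.table_path and ino in filtered.columns:
            excl = exclude_feature_and_renormalize(filtered, [ino])
            rows = []
            for label, tab in (("all_features", filtered),
                               ("without_inoculant", excl)):
                D = bray_curtis(tab)
                for soil, grp in metadata.groupby("soil", sort=True):
                    sub = D.filter(grp.index.tolist())
                    r = permanova(sub, grp, ["treatment"], n_perm=config.n_perm,
                                  seed=substream_seed(config.seed,
                                                      f"perm-excl-{soil}"))
                    rows.append(dict(dataset=label, soil=str(soil),
                                     R2=r.r2("treatment"),
                                     p=r.p_value("treatment")))
            pd.DataFrame(rows).to_csv(out / "exclusion_reanalysis.tsv",
                                      sep="\t", index=False)
            record("exclusion_reanalysis", out / "exclusion_reanalysis.tsv")

        alpha = alpha_diversity_table(filtered)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t",
                     index_label="sample_id")
        record("alpha_diversity", out / "alpha_diversity.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise PipelineError(stage, exc) from exc

    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _write_sweep(sweep, out: Path, label: str, record, manifest) -> None:
    for E in sweep.embeddings:
        p = out / f"embedding.{label}.d{E.dimension}.tsv"
        oio.write_embedding(E, p)
        record(f"embedding_{label}_d{E.dimension}", p)
    if sweep.skipped:
        manifest["skipped_dimensions"][label] = {
            str(d): reason for d, reason in sweep.skipped.items()
        }


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["design"] = config.design.to_dict()
    d["effects"] = config.effects.to_dict()
    return d
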