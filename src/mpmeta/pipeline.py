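"""End-to-end orchestration of the cross-cohort analysis.

A single structured config (YAML) drives the full sequence: simulate or read
peptide tables -> domain filter -> renormalize -> aggregate (taxa, functions,
taxon-functions) -> summarize -> correlation meta-analysis -> phylum contrast
-> genus specificity -> attribution matrix.  Every output is a TSV under the
run directory and a manifest records the config, seed, stage tallies and
sha256 checksums, so identical config + seed gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate as agg
from . import core_rank, corr_meta, taxon_attrib
from .peptide_io import (
    filter_microbial,
    read_ko_pathway_map,
    read_peptide_table,
    renormalize,
    write_ko_pathway_map,
    write_peptide_table,
)
from .synthetic import SimConfig, default_pathway_map, simulate_cohorts

logger = logging.getLogger(__name__)

STAGES = (
    "load", "filter", "renormalize", "aggregate",
    "summarize", "corr_meta", "phylum_contrast", "specificity", "attribution",
)


@dataclass
class RunConfig:
    """Full-run configuration with the analysis thresholds in one place."""

    out_dir: str
    seed: int = 0
    dataset_paths: list[str] = field(default_factory=list)
    pathway_map_path: str | None = None
    simulate: dict | None = None          # SimConfig fields; used when no paths
    alpha: float = 0.05
    top_ko_n: int = 50
    top_ko_min_mean_det: float = 0.75
    pathway_min_mean_pct: float = 1.0
    variability_min_mean_pct: float = 0.01
    specificity_missing_max: float = 0.5
    specificity_specific_min: float = 0.9
    specificity_shared_max: float = 0.75
    attribution_min_datasets: int = 6
    attribution_min_mean_pct: float = 0.001
    attribution_ko_list: list[str] | None = None
    ribosomal_kos: list[str] = field(default_factory=list)
    variance_model: str = "zcor"
    knapp_hartung: bool = False
    log_base: float = 2.718281828459045
    contrast_phyla: tuple[str, str] = ("Bacillota", "Bacteroidota")

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.dataset_paths and self.simulate is None:
            raise ValueError("either dataset_paths or a simulate block is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "contrast_phyla" in raw:
            raw["contrast_phyla"] = tuple(raw["contrast_phyla"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    # validation first: fail before any stage runs
    for p in config.dataset_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"dataset path does not exist: {p}")
    if config.pathway_map_path and not Path(config.pathway_map_path).exists():
        raise FileNotFoundError(
            f"pathway map path does not exist: {config.pathway_map_path}"
        )
    out.mkdir(parents=True, exist_ok=True)
    import numpy, pandas, scipy

    from . import __version__
    manifest: dict = {
        "seed": config.seed, "stages": {}, "outputs": {},
        "config": {k: v for k, v in vars(config).items()},
        "versions": {
            "mpmeta": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
        },
    }

    def done(stage, **counts):
        manifest["stages"][stage] = {"status": "completed", **counts}
        logger.info("stage %s completed: %s", stage, counts)

    try:
        # --- load / simulate ---
        if config.dataset_paths:
            datasets = [read_peptide_table(p) for p in config.dataset_paths]
            pathway_map = (
                read_ko_pathway_map(config.pathway_map_path)
                if config.pathway_map_path else {}
            )
        else:
            sim_cfg = SimConfig(**{**(config.simulate or {}), "seed": config.seed})
            datasets, gt = simulate_cohorts(sim_cfg)
            pathway_map = default_pathway_map(sim_cfg)
            sim_dir = out / "simulated"
            sim_dir.mkdir(exist_ok=True)
            for ds in datasets:
                write_peptide_table(ds, sim_dir / f"{ds.dataset_id}.tsv")
            gt.to_dir(sim_dir / "ground_truth")
            write_ko_pathway_map(pathway_map, sim_dir / "pathway_map.tsv")
        done("load", n_datasets=len(datasets),
             n_peptides=sum(len(d.peptides) for d in datasets))

        # --- filter + renormalize ---
        filtered = [filter_microbial(d) for d in datasets]
        done("filter", n_peptides=sum(len(d.peptides) for d in filtered))
        normed = [renormalize(d) for d in filtered]
        done("renormalize", n_datasets=len(normed))

        # --- aggregate ---
        tables: dict[str, list[agg.FeatureTable]] = {}
        tables["phylum"] = [agg.aggregate_taxa(d, "phylum") for d in normed]
        tables["genus"] = [agg.aggregate_taxa(d, "genus") for d in normed]
        tables["KO"] = [agg.aggregate_functions(d, "KO") for d in normed]
        tables["pathway"] = [
            agg.aggregate_functions(d, "pathway", pathway_map) for d in normed
        ]
        tables["phylum-KO"] = [
            agg.aggregate_taxon_function(d, "phylum", "KO") for d in normed
        ]
        tables["genus-KO"] = [
            agg.aggregate_taxon_function(d, "genus", "KO") for d in normed
        ]
        tables["deepest-KO"] = [
            agg.aggregate_deepest_taxon_function(d, "KO") for d in normed
        ]
        tdir = out / "tables"
        tdir.mkdir(exist_ok=True)
        for cls, tabs in tables.items():
            for t in tabs:
                agg.write_feature_table(t, tdir / f"{cls}_{t.dataset_id}.tsv")
        done("aggregate", n_classes=len(tables))

        # --- summarize ---
        summaries = {}
        for cls in ("phylum", "genus", "KO", "pathway"):
            s = core_rank.summarize_features(tables[cls])
            summaries[cls] = s
            core_rank.write_summary(s, cls, out / f"summary_{cls}.tsv")
        done("summarize", **{
            f"core_subjects_{c}": int(s["core_subjects"].sum())
            for c, s in summaries.items()
        })

        # --- correlation meta-analysis ---
        top_ko = corr_meta.select_top_ko(
            summaries["KO"], n=config.top_ko_n,
            min_mean_det=config.top_ko_min_mean_det,
            ribosomal_kos=frozenset(config.ribosomal_kos),
        )
        ko_meta = corr_meta.meta_correlate(
            tables["KO"], top_ko, alpha=config.alpha,
            variance_model=config.variance_model,
            knapp_hartung=config.knapp_hartung,
        )
        ko_meta.to_csv(out / "corr_meta_KO.tsv", sep="\t", index=False)
        pws = corr_meta.select_pathways(
            summaries["pathway"], min_mean_pct=config.pathway_min_mean_pct
        )
        pw_meta = (
            corr_meta.meta_correlate(tables["pathway"], pws, alpha=config.alpha)
            if len(pws) >= 2 else pd.DataFrame()
        )
        pw_meta.to_csv(out / "corr_meta_pathway.tsv", sep="\t", index=False)
        done("corr_meta",
             n_ko_pairs=len(ko_meta),
             n_ko_significant=int(ko_meta["significant"].sum()) if len(ko_meta) else 0,
             n_pw_pairs=len(pw_meta),
             n_pw_significant=int(pw_meta["significant"].sum()) if len(pw_meta) else 0)

        # --- phylum contrast ---
        contrast = taxon_attrib.phylum_contrast(
            tables["phylum-KO"], *config.contrast_phyla, log_base=config.log_base
        )
        contrast.to_csv(out / "phylum_contrast_KO.tsv", sep="\t", index=False)
        done("phylum_contrast", n_functions=len(contrast))

        # --- genus specificity ---
        spec = taxon_attrib.genus_specificity(
            tables["genus-KO"],
            missing_max=config.specificity_missing_max,
            specific_min=config.specificity_specific_min,
            shared_max=config.specificity_shared_max,
        )
        spec.to_csv(out / "genus_specificity.tsv", sep="\t", index=False)
        counts = spec["class"].value_counts().to_dict() if len(spec) else {}
        done("specificity", **{f"n_{k}": int(v) for k, v in counts.items()})

        # --- attribution matrix ---
        ko_list = config.attribution_ko_list or list(summaries["KO"].index)
        attr = taxon_attrib.attribution_matrix(
            tables["deepest-KO"], ko_list,
            plain_ko_tables=tables["KO"],
            min_datasets=config.attribution_min_datasets,
            min_mean_pct=config.attribution_min_mean_pct,
        )
        attr.to_csv(out / "attribution_matrix.tsv", sep="\t")
        taxon_attrib.attribution_long(attr).to_csv(
            out / "attribution_long.tsv", sep="\t", index=False
        )
        done("attribution", n_ko=attr.shape[1], n_taxa=max(attr.shape[0] - 1, 0))
    except Exception as e:
        failed = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {e}") from e

    for f in sorted(out.rglob("*.tsv")):
        manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
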