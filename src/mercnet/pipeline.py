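"""End-to-end pipeline: generate/load → validate → rarefy → metrics → network → associations.

One global seed fans out deterministically to per-stage child seeds
(metadata/community generation, rarefaction, module detection), so a stage
can be rerun in isolation and two runs with identical configuration and seed
produce byte-identical artifacts. Every stage writes its intermediate table
under ``output_dir`` and the run report records counts, thresholds, seeds
and the achieved modularity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mercnet._version import __version__
from mercnet.associations import (
    attribute_correlations,
    fit_gradient,
    land_use_anova,
    soil_pca,
)
from mercnet.errors import ConfigurationError
from mercnet.io import (
    CountTable,
    align_tables,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_metadata,
    write_taxonomy,
)
from mercnet.metrics import (
    aggregate_by_rank,
    observed_richness,
    rarefy,
    relative_abundance,
    shannon,
)
from mercnet.network import (
    build_network,
    detect_modules,
    filter_dominant_taxa,
    module_relative_abundance,
    recover_planted_modules,
    spearman_all_pairs,
    write_edge_list,
    write_graphml,
    write_membership,
)
from mercnet.synthetic import DesignSpec, EffectSpec, generate_community, generate_metadata, write_module_truth

logger = logging.getLogger(__name__)

SOIL_VARS = ["ph", "soc", "tc", "tn", "c_n", "doc", "nh4", "no3"]


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2³¹) from the global seed."""
    return int(np.random.SeedSequence(seed, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run."""

    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    synthetic: bool = True
    rarefaction_depth: int = 30212
    coverage: float = 0.80
    rho_min: float = 0.25
    alpha: float = 0.01
    resolution: float = 1.0
    seed: int = 0
    output_dir: str = "mercnet_out"
    log10_hg: bool = True
    graphml: bool = False
    # synthetic-mode design knobs
    n_taxa: int = 300
    n_modules: int = 5
    depth_mean: int = 40000

    def validate(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ConfigurationError("rarefaction_depth must be positive")
        if not 0 < self.coverage <= 1:
            raise ConfigurationError(f"coverage must be in (0, 1], got {self.coverage}")
        if not -1 <= self.rho_min <= 1:
            raise ConfigurationError(f"rho_min must be in [-1, 1], got {self.rho_min}")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if not self.synthetic:
            for name in ("counts_path", "metadata_path"):
                if getattr(self, name) is None:
                    raise ConfigurationError(f"{name} required when synthetic mode is off")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _load_inputs(config: PipelineConfig, out: Path):
    if config.synthetic:
        design = DesignSpec(
            n_taxa=config.n_taxa,
            n_modules=config.n_modules,
            depth_mean=config.depth_mean,
            seed=stage_seed(config.seed, 0),
        )
        effects = EffectSpec()
        meta = generate_metadata(design, effects)
        counts, tax, truth = generate_community(design, effects, meta)
        write_module_truth(truth, out / "module_truth.tsv")
        return counts, meta, tax, truth
    counts = read_count_table(config.counts_path)
    meta = read_metadata(config.metadata_path)
    tax = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    counts, meta, tax, report = align_tables(counts, meta, tax)
    if report.dropped_samples_counts or report.dropped_samples_meta:
        logger.info(
            "alignment dropped %d count samples, %d metadata samples",
            len(report.dropped_samples_counts),
            len(report.dropped_samples_meta),
        )
    return counts, meta, tax, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the machine-readable run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }

    counts, meta, tax, truth = _load_inputs(config, out)
    write_count_table(counts, out / "counts.tsv")
    write_metadata(meta, out / "metadata.tsv")
    if tax is not None:
        write_taxonomy(tax, out / "taxonomy.tsv")
    report["stages"]["input"] = {
        "n_samples": counts.shape[0],
        "n_taxa": counts.shape[1],
        "n_paddy": int((meta["land_use"] == "paddy").sum()),
        "n_upland": int((meta["land_use"] == "upland").sum()),
    }

    rare = rarefy(counts, config.rarefaction_depth, seed=stage_seed(config.seed, 1))
    write_count_table(rare, out / "rarefied.tsv")
    report["stages"]["rarefaction"] = {
        "depth": config.rarefaction_depth,
        "seed": stage_seed(config.seed, 1),
        "n_taxa_observed": int((rare.data.sum(axis=0) > 0).sum()),
    }

    div = pd.DataFrame(
        {
            "depth": rare.sample_totals(),
            "richness": observed_richness(rare),
            "shannon": shannon(rare),
        }
    )
    div.index.name = "sample_id"
    div.to_csv(out / "diversity.tsv", sep="\t")
    report["stages"]["metrics"] = {"mean_shannon": float(div["shannon"].mean())}

    rel = relative_abundance(rare)
    dominant = filter_dominant_taxa(rel, coverage=config.coverage)
    corr = spearman_all_pairs(dominant)
    net = build_network(corr, rho_min=config.rho_min, alpha=config.alpha)
    net = detect_modules(net, resolution=config.resolution, seed=stage_seed(config.seed, 2))
    write_edge_list(net, out / "edges.tsv")
    write_membership(net, out / "membership.tsv", tax=tax)
    if config.graphml:
        write_graphml(net, out / "network.graphml")
    report["stages"]["network"] = {
        "n_taxa_dominant": dominant.shape[1],
        "n_tested_pairs": net.n_tested_pairs,
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "n_modules": net.n_modules,
        "n_major_modules": len(net.major_modules()),
        "major_module_sizes": [net.module_sizes()[m] for m in net.major_modules()],
        "modularity": net.modularity,
        "louvain_seed": stage_seed(config.seed, 2),
    }
    if truth is not None:
        report["stages"]["network"]["planted_ari"] = recover_planted_modules(net, truth)

    profile = module_relative_abundance(rel, net)
    profile.values.index.name = "sample_id"
    profile.values.to_csv(out / "module_profile.tsv", sep="\t")

    # association layer: fits, correlation tables, ANOVA, soil PCA
    paddy = (meta["land_use"] == "paddy").to_numpy()
    upland = (meta["land_use"] == "upland").to_numpy()
    ab_col = (
        "log10_bacterial_abundance"
        if "log10_bacterial_abundance" in meta.columns
        else "bacterial_abundance"
    )
    fits = []
    for label, mask, model in (
        ("paddy", paddy, "linear"),
        ("upland", upland, "linear"),
    ):
        fit = fit_gradient(
            meta[ab_col], meta["total_hg"], model=model,
            log10_predictor=config.log10_hg, subset=mask,
        )
        fits.append(("bacterial_abundance", "total_hg", label, fit))
    fits.append(
        (
            "shannon",
            "total_hg",
            "paddy",
            fit_gradient(div["shannon"], meta["total_hg"], model="linear",
                         log10_predictor=config.log10_hg, subset=paddy),
        )
    )
    fits.append(
        (
            "shannon",
            "total_hg",
            "upland",
            fit_gradient(div["shannon"], meta["total_hg"], model="cubic",
                         log10_predictor=config.log10_hg, subset=upland),
        )
    )
    fit_rows = [
        {
            "response": resp,
            "predictor": pred,
            "subset": label,
            "model": f.model,
            "slope": f.slope,
            "df_model": f.df_model,
            "df_resid": f.df_resid,
            "F": f.f,
            "p": f.p,
            "r2": f.r2,
            "n": f.n,
        }
        for resp, pred, label, f in fits
    ]
    pd.DataFrame(fit_rows).to_csv(out / "fits.tsv", sep="\t", index=False)

    env = pd.DataFrame(
        {
            "total_hg": np.log10(meta["total_hg"]) if config.log10_hg else meta["total_hg"],
            "mehg": np.log10(meta["mehg"]) if config.log10_hg else meta["mehg"],
        },
        index=meta.index,
    )
    attributes = profile.values.copy()
    attributes["shannon"] = div["shannon"]
    attributes["bacterial_abundance"] = meta[ab_col]
    if tax is not None:
        phyla = aggregate_by_rank(rel, tax, "phylum")
        attributes = attributes.join(phyla.add_prefix("phylum_"))
    corr_table = attribute_correlations(attributes, env, method="pearson")
    corr_table.coef.to_csv(out / "correlations.tsv", sep="\t")
    corr_table.p.to_csv(out / "correlations_p.tsv", sep="\t")

    anova_rows = []
    for col in [ab_col, "shannon"] + list(profile.values.columns):
        series = div["shannon"] if col == "shannon" else (
            meta[ab_col] if col == ab_col else profile.values[col]
        )
        res = land_use_anova(series, meta)
        anova_rows.append(
            {
                "attribute": col,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "F": res.f,
                "p": res.p,
                **{f"mean_{k}": v for k, v in res.group_means.items()},
            }
        )
    pd.DataFrame(anova_rows).to_csv(out / "anova.tsv", sep="\t", index=False)

    soil_cols = [c for c in SOIL_VARS if c in meta.columns]
    pca = soil_pca(meta[soil_cols])
    pca.loadings.to_csv(out / "soil_pca_loadings.tsv", sep="\t")
    pca.scores.to_csv(out / "soil_pca_scores.tsv", sep="\t")
    report["stages"]["associations"] = {
        "n_fits": len(fit_rows),
        "n_anova": len(anova_rows),
        "pca_variance_explained": [float(v) for v in pca.variance_explained],
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
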