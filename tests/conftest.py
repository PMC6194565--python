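"""Shared fixtures: tiny hand tables and a multi-seed synthetic sweep.

The seed sweep runs the reduced-scale end-to-end pipeline (300 taxa,
test-mode rarefaction depth 2,000) once per seed and caches the summary
statistics that several stochastic checks share, so the suite pays the
simulation cost a single time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mercnet import (
    CountTable,
    build_network,
    detect_modules,
    filter_dominant_taxa,
    fit_gradient,
    generate_community,
    generate_metadata,
    match_modules_to_truth,
    module_relative_abundance,
    rarefy,
    recover_planted_modules,
    relative_abundance,
    spearman_all_pairs,
)
from mercnet.metrics import aggregate_by_rank
from mercnet.synthetic import DesignSpec, EffectSpec

N_SWEEP_SEEDS = 50
TEST_DEPTH = 2000


@pytest.fixture
def tiny_counts() -> CountTable:
    """3 samples × 4 taxa with unequal library sizes."""
    df = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 85], [25, 25, 25, 25]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CountTable(df)


@pytest.fixture
def tiny_taxonomy() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": ["PhA", "PhA", "PhB", "PhB"],
            "class": "unclassified",
            "order": "unclassified",
            "family": "unclassified",
            "genus": ["g1", "g2", "g3", "g4"],
        },
        index=pd.Index(["t1", "t2", "t3", "t4"], name="taxon_id"),
    )


@dataclass
class SweepResult:
    n_major_modules: int
    ari: float
    mod4_profile_mehg_corr: float | None
    nitrospirae_mehg_corr: float
    abundance_slope_paddy: float
    abundance_slope_upland: float


def _run_one_seed(seed: int) -> SweepResult:
    design = DesignSpec(n_taxa=300, depth_mean=int(TEST_DEPTH * 1.3), seed=seed)
    effects = EffectSpec()
    meta = generate_metadata(design, effects)
    counts, tax, truth = generate_community(design, effects, meta)
    rare = rarefy(counts, TEST_DEPTH, seed=seed)
    rel = relative_abundance(rare)
    dominant = filter_dominant_taxa(rel, coverage=0.80)
    net = detect_modules(build_network(spearman_all_pairs(dominant)), seed=seed)
    ari = recover_planted_modules(net, truth)
    match = match_modules_to_truth(net, truth)
    profile = module_relative_abundance(rel, net)
    log_mehg = np.log10(meta["mehg"])
    mod4 = [m for m, planted in match.items() if planted == 4]
    mod4_corr = None
    if mod4:
        mod4_corr = float(
            stats.pearsonr(profile.values[f"module_{mod4[0]}"], log_mehg)[0]
        )
    phyla = aggregate_by_rank(rel, tax, "phylum")
    nitro_corr = float(stats.pearsonr(phyla["Nitrospirae"], log_mehg)[0])
    paddy = (meta["land_use"] == "paddy").to_numpy()
    upland = ~paddy
    slope_p = fit_gradient(
        meta["log10_bacterial_abundance"], meta["total_hg"], subset=paddy
    ).slope
    slope_u = fit_gradient(
        meta["log10_bacterial_abundance"], meta["total_hg"], subset=upland
    ).slope
    return SweepResult(
        n_major_modules=len(net.major_modules()),
        ari=ari,
        mod4_profile_mehg_corr=mod4_corr,
        nitrospirae_mehg_corr=nitro_corr,
        abundance_slope_paddy=slope_p,
        abundance_slope_upland=slope_u,
    )


@pytest.fixture(scope="session")
def seed_sweep() -> list[SweepResult]:
    return [_run_one_seed(seed) for seed in range(N_SWEEP_SEEDS)]
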