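"""Synthetic soil communities with planted co-occurrence modules on an Hg gradient.

The generator emulates the sampling design the analysis targets: 47 sites
(24 paddy, 23 upland) × 3 replicates = 141 samples, with site-level total Hg
drawn log-uniformly over 0.27–52.4 mg kg⁻¹ (pollution gradients are
multiplicative) and methylmercury a noisy power law of total Hg.

Community structure uses a latent-factor model. Each planted module has one
per-sample factor driven by the standardised log-Hg variables plus a
standard-normal innovation; a member taxon's log-abundance is its baseline
plus the module factor times a common loading plus independent noise, so
taxa in the same module co-vary positively across samples — the structure a
thresholded positive Spearman network is designed to recover. Log-abundances
pass through a per-sample softmax (the data are compositional) and integer
counts are multinomial at a drawn library size, always above the intended
rarefaction depth.

Phylum labels are assigned module-aware: the module rising with MeHg is
enriched in putatively Hg-tolerant phyla (Proteobacteria, Bacteroidetes,
Actinobacteria, Firmicutes) while the module declining with MeHg carries the
Nitrospirae, matching the field observation that nitrifiers are
metal-sensitive and fast-growing opportunists profit from disturbance.
Phylum-level slopes then add on top of the module factor, so phylum and
module signals reinforce rather than cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mercnet.errors import ConfigurationError
from mercnet.io import RANKS, CountTable

NEUTRAL_PHYLA = (
    "Proteobacteria",
    "Acidobacteria",
    "Actinobacteria",
    "Chloroflexi",
    "Verrucomicrobia",
    "Planctomycetes",
    "Gemmatimonadetes",
)


@dataclass
class DesignSpec:
    """Sampling design and gradient of the synthetic study."""

    n_paddy_sites: int = 24
    n_upland_sites: int = 23
    replicates_per_site: int = 3
    hg_min: float = 0.27  # mg kg⁻¹
    hg_max: float = 52.4  # mg kg⁻¹
    n_taxa: int = 300
    n_modules: int = 5
    depth_mean: int = 40000  # reads per sample
    seed: int = 0
    # replicate-level jitter on the site Hg value (coefficient of variation)
    hg_replicate_cv: float = 0.10
    # MeHg = coeff · THg^exponent · exp(ε), ε ~ N(0, noise_sd²); emitted in
    # mg kg⁻¹ — placeholders, the source study reports no MeHg units or range
    mehg_coeff: float = 0.01
    mehg_exponent: float = 0.7
    mehg_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        counts = {
            "n_paddy_sites": self.n_paddy_sites,
            "n_upland_sites": self.n_upland_sites,
            "replicates_per_site": self.replicates_per_site,
            "n_taxa": self.n_taxa,
            "n_modules": self.n_modules,
            "depth_mean": self.depth_mean,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if not self.hg_min < self.hg_max:
            raise ConfigurationError(
                f"hg_min must be below hg_max, got [{self.hg_min}, {self.hg_max}]"
            )
        if self.hg_min <= 0:
            raise ConfigurationError("hg_min must be positive")

    @property
    def n_sites(self) -> int:
        return self.n_paddy_sites + self.n_upland_sites

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.replicates_per_site


def _default_module_slopes() -> dict[int, tuple[float, float]]:
    # (slope on standardised log THg, slope on standardised log MeHg):
    # module 0 declines with MeHg, module 4 rises with MeHg; modules 2/3
    # respond to THg in opposite directions, module 1 mildly tracks both.
    # MeHg is a power law of THg, so the two standardised predictors are
    # nearly collinear; slope magnitudes stay well below the unit-variance
    # module innovation so between-module factor covariance remains small
    # and the planted modules stay separable in the correlation network.
    return {
        0: (0.0, -0.3),
        1: (0.15, 0.15),
        2: (-0.3, 0.0),
        3: (0.3, 0.0),
        4: (0.0, 0.3),
    }


def _default_phylum_slopes() -> dict[str, tuple[float, float]]:
    return {
        "Firmicutes": (0.4, 0.0),
        "Bacteroidetes": (0.4, 0.0),
        "Nitrospirae": (0.0, -0.4),
    }


@dataclass
class EffectSpec:
    """Effect sizes linking the gradient to community structure and attributes."""

    module_env_slopes: dict[int, tuple[float, float]] = field(
        default_factory=_default_module_slopes
    )
    phylum_env_slopes: dict[str, tuple[float, float]] = field(
        default_factory=_default_phylum_slopes
    )
    abundance_slope_on_logTHg: float = -0.5
    diversity_evenness_slope: float = 0.15
    noise_sd: float = 0.3
    within_module_factor_loading: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.within_module_factor_loading <= 1:
            raise ConfigurationError(
                "within_module_factor_loading must be in (0, 1], got "
                f"{self.within_module_factor_loading}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def _rng_for(design: DesignSpec, stream: int) -> np.random.Generator:
    # independent, reproducible per-stage streams from the one design seed
    return np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(stream,)))


def generate_metadata(design: DesignSpec, effects: EffectSpec | None = None) -> pd.DataFrame:
    """One metadata row per sample: design factors, Hg gradient, soil chemistry.

    Site-level total Hg is log-uniform on [hg_min, hg_max] and shared across a
    site's replicates up to a 10% lognormal-style jitter (clipped back to the
    range); MeHg is a noisy increasing power law of total Hg; soil covariates
    come from land-use-specific distributions; the qPCR-like bacterial
    abundance declines log-linearly with total Hg.
    """
    effects = effects or EffectSpec()
    rng = _rng_for(design, 0)
    rows: list[dict] = []
    site_specs: list[tuple[str, str]] = [
        (f"P{i + 1:02d}", "paddy") for i in range(design.n_paddy_sites)
    ] + [(f"U{i + 1:02d}", "upland") for i in range(design.n_upland_sites)]
    for site_id, land_use in site_specs:
        site_thg = float(
            np.exp(rng.uniform(np.log(design.hg_min), np.log(design.hg_max)))
        )
        lat = float(rng.normal(27.9, 0.35))
        lon = float(rng.normal(109.3, 0.5))
        paddy = land_use == "paddy"
        for rep in range(1, design.replicates_per_site + 1):
            thg = float(
                np.clip(
                    site_thg * (1.0 + design.hg_replicate_cv * rng.standard_normal()),
                    design.hg_min,
                    design.hg_max,
                )
            )
            mehg = float(
                design.mehg_coeff
                * thg**design.mehg_exponent
                * np.exp(design.mehg_noise_sd * rng.standard_normal())
            )
            tn = max(rng.normal(2.2, 0.4) if paddy else rng.normal(1.5, 0.3), 0.3)
            soc = max(rng.normal(25, 5) if paddy else rng.normal(15, 4), 2.0)
            tc = soc * 1.1 + max(rng.normal(2.0, 0.8), 0.0)
            log10_ab = (
                10.5
                + effects.abundance_slope_on_logTHg * np.log10(thg)
                + (0.2 if paddy else 0.0)
                + 0.3 * rng.standard_normal()
            )
            rows.append(
                {
                    "sample_id": f"{site_id}_r{rep}",
                    "site_id": site_id,
                    "land_use": land_use,
                    "replicate": rep,
                    "total_hg": thg,
                    "mehg": mehg,
                    "cu": float(np.exp(rng.normal(3.3, 0.5))),
                    "pb": float(np.exp(rng.normal(3.5, 0.6))),
                    "cd": float(np.exp(rng.normal(0.0, 0.7))),
                    "zn": float(np.exp(rng.normal(4.4, 0.4))),
                    "ni": float(np.exp(rng.normal(3.3, 0.4))),
                    "as": float(np.exp(rng.normal(2.5, 0.6))),
                    "ph": float(rng.normal(6.8, 0.4) if paddy else rng.normal(5.9, 0.5)),
                    "soc": float(soc),
                    "tc": float(tc),
                    "tn": float(tn),
                    "c_n": float(tc / tn),
                    "doc": float(
                        max(rng.normal(180, 40) if paddy else rng.normal(120, 30), 10.0)
                    ),
                    "nh4": float(max(rng.normal(12, 4) if paddy else rng.normal(6, 2), 0.1)),
                    "no3": float(max(rng.normal(8, 3) if paddy else rng.normal(15, 5), 0.1)),
                    "latitude": lat,
                    "longitude": lon,
                    "log10_bacterial_abundance": float(log10_ab),
                    "bacterial_abundance": float(10.0**log10_ab),
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _module_phylum_probs(role: str) -> tuple[list[str], np.ndarray]:
    """Phylum pool for one module, chosen from its gradient role.

    Each gradient-responsive phylum is confined to a single module's pool: a
    phylum-wide slope shared by taxa of several modules would add
    cross-module covariance and blur the planted partition.
    """
    if role == "mehg_pos":
        pool = ["Proteobacteria", "Bacteroidetes", "Actinobacteria", "Firmicutes"]
        probs = [0.30, 0.25, 0.20, 0.25]
    elif role == "mehg_neg":
        pool = ["Nitrospirae", "Acidobacteria", "Chloroflexi", "Proteobacteria"]
        probs = [0.30, 0.30, 0.20, 0.20]
    else:
        pool = list(NEUTRAL_PHYLA)
        probs = [1.0 / len(pool)] * len(pool)
    return pool, np.asarray(probs)


def generate_community(
    design: DesignSpec,
    effects: EffectSpec,
    metadata: pd.DataFrame,
) -> tuple[CountTable, pd.DataFrame, dict[str, int]]:
    """Counts, taxonomy and planted module membership for the given metadata.

    Returns the samples × taxa :class:`CountTable`, a taxonomy table with
    module-aware phylum labels, and the taxon → module truth map.
    """
    if design.n_taxa < design.n_modules:
        raise ConfigurationError(
            f"n_taxa ({design.n_taxa}) must be at least n_modules ({design.n_modules})"
        )
    if len(metadata) != design.n_samples:
        raise ConfigurationError(
            f"metadata has {len(metadata)} rows but the design implies {design.n_samples}"
        )
    rng = _rng_for(design, 1)
    n_s, n_t, n_m = len(metadata), design.n_taxa, design.n_modules
    z_thg = _standardise(np.log10(metadata["total_hg"].to_numpy(dtype=float)))
    z_mehg = _standardise(np.log10(metadata["mehg"].to_numpy(dtype=float)))

    taxa = [f"OTU_{i + 1:04d}" for i in range(n_t)]
    module_of = np.arange(n_t) % n_m  # balanced planted membership
    module_truth = {t: int(m) for t, m in zip(taxa, module_of)}

    slopes = np.array(
        [effects.module_env_slopes.get(m, (0.0, 0.0)) for m in range(n_m)], dtype=float
    )
    factors = (
        np.outer(z_thg, slopes[:, 0])
        + np.outer(z_mehg, slopes[:, 1])
        + rng.standard_normal((n_s, n_m))
    )

    # the MeHg-responsive phylum pools go to the modules responding most
    # strongly to MeHg in either direction (if any respond at all)
    roles = {m: "neutral" for m in range(n_m)}
    if slopes[:, 1].max() > 0:
        roles[int(slopes[:, 1].argmax())] = "mehg_pos"
    if slopes[:, 1].min() < 0:
        roles[int(slopes[:, 1].argmin())] = "mehg_neg"

    phyla = np.empty(n_t, dtype=object)
    for m in range(n_m):
        members = np.nonzero(module_of == m)[0]
        pool, probs = _module_phylum_probs(roles[m])
        phyla[members] = rng.choice(pool, size=len(members), p=probs)
        # the gradient-responsive phyla are structural features of their
        # module, not a sampling accident: guarantee their presence
        forced = [
            ph for ph in pool if ph in effects.phylum_env_slopes
        ][: len(members)]
        for k, ph in enumerate(forced):
            phyla[members[k]] = ph

    phylum_effect = np.zeros((n_s, n_t))
    for t in range(n_t):
        ph_slopes = effects.phylum_env_slopes.get(str(phyla[t]))
        if ph_slopes is not None:
            phylum_effect[:, t] = ph_slopes[0] * z_thg + ph_slopes[1] * z_mehg

    baseline = rng.normal(0.0, 1.0, size=n_t)
    # higher THg flattens the static baseline → more even community → higher H
    evenness = np.exp(-effects.diversity_evenness_slope * z_thg)[:, None]
    log_abund = (
        baseline[None, :] * evenness
        + effects.within_module_factor_loading * factors[:, module_of]
        + phylum_effect
        + effects.noise_sd * rng.standard_normal((n_s, n_t))
    )
    log_abund -= log_abund.max(axis=1, keepdims=True)
    rel = np.exp(log_abund)
    rel /= rel.sum(axis=1, keepdims=True)

    # library sizes always at or above depth_mean, so a rarefaction depth up
    # to depth_mean is guaranteed feasible for every sample
    sizes = rng.integers(design.depth_mean, int(design.depth_mean * 1.3) + 1, size=n_s)
    counts = np.empty((n_s, n_t), dtype=np.int64)
    for s in range(n_s):
        counts[s] = rng.multinomial(sizes[s], rel[s])

    table = CountTable(pd.DataFrame(counts, index=metadata.index, columns=taxa))
    tax = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": phyla,
            "class": "unclassified",
            "order": "unclassified",
            "family": "unclassified",
            "genus": [f"g_{t}" for t in taxa],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )[list(RANKS)]
    return table, tax, module_truth


def write_module_truth(truth: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"taxon": list(truth), "module": list(truth.values())}
    ).to_csv(path, sep="\t", index=False)


def read_module_truth(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["taxon"].astype(str), df["module"].astype(int)))
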