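"""Co-occurrence network inference and ecological-cluster (module) analysis.

The procedure: keep the dominant taxa that jointly account for a target
fraction (default 80%) of total relative abundance; compute all pairwise
Spearman rank correlations across samples; keep an edge only when the
correlation is positive, above a threshold (default ρ > 0.25) and
significant (default P < 0.01, two-sided t approximation) — negative
correlations are never used; partition the resulting undirected graph into
modules by Louvain modularity maximisation; and summarise each module per
sample as the mean z-scored relative abundance of its member taxa
("module relative abundance").

Both threshold comparisons are strict: a pair sitting exactly at ρ = 0.25
or P = 0.01 does not become an edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mercnet.errors import InsufficientDataError, MercnetError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """All-pairs Spearman correlations: symmetric ρ and p matrices over taxa."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass
class CooccurrenceNetwork:
    """Positive thresholded correlation graph with optional module assignment.

    ``graph`` nodes are taxon IDs; each edge carries ``rho`` and ``p``.
    ``module_of`` maps node → module index, contiguous from 0 and ordered by
    descending module size (ties broken by smallest member taxon ID).
    """

    graph: nx.Graph
    module_of: dict[str, int] | None = None
    resolution: float = 1.0
    seed: int | None = None
    modularity: float | None = None
    n_tested_pairs: int = 0
    stats: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_modules(self) -> int:
        if self.module_of is None:
            return 0
        return len(set(self.module_of.values()))

    def module_sizes(self) -> dict[int, int]:
        if self.module_of is None:
            return {}
        sizes: dict[int, int] = {}
        for m in self.module_of.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def major_modules(self, min_size: int = 10) -> list[int]:
        """Module indices with at least ``min_size`` members (the "major" clusters)."""
        return sorted(m for m, s in self.module_sizes().items() if s >= min_size)

    def membership_frame(self) -> pd.DataFrame:
        if self.module_of is None:
            raise MercnetError("modules not yet detected")
        return pd.DataFrame(
            {"taxon": list(self.module_of), "module": list(self.module_of.values())}
        ).set_index("taxon")


@dataclass
class ModuleProfile:
    """Samples × modules matrix of mean member-taxon z-scores."""

    values: pd.DataFrame
    module_sizes: dict[int, int]


def filter_dominant_taxa(rel: pd.DataFrame, coverage: float = 0.80) -> pd.DataFrame:
    """Keep the most abundant taxa jointly covering ``coverage`` of the community.

    Taxa are ranked by mean relative abundance over all samples (descending,
    ties broken by taxon ID); the smallest prefix whose cumulative mean
    abundance reaches ``coverage`` is retained. Zero-mean taxa are never kept.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    if rel.shape[1] == 0 or rel.shape[0] == 0:
        raise ValueError("empty relative-abundance table")
    means = rel.mean(axis=0)
    means = means[means > 0]
    order = means.to_frame("mean").reset_index(names="taxon")
    order = order.sort_values(["mean", "taxon"], ascending=[False, True])
    cum = order["mean"].cumsum()
    # first position where cumulative abundance reaches the target
    reached = np.nonzero(cum.to_numpy() >= coverage - 1e-12)[0]
    k = int(reached[0]) + 1 if reached.size else len(order)
    keep = order["taxon"].iloc[:k].tolist()
    return rel[keep]


def spearman_all_pairs(rel: pd.DataFrame) -> CorrelationResult:
    """All pairwise Spearman ρ between taxa, with two-sided p (t, n−2 df).

    Ties receive average ranks. Constant taxa cannot be ranked meaningfully:
    their correlations are recorded as ρ = 0 with p = 1. The diagonal is 1.
    """
    n = rel.shape[0]
    if n < 4:
        raise InsufficientDataError(f"need at least 4 samples for correlations, got {n}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(rel.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        r, pv = float(rho), float(p)
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    constant = rel.nunique(axis=0).to_numpy() <= 1
    rho[np.isnan(rho)] = 0.0
    p[np.isnan(p)] = 1.0
    if constant.any():
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
        p[constant, :] = 1.0
        p[:, constant] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    taxa = rel.columns
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n=n,
    )


def build_network(
    corr: CorrelationResult,
    rho_min: float = 0.25,
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> CooccurrenceNetwork:
    """Threshold the correlation matrices into a positive co-occurrence graph.

    An edge (a, b) exists iff ρ_ab > ``rho_min`` and p_ab < ``alpha`` —
    strictly, and only for positive ρ; negative correlations are discarded
    regardless of magnitude. Taxa left without any edge are dropped.
    ``bh_correct`` applies Benjamini–Hochberg to the pairwise p-values first
    (off by default: the edge rule is a raw P threshold).
    """
    if not -1 <= rho_min <= 1:
        raise ValueError(f"rho_min must be in [-1, 1], got {rho_min}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    taxa = list(corr.rho.columns)
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    pvals = p[iu]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    rhos = rho[iu]
    keep = (rhos > 0) & (rhos > rho_min) & (pvals < alpha)
    graph = nx.Graph()
    for i, j, r_ij, p_ij in zip(
        iu[0][keep], iu[1][keep], rhos[keep], pvals[keep]
    ):
        graph.add_edge(taxa[i], taxa[j], rho=float(r_ij), p=float(p_ij))
    net = CooccurrenceNetwork(graph=graph, n_tested_pairs=int(len(rhos)))
    net.stats = {
        "n_tested_pairs": int(len(rhos)),
        "n_edges": graph.number_of_edges(),
        "n_nodes": graph.number_of_nodes(),
        "n_taxa_in": len(taxa),
    }
    logger.info(
        "co-occurrence network: %d/%d pairs became edges over %d retained nodes "
        "(%d isolated taxa dropped)",
        graph.number_of_edges(),
        len(rhos),
        graph.number_of_nodes(),
        len(taxa) - graph.number_of_nodes(),
    )
    return net


def detect_modules(
    net: CooccurrenceNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    weighted: bool = False,
    n_restarts: int = 8,
) -> CooccurrenceNetwork:
    """Partition the network into modules by Louvain modularity maximisation.

    Runs on the unweighted graph by default (``weighted=True`` uses ρ as the
    edge weight). Louvain is a greedy heuristic, so the optimiser is restarted
    ``n_restarts`` times from seeds derived deterministically from ``seed``
    and the highest-modularity partition is kept; the whole procedure is
    deterministic under ``seed``. Modules are re-indexed by descending size,
    ties broken by the smallest member taxon ID, and the achieved modularity
    Q is stored on the returned network.
    """
    if net.graph.number_of_nodes() == 0:
        raise MercnetError("cannot detect modules in an empty network")
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    weight = "rho" if weighted else None
    best: list | None = None
    best_q = -np.inf
    for r in range(n_restarts):
        child = int(
            np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0] % (2**31)
        )
        communities = nx.community.louvain_communities(
            net.graph, weight=weight, resolution=resolution, seed=child
        )
        q = nx.community.modularity(
            net.graph, communities, weight=weight, resolution=resolution
        )
        if q > best_q:
            best, best_q = communities, q
    ordered = sorted(best, key=lambda c: (-len(c), min(c)))
    module_of = {node: m for m, comm in enumerate(ordered) for node in comm}
    q = nx.community.modularity(
        net.graph, ordered, weight=weight, resolution=resolution
    )
    net.module_of = module_of
    net.resolution = resolution
    net.seed = seed
    net.modularity = float(q)
    net.stats.update({"n_modules": len(ordered), "modularity": float(q)})
    logger.info("detected %d modules, modularity Q = %.4f", len(ordered), q)
    return net


def module_relative_abundance(rel: pd.DataFrame, net: CooccurrenceNetwork) -> ModuleProfile:
    """Per-sample module abundance: mean z-scored relative abundance of members.

    Each member taxon is standardised across the full sample set (population
    standard deviation); zero-variance taxa contribute z = 0. The profile
    value for a module in a sample is the unweighted mean of its members'
    z-scores, so every module column has mean 0 over the sample set.
    """
    if net.module_of is None:
        raise MercnetError("modules not yet detected")
    missing_any = [t for t in net.module_of if t not in rel.columns]
    if missing_any:
        sizes: dict[int, int] = {}
        for t in missing_any:
            m = net.module_of[t]
            sizes[m] = sizes.get(m, 0) + 1
        full = net.module_sizes()
        dead = [m for m in full if sizes.get(m, 0) == full[m]]
        if dead:
            raise MercnetError(
                f"module(s) {dead} have no member taxa present in the table"
            )
    sub = rel[[t for t in net.module_of if t in rel.columns]]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = (sub - mu).div(sd.replace(0.0, np.inf), axis=1)
    labels = pd.Series({t: net.module_of[t] for t in sub.columns})
    prof = z.T.groupby(labels).mean().T
    prof.columns = [f"module_{m}" for m in prof.columns]
    return ModuleProfile(values=prof, module_sizes=net.module_sizes())


def recover_planted_modules(net: CooccurrenceNetwork, truth: dict[str, int]) -> float:
    """Adjusted Rand index between detected modules and a planted assignment.

    Evaluated over the taxa shared between the network and the truth map.
    """
    if net.module_of is None:
        raise MercnetError("modules not yet detected")
    shared = [t for t in net.module_of if t in truth]
    if not shared:
        raise MercnetError("no overlap between network nodes and planted truth")
    detected = [net.module_of[t] for t in shared]
    planted = [truth[t] for t in shared]
    return float(adjusted_rand_score(planted, detected))


def match_modules_to_truth(
    net: CooccurrenceNetwork, truth: dict[str, int]
) -> dict[int, int]:
    """Map each detected module to the planted module it overlaps most.

    Useful for locating the detected analogue of a specific planted module
    (e.g. the one whose latent factor rises with MeHg).
    """
    if net.module_of is None:
        raise MercnetError("modules not yet detected")
    overlap: dict[int, dict[int, int]] = {}
    for t, m in net.module_of.items():
        if t not in truth:
            continue
        overlap.setdefault(m, {})
        overlap[m][truth[t]] = overlap[m].get(truth[t], 0) + 1
    if not overlap:
        raise MercnetError("no overlap between network nodes and planted truth")
    return {m: max(c, key=c.get) for m, c in overlap.items()}


def write_edge_list(net: CooccurrenceNetwork, path: str | Path) -> None:
    rows = [
        {"taxon_a": a, "taxon_b": b, "rho": d["rho"], "p": d["p"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"]).to_csv(
        path, sep="\t", index=False
    )


def write_membership(
    net: CooccurrenceNetwork, path: str | Path, tax: pd.DataFrame | None = None
) -> None:
    df = net.membership_frame()
    if tax is not None:
        df["phylum"] = [
            tax.loc[t, "phylum"] if t in tax.index else "unclassified"
            for t in df.index
        ]
    df.to_csv(path, sep="\t")


def write_graphml(net: CooccurrenceNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    if net.module_of is not None:
        nx.set_node_attributes(g, net.module_of, "module")
    nx.write_graphml(g, path)
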