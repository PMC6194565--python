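"""Rarefaction, relative abundance, Shannon diversity and rank aggregation.

Diversity and composition analyses in this package run on a rarefied table:
every sample is subsampled without replacement to a common depth so that
richness and diversity are comparable across libraries of unequal size.
Subsampling uses the multivariate hypergeometric distribution, i.e. exact
draw-without-replacement over the observed reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mercnet.errors import InsufficientDataError, RarefactionError
from mercnet.io import RANKS, CountTable

_LOG_BASES = {"e": np.e, "2": 2.0, "10": 10.0}


def rarefy(counts: CountTable, depth: int, seed: int | np.random.Generator) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Deterministic under ``seed``. Raises :class:`RarefactionError` naming the
    first sample whose total is below the requested depth.
    """
    if depth <= 0:
        raise RarefactionError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    mat = counts.data.to_numpy()
    totals = mat.sum(axis=1)
    short = totals < depth
    if short.any():
        sid = counts.data.index[np.argmax(short)]
        raise RarefactionError(
            f"sample {sid!r} has {totals[np.argmax(short)]} reads, fewer than depth {depth}"
        )
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    return CountTable(pd.DataFrame(out, index=counts.data.index, columns=counts.data.columns))


def relative_abundance(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Close each sample to 1 (per-sample proportions)."""
    df = counts.data if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        raise InsufficientDataError("cannot compute proportions for an all-zero sample")
    return df.div(totals, axis=0)


def shannon(table: CountTable | pd.DataFrame, base: str = "e") -> pd.Series:
    """Shannon diversity H = −Σ pᵢ log pᵢ per sample.

    Accepts counts or proportions (rows are closed to 1 internally).
    ``base`` selects the logarithm: "e" (nats, default), "2" or "10".
    """
    if base not in _LOG_BASES:
        raise ValueError(f"unknown log base {base!r}; choose from {sorted(_LOG_BASES)}")
    rel = relative_abundance(table)
    p = rel.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(_LOG_BASES[base])
    return pd.Series(h, index=rel.index, name="shannon")


def observed_richness(counts: CountTable | pd.DataFrame) -> pd.Series:
    df = counts.data if isinstance(counts, CountTable) else counts
    return (df > 0).sum(axis=1).rename("richness")


def aggregate_by_rank(rel: pd.DataFrame, tax: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum member-taxon proportions per taxonomic rank value.

    Taxa without a taxonomy row, or with a missing value at ``rank``, are
    pooled into an ``"unclassified"`` column. Row sums are preserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    labels = pd.Series("unclassified", index=rel.columns, dtype=object)
    known = [t for t in rel.columns if t in tax.index]
    labels.loc[known] = tax.loc[known, rank].fillna("unclassified").astype(str).values
    out = rel.T.groupby(labels).sum().T
    return out
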