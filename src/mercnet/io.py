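"""Reading, writing and validation of the tabular inputs.

Three tables drive the analysis:

* a count table (samples × taxa, non-negative integers) — on disk the
  conventional OTU-table orientation is used: taxa as rows, samples as
  columns, tab-separated, first column the taxon ID;
* a taxonomy table mapping each taxon to its ranks
  (kingdom … genus, missing ranks stored as ``"unclassified"``);
* per-sample metadata (site, land use, replicate, Hg and MeHg
  concentrations in mg kg⁻¹, other metals, soil chemistry, coordinates,
  qPCR-derived bacterial abundance).

The count table is also supported in the BIOM 1.0 JSON dialect
(sparse or dense); HDF5 BIOM is intentionally not handled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mercnet.errors import AlignmentError, FormatError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
LAND_USES = ("paddy", "upland")


@dataclass
class CountTable:
    """Samples × taxa matrix of non-negative integer read counts.

    ``data`` is a pandas DataFrame indexed by sample ID with taxon IDs as
    columns. Validation enforces unique IDs, integer non-negative entries
    and no all-zero samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample IDs in count table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate taxon IDs in count table")
        values = df.to_numpy()
        if values.size == 0:
            raise FormatError("empty count table")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0, rtol=0):
                raise FormatError("count table contains non-integer entries")
            df = df.astype(np.int64)
            self.data = df
            values = df.to_numpy()
        if (values < 0).any():
            raise FormatError("count table contains negative entries")
        zero = values.sum(axis=1) == 0
        if zero.any():
            bad = df.index[zero].tolist()
            raise FormatError(f"all-zero samples in count table: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass
class AlignmentReport:
    """IDs dropped while aligning the three tables."""

    dropped_samples_counts: list[str] = field(default_factory=list)
    dropped_samples_meta: list[str] = field(default_factory=list)
    taxa_filled_unclassified: list[str] = field(default_factory=list)


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a count table from TSV (taxa rows × sample columns) or BIOM 1.0 JSON."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"count table not found: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        # on-disk orientation is taxa × samples
        return CountTable(df.T)
    if format == "biom_json":
        return _read_biom_json(path)
    raise FormatError(f"unknown count-table format: {format!r}")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.data.T
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")
    elif format == "biom_json":
        _write_biom_json(table, path)
    else:
        raise FormatError(f"unknown count-table format: {format!r}")


def _read_biom_json(path: Path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_taxa, n_samples = doc["shape"]
        taxa = [row["id"] for row in doc["rows"]]
        samples = [col["id"] for col in doc["columns"]]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a BIOM 1.0 JSON table: {path}") from exc
    values = np.zeros((n_taxa, n_samples), dtype=np.int64)
    if matrix_type == "sparse":
        for i, j, v in data:
            values[i, j] = v
    elif matrix_type == "dense":
        values[:] = np.asarray(data)
    else:
        raise FormatError(f"unsupported BIOM matrix_type: {matrix_type!r}")
    df = pd.DataFrame(values.T, index=samples, columns=taxa)
    return CountTable(df)


def _write_biom_json(table: CountTable, path: Path) -> None:
    mat = table.data.T.to_numpy()  # taxa × samples
    rows_idx, cols_idx = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mercnet",
        "date": "1970-01-01T00:00:00",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [mat.shape[0], mat.shape[1]],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [
            [int(i), int(j), int(mat[i, j])] for i, j in zip(rows_idx, cols_idx)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: first column taxon_id, then rank columns; missing → unclassified."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise FormatError("duplicate taxon IDs in taxonomy table")
    df.columns = [c.lower() for c in df.columns]
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = "unclassified"
    df = df[list(RANKS)].fillna("unclassified")
    return df


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    out = tax.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-sample metadata TSV indexed by sample_id; validates the design columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    validate_metadata(df)
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def validate_metadata(meta: pd.DataFrame) -> None:
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample IDs in metadata")
    if "land_use" in meta.columns:
        bad = set(meta["land_use"].unique()) - set(LAND_USES)
        if bad:
            raise FormatError(f"unknown land_use levels: {sorted(bad)}")
    if "total_hg" in meta.columns and (meta["total_hg"] <= 0).any():
        raise FormatError("total_hg must be positive")


def align_tables(
    counts: CountTable,
    meta: pd.DataFrame,
    tax: pd.DataFrame | None = None,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame, AlignmentReport]:
    """Restrict and reorder the tables to their shared samples.

    Samples end up in identical (sorted) order in counts and metadata; every
    taxon in the count table gets a taxonomy row, filled with
    ``"unclassified"`` where absent. The report lists what was dropped.
    """
    shared = sorted(set(counts.sample_ids) & set(meta.index))
    if not shared:
        raise AlignmentError("no samples shared between count table and metadata")
    report = AlignmentReport(
        dropped_samples_counts=sorted(set(counts.sample_ids) - set(shared)),
        dropped_samples_meta=sorted(set(meta.index) - set(shared)),
    )
    counts_out = CountTable(counts.data.loc[shared])
    meta_out = meta.loc[shared]
    if tax is None:
        tax = pd.DataFrame(index=pd.Index([], dtype=str), columns=list(RANKS))
    missing = [t for t in counts_out.taxon_ids if t not in tax.index]
    if missing:
        filler = pd.DataFrame(
            "unclassified", index=pd.Index(missing), columns=list(RANKS)
        )
        tax = pd.concat([tax, filler])
        report.taxa_filled_unclassified = missing
    tax_out = tax.loc[counts_out.taxon_ids, list(RANKS)].fillna("unclassified")
    return counts_out, meta_out, tax_out, report
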