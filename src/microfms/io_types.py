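"""Canonical data model: OTU tables, taxonomy, metadata, and responses.

The in-memory orientation is fixed to samples x taxa (rows are samples),
matching the ML convention used downstream; file readers transpose
``taxa_rows`` inputs on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: The five taxonomic ranks handled by the pipeline, coarsest first.
RANKS: tuple[str, ...] = ("Phylum", "Class", "Order", "Family", "Genus")

#: Label given to taxa whose lineage is unassigned at a rank.  Pooling
#: (rather than dropping) such taxa conserves per-sample depth, which the
#: depth-based normalizations (COM, rarefying) rely on.
UNASSIGNED = "unassigned"


class ParseError(ValueError):
    """Raised when an on-disk table violates the data contract."""


@dataclass
class OTUTable:
    """A samples x taxa abundance matrix at a single taxonomic rank.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with taxon-id columns.  Values are
        non-negative; integer counts before normalization, reals after.
    rank:
        One of :data:`RANKS`.
    """

    data: pd.DataFrame
    rank: str = "Genus"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {RANKS}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("OTU table must have at least one sample and one taxon")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("OTU table must be numeric")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def depths(self) -> pd.Series:
        """Per-sample sequencing depth m^(k), recomputed from the counts."""
        return self.data.sum(axis=1)

    def copy(self) -> "OTUTable":
        return OTUTable(self.data.copy(), self.rank)


@dataclass
class TaxonomyMap:
    """Genus taxon id -> (Phylum, Class, Order, Family, Genus) lineage.

    Missing (NA) entries at a rank are tolerated; aggregation pools them
    into a single per-rank ``unassigned`` taxon.
    """

    lineage: pd.DataFrame  # indexed by Genus taxon id, columns = RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineage.columns]
        if missing:
            raise ValueError(f"taxonomy map missing rank columns: {missing}")
        if self.lineage.index.has_duplicates:
            raise ValueError("duplicate taxon ids in taxonomy map")
        # lineages must be consistent: each child name has a single parent
        filled = self.lineage[list(RANKS)].fillna(UNASSIGNED)
        for child, parent in zip(RANKS[1:], RANKS[:-1]):
            n_parents = filled.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValueError(
                    f"inconsistent lineage: {child} taxa with multiple "
                    f"{parent} parents: {bad.index.tolist()}"
                )

    def names_at(self, taxa: Iterable, level: str) -> pd.Series:
        """Rank-``level`` name for each Genus taxon id, NA pooled."""
        if level not in RANKS:
            raise ValueError(f"unknown rank {level!r}")
        taxa = pd.Index(taxa)
        missing = taxa.difference(self.lineage.index)
        if len(missing):
            raise KeyError(f"taxa missing from taxonomy map: {missing.tolist()}")
        return self.lineage.loc[taxa, level].fillna(UNASSIGNED)


def read_otu_table(
    path: str | Path,
    orientation: str = "taxa_rows",
    rank: str = "Genus",
    sep: str = "\t",
) -> OTUTable:
    """Read an OTU table from a delimited text file.

    ``orientation`` declares how the file is laid out (``taxa_rows`` is the
    conventional export: taxon rows, sample columns); the returned table is
    always samples x taxa.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            row = raw.index[converted.isna().to_numpy().argmax()]
            raise ParseError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        raw[col] = converted
    if orientation == "taxa_rows":
        raw = raw.T
    try:
        return OTUTable(raw, rank=rank)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_otu_table(table: OTUTable, path: str | Path, sep: str = "\t") -> None:
    """Write in the conventional taxa-rows x sample-columns orientation."""
    table.data.T.to_csv(path, sep=sep)


def read_taxonomy(path: str | Path, sep: str = "\t") -> TaxonomyMap:
    """Read a 6-column taxonomy table (taxon_id, Phylum..Genus)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return TaxonomyMap(df)


def write_taxonomy(tax: TaxonomyMap, path: str | Path, sep: str = "\t") -> None:
    tax.lineage.to_csv(path, sep=sep, index_label="taxon_id")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV keyed by a ``sample_id`` column (metadata/env/responses)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required key column 'sample_id'")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id values")
    return df.set_index("sample_id")


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="sample_id")


def aggregate_to_level(table: OTUTable, tax: TaxonomyMap, level: str) -> OTUTable:
    """Merge a Genus-rank table to a coarser rank by summing counts.

    Genus taxa sharing the same rank-``level`` name are summed; NA lineage
    entries are pooled into a single ``unassigned`` taxon, so per-sample
    depths are conserved exactly.
    """
    if table.rank != "Genus":
        raise ValueError("aggregation starts from a Genus-rank table")
    names = tax.names_at(table.taxon_ids, level)
    if level == "Genus":
        return table.copy()
    grouped = table.data.T.groupby(names.to_numpy()).sum().T
    grouped = grouped.sort_index(axis=1)
    return OTUTable(grouped, rank=level)


def filter_by_prevalence(table: OTUTable, min_samples: int = 15) -> OTUTable:
    """Keep taxa with a nonzero count in at least ``min_samples`` samples.

    The default of 15 samples is the pipeline's standard prevalence filter
    for sparse amplicon tables.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.data > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_samples].index
    if len(keep) == 0:
        raise ValueError(
            f"prevalence filter (min_samples={min_samples}) removed all "
            f"{table.n_taxa} taxa"
        )
    return OTUTable(table.data[keep], rank=table.rank)
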