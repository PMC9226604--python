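"""Tabular I/O and explicit sample/OTU filters.

The entry point of the pipeline is a derived OTU count table (samples x
OTUs) with two sidecar tables: per-sample metadata (host, inoculum,
compartment) and per-OTU taxonomy (genus, family, order).  Plant traits
travel in a separate per-pot CSV.  All readers validate; all writers emit
a deterministic column order so byte-identical reruns are possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "read_traits",
    "write_traits",
    "validate_traits",
    "filter_low_depth_samples",
    "filter_rare_otus",
]

HOSTS = ("A", "B", "C", "D")
INOCULA = ("A", "B", "C", "D", "control")
COMPARTMENTS = ("soil", "root")

TRAIT_COLUMNS = [
    "pot_id",
    "host",
    "inoculum",
    "aboveground_biomass",
    "belowground_biomass",
    "total_biomass",
    "height",
    "colonization",
    "n_survivors",
]


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) plus sample metadata and taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame; index = sample ids, columns = OTU ids.
    sample_meta
        DataFrame indexed by sample id with columns ``host``, ``inoculum``,
        ``compartment`` (extra columns such as ``pot_id`` are preserved).
    taxonomy
        Optional DataFrame indexed by OTU id with columns ``genus``,
        ``family``, ``order``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(arr.astype(float))):
                i, j = np.argwhere(frac != 0)[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{counts.index[i]!r}, OTU {counts.columns[j]!r}"
                )
            counts = counts.astype(np.int64)
            object.__setattr__(self, "counts", counts)
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[i]!r}, "
                f"OTU {counts.columns[j]!r}"
            )
        missing = counts.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples lacking metadata: {missing.tolist()}")
        counts.index.name = "sample_id"
        counts.columns.name = None
        # keep metadata aligned to the count rows
        meta = self.sample_meta.loc[counts.index]
        meta.index.name = "sample_id"
        object.__setattr__(self, "sample_meta", meta)
        if self.taxonomy is not None:
            self.taxonomy.index.name = "otu_id"

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(
            self.counts.loc[list(sample_ids)], self.sample_meta, self.taxonomy
        )

    def subset_otus(self, otu_ids) -> "OtuTable":
        tax = self.taxonomy.loc[list(otu_ids)] if self.taxonomy is not None else None
        return OtuTable(self.counts[list(otu_ids)], self.sample_meta, tax)


def read_otu_table(
    counts_path,
    meta_path,
    taxonomy_path=None,
    orientation: str = "samples_as_rows",
) -> OtuTable:
    """Read a tab-separated OTU count table plus metadata/taxonomy sidecars.

    ``orientation`` is ``"samples_as_rows"`` (canonical) or ``"otus_as_rows"``
    for transposed files; the returned table is always samples x OTUs.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    if orientation == "otus_as_rows":
        counts = counts.T
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    tax = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col="otu_id")
        tax.index = tax.index.astype(str)
    return OtuTable(counts, meta, tax)


def write_otu_table(table: OtuTable, counts_path, meta_path, taxonomy_path=None) -> None:
    """Write counts/metadata/taxonomy as UTF-8 TSVs with fixed column order."""
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(counts_path, sep="\t")
    meta_cols = ["host", "inoculum", "compartment"] + [
        c for c in table.sample_meta.columns if c not in ("host", "inoculum", "compartment")
    ]
    meta = table.sample_meta[meta_cols].copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")
    if taxonomy_path is not None and table.taxonomy is not None:
        tax = table.taxonomy[["genus", "family", "order"]].copy()
        tax.index.name = "otu_id"
        tax.to_csv(taxonomy_path, sep="\t")


def validate_traits(traits: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Validate a per-pot plant trait table and return it with canonical columns.

    Checks: positive biomass, total = above + below within ``atol``,
    ``n_survivors`` >= 1, unique pot ids.
    """
    required = [c for c in TRAIT_COLUMNS if c != "colonization"]
    missing = [c for c in required if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if traits["pot_id"].duplicated().any():
        dup = traits.loc[traits["pot_id"].duplicated(), "pot_id"].tolist()
        raise ValueError(f"duplicate pot ids: {dup}")
    for col in ("aboveground_biomass", "belowground_biomass", "total_biomass"):
        if (traits[col] <= 0).any():
            bad = traits.loc[traits[col] <= 0, "pot_id"].tolist()
            raise ValueError(f"non-positive {col} for pots {bad}")
    resid = traits["total_biomass"] - traits["aboveground_biomass"] - traits["belowground_biomass"]
    if (resid.abs() > atol).any():
        bad = traits.loc[resid.abs() > atol, "pot_id"].tolist()
        raise ValueError(f"total != above + below for pots {bad}")
    if (traits["n_survivors"] < 1).any():
        bad = traits.loc[traits["n_survivors"] < 1, "pot_id"].tolist()
        raise ValueError(f"n_survivors < 1 for pots {bad}")
    cols = [c for c in TRAIT_COLUMNS if c in traits.columns]
    return traits[cols].reset_index(drop=True)


def read_traits(path) -> pd.DataFrame:
    return validate_traits(pd.read_csv(path))


def write_traits(traits: pd.DataFrame, path) -> None:
    validate_traits(traits).to_csv(path, index=False)


def filter_low_depth_samples(table: OtuTable, min_reads: int = 5000):
    """Drop samples whose total reads are strictly below ``min_reads``.

    Returns ``(filtered_table, discarded_ids)``.  Raises if every sample
    would be discarded.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.library_sizes
    keep = depths[depths >= min_reads].index
    discarded = [s for s in table.sample_ids if s not in set(keep)]
    if len(keep) == 0:
        raise ValueError(f"all {len(discarded)} samples below {min_reads} reads")
    return table.subset_samples([s for s in table.sample_ids if s in set(keep)]), discarded


def filter_rare_otus(table: OtuTable, min_total_reads: int = 10) -> OtuTable:
    """Drop OTUs whose total reads across samples are strictly below the cutoff."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    totals = table.counts.sum(axis=0)
    keep = [o for o in table.otu_ids if totals[o] >= min_total_reads]
    if not keep:
        warnings.warn("rare-OTU filter removed every OTU", stacklevel=2)
        return OtuTable(table.counts[[]], table.sample_meta, None)
    return table.subset_otus(keep)
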