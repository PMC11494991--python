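"""Feature-table containers, standard-format IO and taxonomy-aware reshaping.

The central container is :class:`FeatureTable`, a taxon-by-sample matrix of
non-negative integer counts, mirroring the usual 16S OTU/genus table.  Sample
metadata carries the four canonical study groups -- N (uncultured control),
M (uncultured model), ND (cultured control) and MD (cultured model) -- plus
compound/cocktail treatment wells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: QIIME-style rank prefixes, e.g. ``g__Lactobacillus``.
_RANK_PREFIXES = tuple(f"{r[0]}__" for r in RANKS)

_UNCLASSIFIED = {"", "unclassified", "uncultured", "unknown", "na", "none"}


class FormatError(ValueError):
    """Raised when an input file violates the documented table format."""


def _strip_prefix(label: str) -> str:
    for pre in _RANK_PREFIXES:
        if label.startswith(pre):
            return label[len(pre):]
    return label


@dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer taxon x sample count matrix.

    Parameters
    ----------
    data
        DataFrame with taxa as rows (index) and samples as columns; all
        entries must be non-negative integers and ids unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0:
            raise FormatError("no taxa in feature table")
        if df.shape[1] == 0:
            raise FormatError("no samples in feature table")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric entries in feature table")
        if np.any(arr != np.floor(arr)) or np.any(~np.isfinite(arr)):
            t, s = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))[0]
            raise FormatError(
                f"non-integer count at taxon {df.index[t]!r}, sample {df.columns[s]!r}"
            )
        if (arr < 0).any():
            t, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at taxon {df.index[t]!r}, sample {df.columns[s]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    # -- basic views -------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int array, taxa x samples."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def library_sizes(self) -> pd.Series:
        """Per-sample column sums N_s."""
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised proportions x_{t,s} / N_s."""
        n = self.library_sizes()
        if (n == 0).any():
            bad = n.index[n == 0].tolist()
            raise FormatError(f"zero library size for sample(s): {bad}")
        return self.data / n

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return FeatureTable(self.data[list(sample_ids)])

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        return cls(df)

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "FeatureTable":
        """Read a BIOM 1.0 JSON table (dense or sparse)."""
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:, :] = np.asarray(doc["data"], dtype=float)
        return cls(pd.DataFrame(mat, index=taxa, columns=samples))


def read_feature_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from TSV or BIOM 1.0 JSON.

    TSV layout: taxa as rows, first column the taxon id (header ``taxon_id``),
    remaining columns one per sample.
    """
    if format == "tsv":
        return FeatureTable.from_tsv(path)
    if format == "biom-json":
        return FeatureTable.from_biom_json(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom-json'")


@dataclass(frozen=True)
class TaxonomyMap:
    """taxon_id -> ordered lineage (kingdom..species), QIIME prefixes allowed."""

    lineages: Mapping[str, tuple[str, ...]]

    def rank_label(self, taxon_id: str, rank: str) -> str:
        """Label of ``taxon_id`` at ``rank``; unresolved labels are pooled as
        ``unclassified-<nearest named parent>``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lineage = self.lineages[taxon_id]
        idx = RANKS.index(rank)
        if idx < len(lineage):
            lab = _strip_prefix(str(lineage[idx])).strip()
            if lab.lower() not in _UNCLASSIFIED:
                return lab
        # walk up to the nearest named parent
        for j in range(min(idx, len(lineage)) - 1, -1, -1):
            parent = _strip_prefix(str(lineage[j])).strip()
            if parent.lower() not in _UNCLASSIFIED:
                return f"unclassified-{parent}"
        return "unclassified-root"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tlineage\n")
            for tid, lin in self.lineages.items():
                fh.write(f"{tid}\t{';'.join(lin)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        lineages = {
            row["taxon_id"]: tuple(p.strip() for p in row["lineage"].split(";"))
            for _, row in df.iterrows()
        }
        return cls(lineages)


_METADATA_COLUMNS = (
    "sample_id",
    "group_label",
    "culture_status",
    "disease_status",
    "treatment_id",
    "replicate",
)

#: canonical group -> (culture_status, disease_status); treatment must be none
CANONICAL_GROUPS = {
    "N": ("uncultured", "control"),
    "M": ("uncultured", "model"),
    "ND": ("cultured", "control"),
    "MD": ("cultured", "model"),
}


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design metadata (group, culture/disease status, treatment)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {missing}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")
        df["treatment_id"] = df["treatment_id"].fillna("none").replace("", "none")
        df = df.set_index("sample_id", drop=False)
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def canonical_group(self, sample_id: str) -> str | None:
        row = self.data.loc[sample_id]
        if row["treatment_id"] != "none":
            return None
        for grp, (cult, dis) in CANONICAL_GROUPS.items():
            if row["culture_status"] == cult and row["disease_status"] == dis:
                return grp
        return None

    def samples_in_group(self, group: str) -> list[str]:
        """Samples in canonical group N/M/ND/MD, carrying treatment ``group``,
        or (failing both) labelled ``group`` in ``group_label``."""
        if group in CANONICAL_GROUPS:
            return [s for s in self.sample_ids if self.canonical_group(s) == group]
        by_treat = list(self.data.loc[self.data["treatment_id"] == group, "sample_id"])
        if by_treat:
            return by_treat
        return list(self.data.loc[self.data["group_label"] == group, "sample_id"])

    def treatments(self) -> list[str]:
        t = [x for x in self.data["treatment_id"].unique() if x != "none"]
        return sorted(t)

    def missing_canonical_groups(self) -> list[str]:
        return [g for g in CANONICAL_GROUPS if not self.samples_in_group(g)]

    def to_tsv(self, path: str | Path) -> None:
        self.data[list(_METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment_id": str})
        return cls(df)


@dataclass(frozen=True)
class TransformedTable:
    """log10 pseudocounted relative abundances, same shape as the source table.

    m_{t,s} = log10 p_{t,s} with p_{t,s} = (x_{t,s} + c0) / (N_s + c0 * T).
    """

    data: pd.DataFrame
    pseudocount: float = 0.5

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# reshaping operations
# ---------------------------------------------------------------------------

def aggregate_to_rank(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Unresolved labels pool under ``unclassified-<nearest named parent>``.
    Output taxa are sorted lexicographically; per-sample totals are conserved.
    """
    missing = [t for t in table.taxon_ids if t not in tax.lineages]
    if missing:
        raise KeyError(f"taxa without lineage: {missing[:5]}")
    labels = [tax.rank_label(t, rank) for t in table.taxon_ids]
    out = table.data.groupby(pd.Index(labels, name="taxon_id")).sum().sort_index()
    return FeatureTable(out)


def filter_prevalence(table: FeatureTable, min_samples: int) -> FeatureTable:
    """Keep taxa with a nonzero count in at least ``min_samples`` samples."""
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    if min_samples == 0:
        return table
    keep = (table.data > 0).sum(axis=1) >= min_samples
    if not keep.any():
        raise FormatError("prevalence filter removed all taxa")
    return FeatureTable(table.data.loc[keep])


def transform_log_relative(table: FeatureTable, pseudocount: float = 0.5) -> TransformedTable:
    """log10 of pseudocounted relative abundance.

    p_{t,s} = (x_{t,s} + c0) / (N_s + c0 T) so that each column of p sums to
    one exactly; m = log10 p is finite for every cell.  This is the default
    abundance scale for group profiles and the remodeling score: 16S
    abundances span orders of magnitude and a linear scale would let the most
    abundant genus dominate the score.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    n = table.library_sizes()
    if (n == 0).any():
        bad = n.index[n == 0].tolist()
        raise FormatError(f"zero library size for sample(s): {bad}")
    t = table.shape[0]
    p = (table.data + pseudocount) / (n + pseudocount * t)
    return TransformedTable(np.log10(p), pseudocount=pseudocount)
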