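"""Reading, validation and serialization of count tables, sample metadata
and classification results.

The canonical on-disk dialect is TSV (tab-separated, UTF-8, header row);
CSV is accepted via ``dialect="csv"``. Count tables have gene IDs in the
first column and sample IDs in the header. Counts are stored as floats even
when raw so that one container serves raw and library-size-normalized
matrices; rawness is tracked by the ``normalized`` flag.

Missing cells are an error, never silently imputed as zero, and decimal
commas are rejected: count tables come out of alignment pipelines and a
malformed cell almost always signals an upstream problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTableFormatError",
    "CountDataset",
    "SampleMeta",
    "ClassificationResult",
    "CATEGORIES",
    "read_count_table",
    "read_sample_metadata",
    "write_classification",
    "read_classification",
]

#: Category vocabulary, in the order used for sorting serialized results.
CATEGORIES = (
    "gonadal_somatic",
    "germ_cell_specific",
    "indeterminate",
    "gonad_specific",
    "not_gonad_specific",
)

#: Recognized experimental groups; anything else is mapped to "other".
KNOWN_GROUPS = ("WT", "GCF")

#: Statistic columns carried alongside each gene's category.
STAT_COLUMNS = (
    "extragonadal_max",
    "ovary_mean",
    "testis_mean",
    "wt_testis_mean",
    "gcf_testis_mean",
)


class CountTableFormatError(ValueError):
    """A count/metadata table violates the expected format."""


def _sep_for(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


@dataclass
class CountDataset:
    """A gene x sample read-count matrix.

    Parameters
    ----------
    counts
        DataFrame with gene IDs as index and sample IDs as columns. All
        entries must be finite and non-negative. Raw counts are integers by
        convention but are stored as floats.
    normalized
        Whether the matrix has been library-size normalized.
    """

    counts: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise CountTableFormatError("count table is empty")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise CountTableFormatError(f"duplicate gene ID {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise CountTableFormatError(f"duplicate sample ID {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountTableFormatError("count matrix contains non-numeric values")
        if np.isnan(values).any():
            gi, si = np.argwhere(np.isnan(values))[0]
            raise CountTableFormatError(
                f"missing count for gene {self.counts.index[gi]!r}, "
                f"sample {self.counts.columns[si]!r}"
            )
        if (values < 0).any():
            gi, si = np.argwhere(values < 0)[0]
            raise CountTableFormatError(
                f"negative count for gene {self.counts.index[gi]!r}, "
                f"sample {self.counts.columns[si]!r}"
            )
        self.counts = self.counts.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class SampleMeta:
    """Per-sample metadata: tissue, experimental group, replicate index.

    ``table`` is indexed by sample_id with columns ``tissue``, ``group``
    (one of ``WT``, ``GCF`` or ``other``) and ``replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"tissue", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise CountTableFormatError(
                f"sample metadata lacks column(s) {sorted(missing)}"
            )
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise CountTableFormatError(f"sample {dup!r} listed twice")
        if "replicate" not in self.table.columns:
            self.table = self.table.assign(
                replicate=self.table.groupby(["tissue", "group"]).cumcount() + 1
            )
        group = self.table["group"].where(
            self.table["group"].isin(KNOWN_GROUPS), "other"
        )
        self.table = self.table.assign(group=group)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def tissue_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "tissue"]

    def covers(self, dataset: CountDataset) -> bool:
        return set(dataset.sample_ids) <= set(self.table.index)


@dataclass
class ClassificationResult:
    """Per-gene category labels plus the group means that induced them.

    ``table`` is indexed by gene_id with a ``category`` column (values from
    :data:`CATEGORIES`) and the supporting statistics in
    :data:`STAT_COLUMNS` (NaN where the underlying tissue/group was not
    observed, e.g. in pre-averaged summary mode).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "category" not in self.table.columns:
            raise ValueError("classification table lacks a 'category' column")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        for col in STAT_COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID {dup!r} in classification")

    def genes_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return list(self.table.index[self.table["category"] == category])

    def counts(self) -> dict[str, int]:
        """Number of genes per category (all categories, zeros included)."""
        vc = self.table["category"].value_counts()
        return {cat: int(vc.get(cat, 0)) for cat in CATEGORIES}

    def __len__(self) -> int:
        return len(self.table)


def read_count_table(path, dialect: str = "tsv") -> CountDataset:
    """Read a gene x sample count table.

    First column: gene IDs; header row: sample IDs. Cells must be
    non-negative numbers with '.' as the decimal separator. Raises
    :class:`CountTableFormatError` on duplicates, negative, missing or
    non-numeric cells, naming the offending gene and sample.
    """
    raw = pd.read_csv(
        path, sep=_sep_for(dialect), index_col=0, dtype=str, keep_default_na=False
    )
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise CountTableFormatError(f"count table {path} is empty")
    raw.index = raw.index.astype(str)
    numeric = raw.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad = numeric.isna().to_numpy()
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise CountTableFormatError(
            f"non-numeric or missing count {raw.iat[gi, si]!r} for gene "
            f"{raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    return CountDataset(counts=numeric, normalized=False)


def read_sample_metadata(path, dialect: str = "tsv") -> SampleMeta:
    """Read sample metadata (columns sample_id, tissue, group[, replicate]).

    Group labels other than WT/GCF are mapped to "other".
    """
    df = pd.read_csv(path, sep=_sep_for(dialect), dtype=str)
    if "sample_id" not in df.columns:
        raise CountTableFormatError("sample metadata lacks column(s) ['sample_id']")
    df = df.set_index("sample_id")
    return SampleMeta(table=df)


def _category_rank(categories: pd.Series) -> pd.Series:
    order = {cat: i for i, cat in enumerate(CATEGORIES)}
    return categories.map(order)


def write_classification(result: ClassificationResult, path) -> None:
    """Write a classification result as TSV.

    Rows are sorted by category (somatic first) then by descending WT-testis
    mean, mirroring how the somatic gene table is presented. Re-reading with
    :func:`read_classification` reproduces the same records.
    """
    if len(result) == 0:
        raise ValueError("refusing to write an empty classification result")
    df = result.table.copy()
    df["_rank"] = _category_rank(df["category"])
    df = df.sort_values(
        by=["_rank", "wt_testis_mean"],
        ascending=[True, False],
        kind="mergesort",
        na_position="last",
    ).drop(columns="_rank")
    df.index.name = "gene_id"
    df = df[["category", *STAT_COLUMNS]]
    df.to_csv(path, sep="\t")


def read_classification(path) -> ClassificationResult:
    """Read back a TSV written by :func:`write_classification`."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ClassificationResult(table=df)
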