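"""Library-size normalization, group averaging, and the two-stage
tissue-specificity classifier.

The screen works on plain read-count thresholds rather than differential
expression statistics. Two cutoffs drive everything:

* ``absent_max`` (default 50): a gene with this many reads or fewer in a
  tissue is considered *not expressed* there (background).
* ``present_min`` (default 100): a gene needs at least this many reads to
  be considered *expressed*; the gap between the two cutoffs separates
  clear presence from background.

Stage one (gonad specificity) keeps genes absent (<= absent_max) in every
extra-gonadal tissue and present (>= present_min) in both ovary and testis.
Stage two classifies the gonad-specific genes by comparing wild-type (WT)
testis with germ-cell-free (GCF) knockout testis: presence in both
compartments means the transcript comes from somatic cells (which both
genotypes retain), presence only in WT means it comes from germ cells
(which the knockout lacks). Group means falling between the cutoffs match
neither rule and are labelled ``indeterminate`` rather than silently
dropped, so the number of discarded genes stays auditable.

Thresholds are applied to group means of normalized counts. Counts are
normalized by scaling every sample to the total of the smallest library;
fractional values are never rounded before thresholding (rounding would
make boundary behavior depend on the scale factors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import (
    STAT_COLUMNS,
    ClassificationResult,
    CountDataset,
    SampleMeta,
)

__all__ = [
    "SpecificityThresholds",
    "GroupMeans",
    "FoldChange",
    "WT_TESTIS",
    "GCF_TESTIS",
    "GONAD_TISSUES",
    "normalize_to_smallest",
    "group_means",
    "combine_means",
    "filter_gonad_specific",
    "classify_testis_compartment",
    "fold_change",
    "fold_change_table",
]

#: Column labels for the knockout-contrast group means.
WT_TESTIS = "WT_testis"
GCF_TESTIS = "GCF_testis"

#: Tissues counted as gonadal in the specificity filter.
GONAD_TISSUES = ("testis", "ovary")


@dataclass(frozen=True)
class SpecificityThresholds:
    """Absent/present read-count cutoffs.

    Both bounds are inclusive: "50 or less" is absent, "100 or more" is
    present. Values strictly between the two are neither.
    """

    absent_max: float = 50.0
    present_min: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.absent_max < self.present_min:
            raise ValueError(
                f"require 0 <= absent_max < present_min, got "
                f"absent_max={self.absent_max}, present_min={self.present_min}"
            )

    def is_absent(self, value: float) -> bool:
        return value <= self.absent_max

    def is_present(self, value: float) -> bool:
        return value >= self.present_min


@dataclass
class GroupMeans:
    """Per-gene arithmetic means of normalized counts per label.

    Labels are tissue names (means over panel samples, i.e. samples whose
    group is neither WT nor GCF) plus :data:`WT_TESTIS` / :data:`GCF_TESTIS`
    for the knockout-contrast testis groups. ``means`` is indexed by gene_id
    with one column per label.
    """

    means: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.means.to_numpy() < 0).any():
            raise ValueError("group means must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.means.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def tissue_labels(self) -> list[str]:
        return [c for c in self.means.columns if c not in (WT_TESTIS, GCF_TESTIS)]

    def extragonadal_labels(self, gonad_tissues=GONAD_TISSUES) -> list[str]:
        return [t for t in self.tissue_labels if t not in gonad_tissues]

    def lookup(self, gene_id: str, label: str) -> float:
        if label not in self.means.columns:
            raise KeyError(
                f"no samples contributed to group/tissue {label!r}; "
                f"available labels: {self.labels}"
            )
        if gene_id not in self.means.index:
            raise KeyError(f"gene {gene_id!r} absent from group means")
        return float(self.means.at[gene_id, label])


def normalize_to_smallest(dataset: CountDataset) -> CountDataset:
    """Scale each sample to the total of the smallest library.

    Every column is multiplied by (min over samples of total reads) /
    (that sample's total reads), so all column totals end up equal to the
    smallest pre-normalization total.
    """
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    totals = dataset.sample_totals()
    if (totals <= 0).any():
        sample = totals.index[totals <= 0][0]
        raise ValueError(f"sample {sample!r} has zero total reads")
    scale = totals.min() / totals
    return CountDataset(counts=dataset.counts * scale, normalized=True)


def group_means(dataset: CountDataset, meta: SampleMeta) -> GroupMeans:
    """Average normalized counts per gene per tissue and per WT/GCF group.

    Tissue means are computed over panel samples only (group "other");
    WT/GCF testis samples contribute to the :data:`WT_TESTIS` /
    :data:`GCF_TESTIS` columns instead. A dataset may contain only panel or
    only knockout-contrast samples; the resulting columns reflect that.
    """
    if not dataset.normalized:
        raise ValueError("group_means expects a normalized dataset")
    if not meta.covers(dataset):
        missing = sorted(set(dataset.sample_ids) - set(meta.table.index))
        raise ValueError(f"samples without metadata: {missing}")
    sub = meta.table.loc[dataset.sample_ids]
    columns: dict[str, pd.Series] = {}
    panel = sub.index[sub["group"] == "other"]
    for tissue, samples in sub.loc[panel].groupby("tissue").groups.items():
        columns[str(tissue)] = dataset.counts[list(samples)].mean(axis=1)
    for group, label in (("WT", WT_TESTIS), ("GCF", GCF_TESTIS)):
        samples = sub.index[sub["group"] == group]
        if len(samples):
            columns[label] = dataset.counts[list(samples)].mean(axis=1)
    return GroupMeans(means=pd.DataFrame(columns, index=dataset.counts.index))


def combine_means(panel: GroupMeans, testis: GroupMeans) -> GroupMeans:
    """Join group means from separately normalized datasets by gene ID.

    The multi-tissue panel and the WT/GCF testis experiment are separate
    sequencing efforts and are normalized independently; this join merges
    their means. Genes present in only one dataset get mean 0 in the other,
    with a warning.
    """
    overlap = set(panel.labels) & set(testis.labels)
    if overlap:
        raise ValueError(f"labels present in both datasets: {sorted(overlap)}")
    joined = panel.means.join(testis.means, how="outer")
    n_missing = int(joined.isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) absent from one dataset; their means there "
            "are taken as 0",
            stacklevel=2,
        )
    return GroupMeans(means=joined.fillna(0.0))


def filter_gonad_specific(
    means: GroupMeans,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    gonad_tissues=GONAD_TISSUES,
) -> set[str]:
    """Genes absent everywhere outside the gonads and present in both gonads.

    A gene passes iff every extra-gonadal tissue mean <= absent_max AND the
    ovary mean >= present_min AND the testis mean >= present_min. Requires
    at least one extra-gonadal tissue — without one the filter is undefined.
    """
    extra = means.extragonadal_labels(gonad_tissues)
    if not extra:
        raise ValueError(
            "gonad-specificity filter undefined: no extra-gonadal tissues in means"
        )
    for tissue in gonad_tissues:
        if tissue not in means.labels:
            raise ValueError(f"gonad tissue {tissue!r} missing from means")
    m = means.means
    absent_outside = (m[extra] <= thresholds.absent_max).all(axis=1)
    present_in_gonads = np.logical_and.reduce(
        [m[t] >= thresholds.present_min for t in gonad_tissues]
    )
    return set(m.index[absent_outside & present_in_gonads])


def classify_testis_compartment(
    gonad_specific: set[str],
    means: GroupMeans,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
) -> ClassificationResult:
    """Split gonad-specific genes into germ-cell vs somatic compartments.

    Within the gonad-specific set: ``gonadal_somatic`` iff both WT and GCF
    testis means are present (>= present_min); ``germ_cell_specific`` iff
    the WT mean is present and the GCF mean absent (<= absent_max);
    otherwise ``indeterminate``. Genes outside the set are labelled
    ``not_gonad_specific``. Every gene in ``means`` receives exactly one
    category.
    """
    for label in (WT_TESTIS, GCF_TESTIS):
        if label not in means.labels:
            raise ValueError(f"means lack the {label!r} group")
    missing = set(gonad_specific) - set(means.gene_ids)
    if missing:
        raise KeyError(
            f"gene {sorted(missing)[0]!r} in gonad_specific set but absent from means"
        )
    m = means.means
    records = {}
    records["wt_testis_mean"] = m[WT_TESTIS]
    records["gcf_testis_mean"] = m[GCF_TESTIS]
    extra = means.extragonadal_labels()
    records["extragonadal_max"] = m[extra].max(axis=1) if extra else np.nan
    records["ovary_mean"] = m["ovary"] if "ovary" in m.columns else np.nan
    records["testis_mean"] = m["testis"] if "testis" in m.columns else np.nan

    wt_present = m[WT_TESTIS] >= thresholds.present_min
    gcf_present = m[GCF_TESTIS] >= thresholds.present_min
    gcf_absent = m[GCF_TESTIS] <= thresholds.absent_max
    in_set = m.index.isin(list(gonad_specific))

    category = pd.Series("indeterminate", index=m.index)
    category[wt_present & gcf_present] = "gonadal_somatic"
    category[wt_present & gcf_absent] = "germ_cell_specific"
    category[~in_set] = "not_gonad_specific"

    table = pd.DataFrame({"category": category, **records})
    table.index.name = "gene_id"
    return ClassificationResult(table=table[["category", *STAT_COLUMNS]])


@dataclass(frozen=True)
class FoldChange:
    """Symmetric fold difference between WT and GCF testis means.

    ``ratio`` is always >= 1 when defined; ``direction`` carries the sign
    (``increase_in_GCF`` / ``decrease_in_GCF`` / ``unchanged``). A zero on
    either side makes the ratio undefined (``defined=False``), never
    infinite, so downstream sorting stays total.
    """

    ratio: float
    direction: str
    defined: bool
    gene_id: str | None = None


def fold_change(wt_mean: float, gcf_mean: float, gene_id: str | None = None) -> FoldChange:
    """Fold difference max/min between WT and GCF means."""
    if wt_mean < 0 or gcf_mean < 0:
        raise ValueError("means must be non-negative")
    lo, hi = min(wt_mean, gcf_mean), max(wt_mean, gcf_mean)
    if lo == 0:
        return FoldChange(ratio=float("nan"), direction="unchanged", defined=False, gene_id=gene_id)
    if gcf_mean > wt_mean:
        direction = "increase_in_GCF"
    elif gcf_mean < wt_mean:
        direction = "decrease_in_GCF"
    else:
        direction = "unchanged"
    return FoldChange(ratio=hi / lo, direction=direction, defined=True, gene_id=gene_id)


def fold_change_table(result: ClassificationResult, category: str = "gonadal_somatic") -> pd.DataFrame:
    """Fold changes for one category, sorted by descending WT testis mean."""
    genes = result.genes_in(category)
    sub = result.table.loc[genes].sort_values("wt_testis_mean", ascending=False)
    rows = []
    for gene_id, row in sub.iterrows():
        fc = fold_change(row["wt_testis_mean"], row["gcf_testis_mean"], gene_id=gene_id)
        rows.append(
            {
                "gene_id": gene_id,
                "wt_testis_mean": row["wt_testis_mean"],
                "gcf_testis_mean": row["gcf_testis_mean"],
                "fold": fc.ratio,
                "direction": fc.direction,
                "defined": fc.defined,
            }
        )
    columns = ["gene_id", "wt_testis_mean", "gcf_testis_mean", "fold", "direction", "defined"]
    return pd.DataFrame(rows, columns=columns).set_index("gene_id")
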