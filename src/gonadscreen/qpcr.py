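"""Comparative-Ct (2^-ddCt) relative expression from qPCR Ct exports.

The workflow: technical replicate wells are averaged on the Ct scale; each
sample's dCt = Ct(target) - Ct(reference gene); ddCt = dCt minus the
arithmetic mean dCt of a designated calibrator group; relative expression
(fold) = 2^-ddCt. Amplification efficiency is fixed at 2 (no efficiency
correction). "ND" (not detected) propagates: it is never imputed as a
maximal cycle number, because a failed amplification carries no quantity.
Group summaries report the mean fold and its standard error over detected
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ND",
    "CtTable",
    "read_ct_table",
    "average_technical_replicates",
    "relative_expression",
    "summarize_groups",
]

logger = logging.getLogger(__name__)

#: Sentinel for "not detected" wells in Ct exports.
ND = "ND"

_CT_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``table`` has columns sample_id, group, gene, replicate, ct; ct is a
    float in cycles (positive when detected) with NaN encoding ND.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_CT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"Ct table lacks column(s) {sorted(missing)}")
        ct = pd.to_numeric(self.table["ct"], errors="raise")
        if (ct.dropna() <= 0).any():
            bad = self.table.loc[ct.notna() & (ct <= 0)].iloc[0]
            raise ValueError(
                f"non-positive Ct {bad['ct']} for sample {bad['sample_id']!r}, "
                f"gene {bad['gene']!r}"
            )
        self.table = self.table.assign(ct=ct)[_CT_COLUMNS].reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def __len__(self) -> int:
        return len(self.table)


def read_ct_table(path, dialect: str = "tsv") -> CtTable:
    """Read a long-format Ct TSV with an "ND" sentinel for failed wells."""
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "group": str, "gene": str})
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby(["sample_id", "gene"]).cumcount() + 1
    df["ct"] = pd.to_numeric(
        df["ct"].astype(str).str.strip().replace(ND, np.nan), errors="raise"
    )
    return CtTable(table=df)


def average_technical_replicates(table: CtTable) -> CtTable:
    """Collapse technical replicates to one Ct per (sample, gene).

    Detected replicate Cts are averaged arithmetically; a (sample, gene)
    whose replicates are all ND stays ND. If some but not all replicates
    are ND, the detected ones are used and a warning is logged.
    """
    rows = []
    for (sample, gene), sub in table.table.groupby(["sample_id", "gene"], sort=True):
        detected = sub["ct"].dropna()
        if len(detected) == 0:
            ct = np.nan
        else:
            if len(detected) < len(sub):
                logger.warning(
                    "sample %r gene %r: %d of %d replicates ND; using detected only",
                    sample, gene, len(sub) - len(detected), len(sub),
                )
            ct = float(detected.mean())
        rows.append(
            {
                "sample_id": sample,
                "group": sub["group"].iloc[0],
                "gene": gene,
                "replicate": 0,
                "ct": ct,
            }
        )
    return CtTable(table=pd.DataFrame(rows, columns=_CT_COLUMNS))


def relative_expression(
    table: CtTable,
    reference_gene: str,
    calibrator_group: str,
    target_gene: str | None = None,
) -> pd.DataFrame:
    """Per-sample dCt, ddCt and fold relative to the calibrator group.

    Returns a DataFrame indexed by sample_id with columns group, delta_ct,
    delta_delta_ct, fold, detected. Samples whose reference gene is ND are
    excluded with a logged warning; samples whose target is ND are kept
    with detected=False and NaN quantities. The calibrator group must have
    at least one sample with both genes detected.
    """
    averaged = average_technical_replicates(table)
    df = averaged.table
    if reference_gene not in set(df["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if target_gene is None:
        targets = sorted(set(df["gene"]) - {reference_gene})
        if len(targets) != 1:
            raise ValueError(
                f"target gene ambiguous ({targets}); pass target_gene explicitly"
            )
        target_gene = targets[0]
    wide = df.pivot_table(index="sample_id", columns="gene", values="ct", dropna=False)
    groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    if calibrator_group not in set(groups):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")

    ref_nd = wide[reference_gene].isna()
    for sample in wide.index[ref_nd]:
        logger.warning("sample %r: reference gene ND; sample excluded", sample)
    wide = wide.loc[~ref_nd]
    groups = groups.loc[wide.index]

    delta_ct = wide[target_gene] - wide[reference_gene]
    calib = delta_ct[(groups == calibrator_group) & delta_ct.notna()]
    if len(calib) == 0:
        raise ValueError(
            f"calibrator group {calibrator_group!r} has no sample with a "
            "detected target"
        )
    calibrator_mean = float(calib.mean())
    delta_delta_ct = delta_ct - calibrator_mean
    out = pd.DataFrame(
        {
            "group": groups,
            "delta_ct": delta_ct,
            "delta_delta_ct": delta_delta_ct,
            "fold": np.power(2.0, -delta_delta_ct),
            "detected": delta_ct.notna(),
        }
    )
    out.index.name = "sample_id"
    out.attrs["calibrator_mean_delta_ct"] = calibrator_mean
    out.attrs["target_gene"] = target_gene
    out.attrs["reference_gene"] = reference_gene
    return out


def summarize_groups(rel: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean fold and SEM fold over detected samples.

    SEM = sample standard deviation / sqrt(n); reported as NaN for n < 2,
    mean as NaN for n = 0.
    """
    rows = []
    for group, sub in rel.groupby("group", sort=True):
        folds = sub.loc[sub["detected"], "fold"]
        n = int(len(folds))
        mean = float(folds.mean()) if n else np.nan
        sem = float(folds.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append({"group": group, "n": n, "mean_fold": mean, "sem_fold": sem})
    return pd.DataFrame(rows, columns=["group", "n", "mean_fold", "sem_fold"]).set_index("group")
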