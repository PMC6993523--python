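"""Pathway membership tallies for classified gene sets.

The tally consumes a user-supplied gene -> pathway membership table (e.g.
an export of KEGG Mapper results) rather than querying a pathway database:
term memberships are database-version-dependent, and keeping the table as
explicit input makes the tally reproducible. Disease pathways carry a
boolean flag and can be excluded, mirroring the "without human diseases"
convention of KEGG-based screens. A gene belonging to several pathways
counts once in each, so pathway counts may sum above the number of
annotated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PathwayMapError", "PathwayMap", "PathwayTally", "load_pathway_map", "tally_pathways"]

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


class PathwayMapError(ValueError):
    """The pathway membership table violates the expected format."""


@dataclass
class PathwayMap:
    """Pathway registry plus gene memberships.

    ``pathways`` maps pathway_id -> (name, is_disease); ``memberships``
    maps gene_id -> set of pathway_ids. Every referenced pathway must be
    registered.
    """

    pathways: dict[str, tuple[str, bool]] = field(default_factory=dict)
    memberships: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, pids in self.memberships.items():
            undeclared = pids - set(self.pathways)
            if undeclared:
                raise PathwayMapError(
                    f"gene {gene!r} references undeclared pathway "
                    f"{sorted(undeclared)[0]!r}"
                )

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class PathwayTally:
    """Ordered per-pathway gene counts.

    ``records`` has columns pathway_id, name, n_genes, gene_ids (sorted,
    ';'-joined), ordered by n_genes descending then pathway_id ascending.
    Genes with no pathway membership are reported separately in
    ``unannotated``.
    """

    records: pd.DataFrame
    unannotated: list[str]

    @property
    def n_unannotated(self) -> int:
        return len(self.unannotated)

    @property
    def n_annotated(self) -> int:
        genes: set[str] = set()
        for ids in self.records["gene_ids"]:
            if ids:
                genes.update(ids.split(";"))
        return len(genes)

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _parse_bool(raw: str, pathway_id: str) -> bool:
    low = str(raw).strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise PathwayMapError(f"bad is_disease value {raw!r} for pathway {pathway_id!r}")


def load_pathway_map(path, dialect: str = "tsv") -> PathwayMap:
    """Load a pathway membership TSV.

    Columns: pathway_id, name, is_disease, gene_id. A row with a non-empty
    ``name`` declares the pathway (first declaration wins; conflicting
    redeclarations are an error); a membership row with an empty name must
    reference an already-declared pathway. Rows with empty gene_id are pure
    declarations.
    """
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"pathway_id", "name", "is_disease", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise PathwayMapError(f"pathway table lacks column(s) {sorted(missing)}")
    if len(df) == 0:
        warnings.warn("pathway membership table is empty", stacklevel=2)
        return PathwayMap()
    pathways: dict[str, tuple[str, bool]] = {}
    memberships: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        pid = row["pathway_id"].strip()
        if not pid:
            raise PathwayMapError("row with empty pathway_id")
        name = row["name"].strip()
        if name:
            entry = (name, _parse_bool(row["is_disease"], pid))
            if pid in pathways and pathways[pid] != entry:
                raise PathwayMapError(f"conflicting redeclaration of pathway {pid!r}")
            pathways.setdefault(pid, entry)
        elif pid not in pathways:
            raise PathwayMapError(
                f"row references pathway {pid!r} never declared (no name given)"
            )
        gene = row["gene_id"].strip()
        if gene:
            memberships.setdefault(gene, set()).add(pid)
    return PathwayMap(pathways=pathways, memberships=memberships)


def tally_pathways(genes, pathway_map: PathwayMap, exclude_disease: bool = True) -> PathwayTally:
    """Count input genes per pathway.

    Disease-flagged pathways are removed when ``exclude_disease`` is true
    (a gene annotated only to disease pathways then counts as unannotated).
    Empty inputs yield empty tallies.
    """
    genes = sorted(set(genes))
    per_pathway: dict[str, list[str]] = {}
    unannotated: list[str] = []
    for gene in genes:
        pids = pathway_map.memberships.get(gene, set())
        if exclude_disease:
            pids = {p for p in pids if not pathway_map.pathways[p][1]}
        if not pids:
            unannotated.append(gene)
            continue
        for pid in pids:
            per_pathway.setdefault(pid, []).append(gene)
    rows = [
        {
            "pathway_id": pid,
            "name": pathway_map.pathways[pid][0],
            "n_genes": len(members),
            "gene_ids": ";".join(sorted(members)),
        }
        for pid, members in per_pathway.items()
    ]
    records = pd.DataFrame(rows, columns=["pathway_id", "name", "n_genes", "gene_ids"])
    records = records.sort_values(
        by=["n_genes", "pathway_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return PathwayTally(records=records, unannotated=unannotated)
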