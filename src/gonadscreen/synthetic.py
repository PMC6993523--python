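"""Synthetic inputs with planted truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`generate_count_dataset` — a raw gene x sample count matrix with
  planted gene classes. Counts are negative-binomial (the standard
  overdispersed model for bulk RNA-seq counts) around class-specific
  expected read counts, with per-sample library-size factors; dispersion is
  a parameter so the Poisson limit is reachable. The sample layout mirrors
  the study design: a multi-tissue panel plus a wild-type vs germ-cell-free
  testis contrast (3 WT + 4 GCF by default).
* :func:`generate_ct_table` — qPCR Ct tables with known group dCt
  effects; duplicate wells are offset +-0.1 cycles around the sample Ct so
  replicate averaging is exact in the noise-free limit.
* :func:`generate_alignment` — protein alignments evolved on a known tree
  under a 20-state Jukes-Cantor-type model whose expected Poisson-corrected
  distance equals the path length, so distance estimation is consistent.

All generators take explicit seeds and never touch global random state;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts_io import CountDataset, SampleMeta
from .phylo import AMINO_ACIDS, Alignment, Tree, TreeNode
from .qpcr import CtTable

__all__ = [
    "CLASS_NAMES",
    "EXPECTED_LABEL",
    "ClassMeans",
    "SyntheticSpec",
    "PlantedTruth",
    "generate_count_dataset",
    "generate_ct_table",
    "generate_alignment",
]

#: Planted gene classes.
CLASS_NAMES = (
    "germ_cell_specific",
    "gonadal_somatic",
    "gonad_specific_mixed",
    "ubiquitous",
    "silent",
    "boundary",
)

#: The category each class should receive from the classifier (boundary
#: genes sit on the thresholds and have no reliable expectation).
EXPECTED_LABEL = {
    "germ_cell_specific": "germ_cell_specific",
    "gonadal_somatic": "gonadal_somatic",
    "gonad_specific_mixed": "indeterminate",
    "ubiquitous": "not_gonad_specific",
    "silent": "not_gonad_specific",
    "boundary": None,
}


@dataclass(frozen=True)
class ClassMeans:
    """Expected read counts for one gene class, by expression context."""

    extragonadal: float
    ovary: float
    testis: float
    wt_testis: float
    gcf_testis: float


#: Default class archetypes. Absent-regime means sit 10x below the 50-read
#: cutoff and present-regime means well above 10x the 100-read cutoff, so
#: class membership stays unambiguous relative to sampling noise even after
#: library-size normalization rescales every sample; the mixed class parks
#: the GCF mean between the cutoffs and the boundary class on them. The
#: large ubiquitous class plays the role of background transcription: it
#: dominates every library's total, keeping per-tissue totals comparable
#: (as in real transcriptomes, where a few hundred tissue-specific genes do
#: not move the library size).
DEFAULT_CLASS_MEANS: dict[str, ClassMeans] = {
    "germ_cell_specific": ClassMeans(5.0, 1500.0, 2000.0, 2000.0, 5.0),
    "gonadal_somatic": ClassMeans(5.0, 1500.0, 2000.0, 2000.0, 1500.0),
    "gonad_specific_mixed": ClassMeans(5.0, 1500.0, 2000.0, 2000.0, 75.0),
    "ubiquitous": ClassMeans(1000.0, 1000.0, 1000.0, 1000.0, 1000.0),
    "silent": ClassMeans(1.0, 1.0, 1.0, 1.0, 1.0),
    "boundary": ClassMeans(50.0, 100.0, 100.0, 100.0, 50.0),
}

DEFAULT_PANEL_TISSUES = (
    "brain",
    "eye",
    "gill",
    "heart",
    "liver",
    "muscle",
    "skin",
    "spleen",
    "ovary",
    "testis",
)

_CLASS_PREFIX = {
    "germ_cell_specific": "gc",
    "gonadal_somatic": "som",
    "gonad_specific_mixed": "mix",
    "ubiquitous": "ubi",
    "silent": "sil",
    "boundary": "bnd",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-truth count simulation.

    ``class_sizes`` gives the number of genes per class; ``class_means``
    the expected reads per (class, context); ``dispersion`` the
    negative-binomial size parameter (None = Poisson limit);
    ``library_size_range`` the uniform range of per-sample library factors.
    """

    class_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "germ_cell_specific": 30,
            "gonadal_somatic": 12,
            "gonad_specific_mixed": 8,
            "ubiquitous": 500,
            "silent": 10,
            "boundary": 10,
        }
    )
    class_means: dict[str, ClassMeans] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    panel_tissues: tuple[str, ...] = DEFAULT_PANEL_TISSUES
    panel_replicates: int = 2
    n_wt: int = 3
    n_gcf: int = 4
    dispersion: float | None = 8.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_sizes) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class(es) {sorted(unknown)}")
        if any(n < 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be non-negative")
        if self.panel_replicates < 1:
            raise ValueError("panel group declared with zero samples")
        if self.n_wt < 1 or self.n_gcf < 1:
            raise ValueError("WT and GCF groups each need at least one sample")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must satisfy 0 < lo <= hi")
        if "ovary" not in self.panel_tissues or "testis" not in self.panel_tissues:
            raise ValueError("panel must include ovary and testis")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass
class PlantedTruth:
    """gene_id -> planted class, plus the category the classifier should
    recover for it (None for boundary genes)."""

    classes: dict[str, str]

    def expected_label(self, gene_id: str) -> str | None:
        return EXPECTED_LABEL[self.classes[gene_id]]

    def genes_in_class(self, name: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == name]

    def __len__(self) -> int:
        return len(self.classes)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion is None:
        return rng.poisson(mean)
    # NB with mean m and size r: var = m + m^2/r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _mean_for(means: ClassMeans, tissue: str, group: str) -> float:
    if group == "WT":
        return means.wt_testis
    if group == "GCF":
        return means.gcf_testis
    if tissue == "ovary":
        return means.ovary
    if tissue == "testis":
        return means.testis
    return means.extragonadal


def generate_count_dataset(
    spec: SyntheticSpec,
) -> tuple[CountDataset, SampleMeta, PlantedTruth]:
    """Simulate a raw count dataset with planted gene classes.

    Samples comprise ``panel_replicates`` samples per panel tissue (group
    "other") plus ``n_wt`` WT-testis and ``n_gcf`` GCF-testis samples.
    Expected counts are the class means scaled by a per-sample library
    factor; the raw counts are meant to be normalized with
    :func:`gonadscreen.specificity.normalize_to_smallest` (panel and testis
    contrast separately) before classification.
    """
    rng = np.random.default_rng(spec.seed)

    samples: list[tuple[str, str, str]] = []  # (sample_id, tissue, group)
    for tissue in spec.panel_tissues:
        for r in range(spec.panel_replicates):
            samples.append((f"{tissue}_{r + 1}", tissue, "other"))
    for i in range(spec.n_wt):
        samples.append((f"testis_WT_{i + 1}", "testis", "WT"))
    for i in range(spec.n_gcf):
        samples.append((f"testis_GCF_{i + 1}", "testis", "GCF"))

    gene_ids: list[str] = []
    classes: dict[str, str] = {}
    gene_means: list[ClassMeans] = []
    for cls in CLASS_NAMES:
        n = spec.class_sizes.get(cls, 0)
        means = spec.class_means[cls]
        for i in range(n):
            gid = f"g_{_CLASS_PREFIX[cls]}_{i + 1:03d}"
            gene_ids.append(gid)
            classes[gid] = cls
            gene_means.append(means)
    if not gene_ids:
        raise ValueError("spec generates no genes")

    lo, hi = spec.library_size_range
    factors = rng.uniform(lo, hi, size=len(samples))
    expected = np.empty((len(gene_ids), len(samples)))
    for s, (_, tissue, group) in enumerate(samples):
        col = np.array([_mean_for(m, tissue, group) for m in gene_means])
        expected[:, s] = col * factors[s]
    counts = _draw_counts(rng, expected, spec.dispersion).astype(float)

    counts_df = pd.DataFrame(
        counts, index=gene_ids, columns=[s for s, _, _ in samples]
    )
    meta_df = pd.DataFrame(
        {
            "tissue": [t for _, t, _ in samples],
            "group": [g for _, _, g in samples],
        },
        index=pd.Index([s for s, _, _ in samples], name="sample_id"),
    )
    return (
        CountDataset(counts=counts_df, normalized=False),
        SampleMeta(table=meta_df),
        PlantedTruth(classes=classes),
    )


def generate_ct_table(
    groups: dict[str, tuple[float, float, int]],
    reference_ct: float = 20.0,
    seed: int = 0,
    target_gene: str = "target",
    reference_gene: str = "ef1a",
) -> CtTable:
    """Simulate a duplicate-well Ct table with known group dCt effects.

    ``groups`` maps group label -> (mean dCt, sd, n samples). Each sample's
    target Ct is reference_ct + Normal(mean dCt, sd); duplicate wells are
    written at +-0.1 cycles around the sample Ct, so their average recovers
    it exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(groups):
        mean_dct, sd, n = groups[group]
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if n < 1:
            raise ValueError(f"group {group!r} declared with zero samples")
        for i in range(n):
            sample = f"{group}_{i + 1}"
            target_ct = reference_ct + rng.normal(mean_dct, sd)
            for gene, base in ((reference_gene, reference_ct), (target_gene, target_ct)):
                for rep, offset in ((1, +0.1), (2, -0.1)):
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": base + offset,
                        }
                    )
    return CtTable(table=pd.DataFrame(rows))


def generate_alignment(tree: Tree, length: int, seed: int = 0) -> Alignment:
    """Evolve a protein alignment along a tree with known branch lengths.

    Model: root sequence uniform over the 20 residues; along a branch of
    length t (substitutions/site) each site is hit with probability
    1 - exp(-t * 20/19) and then redrawn uniformly from the 20 residues
    (possibly unchanged). Under this 20-state Jukes-Cantor-type model the
    expected Poisson-corrected distance between two leaves approximates
    their path length (bias < 3% for path lengths up to ~0.3).
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(AMINO_ACIDS)
    root_seq = rng.integers(0, k, size=length)
    taxa: list[str] = []
    rows: list[np.ndarray] = []

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.length is not None:
            if node.length < 0:
                raise ValueError("branch lengths must be >= 0 for simulation")
            p_event = 1.0 - np.exp(-node.length * k / (k - 1))
            hit = rng.random(length) < p_event
            seq = seq.copy()
            seq[hit] = rng.integers(0, k, size=int(hit.sum()))
        if node.is_leaf:
            taxa.append(node.name)
            rows.append(seq)
            return
        for child in node.children:
            walk(child, seq)

    walk(tree.root, root_seq)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    return Alignment(taxa=taxa, rows=[bytes(alphabet[r]).decode() for r in rows])
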