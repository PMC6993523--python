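# Methods

## Normalization and group means

Raw per-gene read counts (one column per sequencing library) are
normalized by scaling every sample to the total of the smallest library:
column *s* is multiplied by min_t(total_t) / total_s, so all column
totals equal the smallest pre-normalization total. This is a pure
library-size correction — no gene-length or composition adjustment — and
it is the normalization the threshold cutoffs are defined against.
Normalization refuses already-normalized input and zero-total samples.

The multi-tissue panel and the WT/GCF testis contrast are treated as
separate sequencing efforts: each is normalized independently and the
per-gene group means are then joined by gene ID (genes present in only
one dataset get mean 0 in the other, with a warning). Thresholds are
applied to arithmetic group means of the normalized counts — per-tissue
means over panel samples, and WT/GCF means over the knockout-contrast
testis samples. Fractional means are never rounded before comparison;
rounding would make boundary behavior depend on the incidental scale
factors.

## The specificity cascade

Two cutoffs, both inclusive: `absent_max` (default 50 reads — at or
below it a gene counts as not expressed; low double-digit counts appear
even for genes known to be absent from a tissue) and `present_min`
(default 100 reads — at or above it a gene counts as expressed; the gap
between the cutoffs separates clear presence from background).

* Gonad-specific: every extra-gonadal tissue mean ≤ absent_max AND ovary
  mean ≥ present_min AND testis mean ≥ present_min. The filter is
  undefined (an error) without at least one extra-gonadal tissue.
* Compartments, within the gonad-specific set: gonadal_somatic iff both
  WT and GCF testis means ≥ present_min; germ_cell_specific iff WT ≥
  present_min and GCF ≤ absent_max; otherwise `indeterminate`. Genes
  outside the set are `not_gonad_specific`.

A mean in the open interval (absent_max, present_min) satisfies neither
rule. Such genes are labelled `indeterminate` rather than dropped, so
the number of genes the cascade discards is always auditable. Every gene
receives exactly one label, and tightening either cutoff can only shrink
the gonad-specific, germ-cell and somatic sets (tested as a property).

Fold changes between WT and GCF means are symmetric (max/min ≥ 1) with
an explicit direction; a zero on either side gives an *undefined* fold,
never infinity, so sorting stays total.

## Pathway tallies

The tally consumes an explicit gene → pathway membership TSV instead of
querying a live database: term memberships drift across database
releases, and an explicit table keeps the tally reproducible. Pathways
carry a user-declared disease flag; with `exclude_disease` the flagged
pathways are removed and genes annotated only to them count as
unannotated. A gene in several pathways counts once per pathway, so
pathway counts may sum above the number of annotated genes. Ordering is
deterministic: count descending, then pathway ID ascending.

## Comparative-Ct qPCR

Technical replicate wells are averaged on the Ct scale (standard
practice; averaging folds instead would change results only at third
decimal places for typical well scatter but is not what instruments
assume). ΔCt = Ct(target) − Ct(reference gene) per sample; ΔΔCt
subtracts the arithmetic mean ΔCt of the designated calibrator group;
fold = 2^−ΔΔCt with amplification efficiency fixed at 2 (no efficiency
correction). "ND" (not detected) propagates: an ND target gives
detected = false, an ND reference excludes the sample with a warning,
and ND is never imputed as a maximal cycle number — a failed well
carries no quantity. Group summaries report mean and SEM
(sd/√n, n ≥ 2) over detected samples only. Two identities pin the
arithmetic down: the fold implied by the calibrator group's mean ΔCt is
exactly 1, and shifting every Ct by a constant leaves all folds
unchanged.

## Phylogeny

Distances: for each sequence pair, alignment columns where either
sequence has '-' or 'X' are removed (pairwise deletion; complete
deletion — dropping a column if any sequence is ambiguous there — is
available behind `deletion="complete"`). Other ambiguity codes (B, Z,
\*) are rejected at parse with a clear error rather than silently
reinterpreted. p = differing / compared sites; Poisson correction
d = −ln(1 − p) expresses the distance in expected amino-acid
substitutions per site under a uniform-rate model. A pair with zero
comparable sites is an error, not a guess.

Neighbor joining is the Saitou–Nei agglomeration on the Q-criterion.
Ties in Q go to the lowest (i, j) index pair in the current node
ordering, making runs bit-reproducible. Branch lengths use the canonical
NJ formulas and negative lengths are retained as computed — clamping
would break the exact additivity NJ guarantees on additive inputs (and
which the tests assert); `negative_branch_lengths` lists them for
reporting.

Bootstrap: alignment columns are resampled with replacement per
replicate (500 by default), each replicate gets its own distance matrix
and NJ tree, and bipartition frequencies become support percentages. The
consensus is majority-rule: bipartitions are admitted in order of
decreasing support (lexicographic tie-break) subject to compatibility,
and branches with support strictly below the collapse threshold
(default 50%) are collapsed — support exactly at the threshold is
retained. One deliberate rule: an internal replicate edge whose
estimated length is ≤ 0 is not counted as evidence for its bipartition.
A zero-length NJ edge arises from ties in the distance matrix, not from
signal; with this rule an alignment containing no information (e.g. all
rows identical) collapses to a star instead of echoing whichever
resolved topology the deterministic tie-break happens to produce in
every replicate. Consensus branch lengths are means over the replicates
containing each edge (terminal branches: means over all replicates);
they are descriptive, not an optimality claim. Newick output quotes
labels containing metacharacters and writes supports as internal-node
labels; parsing back (via dendropy) recovers topology, lengths and
supports.

## Synthetic data

The count generator emulates the study design: a multi-tissue panel
(10 tissues including ovary and testis, 2 replicates each — panel
replication is a free choice; the analysis only uses per-tissue means)
plus 3 WT and 4 GCF testis libraries. Counts are negative-binomial with
size 8 (typical bulk RNA-seq overdispersion, CV ≈ 0.35 at high means;
`dispersion=None` gives the Poisson limit) around class × context
expected reads, scaled by per-sample library factors drawn uniformly
from [0.7, 1.3].

Planted classes and their default expected reads (extragonadal / ovary /
panel testis / WT / GCF):

| class | means | expected label |
|---|---|---|
| germ_cell_specific (30) | 5 / 1500 / 2000 / 2000 / 5 | germ_cell_specific |
| gonadal_somatic (12) | 5 / 1500 / 2000 / 2000 / 1500 | gonadal_somatic |
| gonad_specific_mixed (8) | 5 / 1500 / 2000 / 2000 / 75 | indeterminate |
| ubiquitous (500) | 1000 everywhere | not_gonad_specific |
| silent (10) | 1 everywhere | not_gonad_specific |
| boundary (10) | 50 / 100 / 100 / 100 / 50 | none (on the cutoffs) |

The large ubiquitous class is the background transcriptome: it
dominates every library's total, which keeps per-tissue library sizes
comparable so that normalization rescales the planted means only
moderately (by the library-factor range times a composition ratio near
1). Without such background, tissue totals would be driven by the
planted gonadal classes themselves and normalization would compress the
planted margins. Absent-regime means sit 10× below the 50-read cutoff
and present-regime means stay ≥ 10× above the 100-read cutoff after
normalization, so ≥ 95% planted-label recovery is expected and asserted
over five seeds; boundary-class genes sit on the cutoffs and are only
asserted to err more often than the clear classes.

What the generator does *not* emulate: gene-length effects, GC or
composition biases, correlated genes, batch structure, or read-level
noise (no FASTQ). Passing recovery tests therefore demonstrates that the
cascade implements its definitions correctly under the assumed
count-generating model, not that the thresholds are optimal for any real
dataset.

The qPCR generator writes duplicate wells at ±0.1 cycles around each
sample's Ct, so replicate averaging is exact in the sd = 0 limit; group
ΔCt effects are Normal(mean, sd). The alignment generator evolves a
uniform random root sequence along a tree: on a branch of length t each
site is hit with probability 1 − exp(−t·20/19) and redrawn uniformly
from the 20 residues (possibly unchanged), a 20-state Jukes–Cantor-type
model whose Poisson-corrected leaf-to-leaf distances approximate path
lengths with < 3% bias for divergences up to ~0.3 substitutions/site —
consistent with the Poisson correction's own uniform-rate assumption.

## Pipeline and problem sizes

The pipeline runs filter → classify → fold-change report → optional
pathway tally in one of three input modes (raw tables, pre-averaged
summary, synthetic), writes per-category TSVs plus a JSON report, and
logs thresholds, seed and SHA-256 digests of the inputs. Reruns with the
same config and seed are byte-identical. The pre-averaged summary mode
exists so published average-read tables can be classified directly; a
summary without extra-gonadal columns is taken as already gonad-filtered.

Test and acceptance runs use deliberately desk-scale problem sizes —
570-gene synthetic matrices over 27 samples, 500-replicate bootstraps of
5-taxon alignments (2 kb), and one 50 kb two-taxon alignment for the
distance-consistency check; each suite finishes in seconds while leaving
the statistical margins (sampling CVs of a few percent against 10×
threshold margins) wide enough that the assertions are not borderline.

## Known limitations

* The screen is purely threshold-based by design: no dispersion
  modelling, no hypothesis testing, no FDR control. Genes near the
  cutoffs land in `indeterminate` and need other evidence.
* Replicated panels are averaged per tissue; a single aberrant panel
  library directly shifts its tissue mean.
* The published multi-tissue and testis datasets themselves are not
  shipped; headline gene counts that depend on them (389 gonad-specific,
  194 germ-cell-specific) are outside what the worked example can
  reproduce.
* The consensus tree's branch lengths are replicate means attached to
  consensus edges, comparable across runs but not an estimate with
  optimality guarantees.
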