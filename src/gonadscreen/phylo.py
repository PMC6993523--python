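"""Protein phylogenies: Poisson-corrected distances, neighbor-joining,
bootstrap majority-rule consensus, Newick I/O.

The distance pipeline follows the classic distance-matrix recipe for
protein alignments: per sequence pair, alignment columns where either
sequence has a gap ('-') or unknown residue ('X') are removed (pairwise
deletion); the p-distance is the fraction of differing residues among the
remaining columns; the Poisson correction d = -ln(1 - p) converts it to an
expected number of amino-acid substitutions per site under a uniform-rate
model. Complete deletion (drop a column if *any* sequence is ambiguous
there) is available via ``deletion="complete"``.

Neighbor joining is the standard Saitou-Nei agglomeration on the
Q-criterion. Ties in Q are broken toward the lowest (i, j) index pair in
the current node ordering, which makes runs bit-reproducible. Negative
branch lengths are retained as computed (clamping would break exact
additivity on additive inputs); :func:`negative_branch_lengths` lists them.

Bootstrap support resamples alignment columns with replacement, rebuilds a
distance+NJ tree per replicate, and tallies bipartitions; the consensus is
built by majority rule with branches below the collapse threshold removed
(a bipartition at exactly the threshold is retained — "less than 50%" is
strict). Internal replicate edges of non-positive estimated length are not
counted as grouping evidence: an NJ edge of length zero reflects ties, not
signal, so an alignment with no information collapses to a star.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUOUS",
    "AlignmentError",
    "DistanceError",
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "read_alignment_fasta",
    "pairwise_p_distance",
    "poisson_distance",
    "poisson_distance_matrix",
    "neighbor_joining",
    "negative_branch_lengths",
    "bootstrap_consensus",
    "majority_rule_consensus",
    "write_newick",
    "read_newick",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Characters excluded per pair when computing distances.
AMBIGUOUS = frozenset("-X")
_ALLOWED = frozenset(AMINO_ACIDS) | AMBIGUOUS


class AlignmentError(ValueError):
    """An alignment violates the expected format."""


class DistanceError(ValueError):
    """A pairwise distance is undefined."""


@dataclass
class Alignment:
    """A protein multiple alignment: equal-length rows over the 20 residues
    plus gap '-' and ambiguity 'X'. Other ambiguity codes (B, Z, *) are
    rejected at construction with a clear error rather than silently
    reinterpreted."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if not self.rows:
            raise AlignmentError("empty alignment")
        self.rows = [r.upper() for r in self.rows]
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError("alignment length must be >= 1")
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"row for {taxon!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - _ALLOWED
            if bad:
                raise AlignmentError(
                    f"row for {taxon!r} contains unsupported character(s) "
                    f"{sorted(bad)}; allowed: 20 residues, '-' and 'X'"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_matrix(self) -> np.ndarray:
        """Integer encoding: residue index 0..19, -1 for '-'/'X'."""
        lut = np.full(128, -1, dtype=np.int8)
        for i, aa in enumerate(AMINO_ACIDS):
            lut[ord(aa)] = i
        return np.stack(
            [lut[np.frombuffer(row.encode(), dtype=np.uint8)] for row in self.rows]
        )


def read_alignment_fasta(path) -> Alignment:
    """Read an aligned FASTA file (Biopython parser)."""
    from Bio import SeqIO

    taxa, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        taxa.append(record.id)
        rows.append(str(record.seq))
    if not taxa:
        raise AlignmentError(f"no sequences found in {path}")
    return Alignment(taxa=taxa, rows=rows)


def pairwise_p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing residues with pairwise deletion.

    Columns where either sequence has '-' or 'X' are excluded; returns
    (p, number of compared sites). Raises :class:`DistanceError` when no
    site is comparable.
    """
    if len(a) != len(b):
        raise AlignmentError("sequences differ in length")
    n = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in AMBIGUOUS or y in AMBIGUOUS:
            continue
        n += 1
        if x != y:
            diff += 1
    if n == 0:
        raise DistanceError("no comparable sites for this sequence pair")
    return diff / n, n


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p), substitutions per site."""
    if not 0 <= p < 1:
        raise DistanceError(f"Poisson correction undefined for p={p}")
    return -math.log1p(-p)


@dataclass
class DistanceMatrix:
    """Symmetric distances with per-pair comparable-site counts."""

    taxa: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T, rtol=0, atol=1e-12):
            raise ValueError("distance matrix is asymmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix has nonzero diagonal")
        if (self.d < 0).any():
            raise ValueError("distance matrix has negative entries")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])


def poisson_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Poisson-corrected distances for all pairs of an alignment.

    ``deletion`` is "pairwise" (default; ambiguous columns dropped per
    pair) or "complete" (columns with any ambiguity dropped globally
    before comparison).
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    mat = aln.to_matrix()
    if deletion == "complete":
        keep = (mat >= 0).all(axis=0)
        if not keep.any():
            raise DistanceError("complete deletion removes every column")
        mat = mat[:, keep]
    n = aln.n_taxa
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] >= 0) & (mat[j] >= 0)
            n_sites = int(ok.sum())
            if n_sites == 0:
                raise DistanceError(
                    f"no comparable sites for pair ({aln.taxa[i]!r}, {aln.taxa[j]!r})"
                )
            p = float((mat[i, ok] != mat[j, ok]).mean())
            d[i, j] = d[j, i] = poisson_distance(p)
            sites[i, j] = sites[j, i] = n_sites
    return DistanceMatrix(taxa=list(aln.taxa), d=d, comparable_sites=sites)


# ---------------------------------------------------------------------------
# Tree container


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None  # length of the edge to the parent
    support: float | None = None  # bootstrap % for the edge to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


_NEWICK_META = set("()[]{}:;,'\" \t\n")


def _quote_label(label: str) -> str:
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class Tree:
    """An (un)rooted tree; unrooted trees are stored rooted at an arbitrary
    internal node of degree >= 3. Internal-node ``support`` values, when
    present, are bootstrap percentages for the edge above the node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def edges(self):
        """Yield (parent, child) pairs."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                yield node, child
                stack.append(child)

    def bipartitions(self) -> set[frozenset]:
        """Leaf bipartitions induced by internal edges, each encoded as the
        side that excludes the lexicographically smallest taxon."""
        all_taxa = frozenset(self.leaf_names())
        ref = min(all_taxa)
        parts: set[frozenset] = set()
        for _, child in self.edges():
            clade = frozenset(_leaf_names_under(child))
            if len(clade) < 2 or len(clade) > len(all_taxa) - 2:
                continue  # terminal or root-adjacent trivial split
            side = all_taxa - clade if ref in clade else clade
            parts.add(side)
        return parts

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (sum of branch lengths)."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.name]: 0.0}
            below: list[dict[int, float]] = []
            for child in node.children:
                sub = walk(child)
                sub = {k: v + (child.length or 0.0) for k, v in sub.items()}
                below.append(sub)
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for i, di in below[a].items():
                        for j, dj in below[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            merged: dict[int, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return names, dist

    def to_newick(self, include_support: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                label = _quote_label(node.name or "")
            else:
                inner = ",".join(render(c) for c in node.children)
                sup = ""
                if include_support and node.support is not None:
                    sup = format(node.support, "g")
                label = f"({inner}){sup}"
            if node.length is not None:
                label += f":{node.length:.10g}"
            return label

        return render(self.root) + ";"


def _leaf_names_under(node: TreeNode) -> list[str]:
    if node.is_leaf:
        return [node.name]
    out: list[str] = []
    for child in node.children:
        out.extend(_leaf_names_under(child))
    return out


def write_newick(tree: Tree, path, include_support: bool = True) -> None:
    """Write a tree as Newick with branch lengths; supports (if any) become
    internal-node labels. Labels containing metacharacters are quoted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick(include_support=include_support) + "\n")


def read_newick(path_or_string) -> Tree:
    """Parse Newick (dendropy parser) into a :class:`Tree`.

    Internal-node labels that parse as numbers are interpreted as bootstrap
    supports.
    """
    import dendropy

    text = str(path_or_string)
    if not text.strip().endswith(";"):
        with open(text, encoding="utf-8") as fh:
            text = fh.read()
    dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon is not None else None
        support = None
        if children and dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                name = dnode.label
        node = TreeNode(
            name=name,
            length=dnode.edge.length,
            support=support,
            children=children,
        )
        return node

    return Tree(root=convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    Requires n >= 3 defined, symmetric, non-negative distances. At each
    step the pair (i, j) minimizing Q is joined; ties go to the lowest
    (i, j) index pair in the current node ordering. Branch lengths come
    from the canonical NJ formulas and may be negative; they are retained
    as computed.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 0.0:  # strict improvement keeps lowest (i, j) on ties
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining nodes
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_new[: m - 2, m - 2] = dk[keep]
        d_new[m - 2, : m - 2] = dk[keep]
        d_new[m - 2, m - 2] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # final three nodes: three-point formulas around the root
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    return Tree(root=TreeNode(children=[a, b, c]))


def negative_branch_lengths(tree: Tree) -> list[tuple[str, float]]:
    """List (description, length) for branches with negative length."""
    out = []
    for _, child in tree.edges():
        if child.length is not None and child.length < 0:
            label = child.name or "internal:" + ",".join(sorted(_leaf_names_under(child)))
            out.append((label, child.length))
    return out


# ---------------------------------------------------------------------------
# Bootstrap consensus


def _compatible(clade: frozenset, others) -> bool:
    return all(
        clade <= other or other <= clade or not (clade & other) for other in others
    )


def majority_rule_consensus(
    bipartition_pct: dict[frozenset, float],
    taxa: list[str],
    collapse_pct: float = 50.0,
    branch_lengths: dict[frozenset, float] | None = None,
    terminal_lengths: dict[str, float] | None = None,
) -> Tree:
    """Build a consensus tree from bipartition support percentages.

    Bipartitions with support < ``collapse_pct`` are collapsed (support
    exactly at the threshold is retained). Surviving bipartitions are added
    in order of decreasing support (ties broken lexicographically) subject
    to pairwise compatibility; the result may be multifurcating.

    Bipartitions must be encoded as the side excluding the smallest taxon
    (see :meth:`Tree.bipartitions`); they then act as clades in a tree
    rooted next to that taxon, and compatibility is nestedness/disjointness.
    """
    ref = min(taxa)
    accepted: list[frozenset] = []
    ordered = sorted(
        bipartition_pct.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )
    for clade, pct in ordered:
        if pct < collapse_pct:
            continue
        if ref in clade:
            raise ValueError("bipartitions must exclude the reference taxon")
        if _compatible(clade, accepted):
            accepted.append(clade)

    # assemble the laminar clade family into a tree
    nodes: dict[frozenset, TreeNode] = {}
    for clade in accepted:
        nodes[clade] = TreeNode(support=bipartition_pct[clade])
        if branch_lengths and clade in branch_lengths:
            nodes[clade].length = branch_lengths[clade]
    leaf_nodes = {
        t: TreeNode(name=t, length=(terminal_lengths or {}).get(t)) for t in taxa
    }
    root = TreeNode()
    by_size = sorted(accepted, key=len, reverse=True)
    for clade in by_size:
        parents = [c for c in by_size if clade < c]
        parent = nodes[min(parents, key=len)] if parents else root
        parent.children.append(nodes[clade])
    for taxon in taxa:
        containers = [c for c in by_size if taxon in c]
        parent = nodes[min(containers, key=len)] if containers else root
        parent.children.append(leaf_nodes[taxon])
    return Tree(root=root)


def bootstrap_consensus(
    aln: Alignment,
    n_reps: int = 500,
    collapse_pct: float = 50.0,
    seed: int = 0,
    deletion: str = "pairwise",
) -> Tree:
    """Bootstrap majority-rule consensus of distance+NJ trees.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate gets a Poisson-corrected distance matrix and an NJ tree.
    Support for a bipartition is the percentage of replicates whose tree
    contains it with positive internal branch length; bipartitions below
    ``collapse_pct`` are collapsed (exactly at the threshold: retained).
    Branch lengths on the consensus are means over the replicates
    containing each edge. All resampling is governed by ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if aln.n_taxa < 3:
        raise AlignmentError("bootstrap consensus requires >= 3 taxa")
    rng = np.random.default_rng(seed)
    mat = aln.to_matrix()
    length = aln.length
    counts: dict[frozenset, int] = {}
    length_sums: dict[frozenset, float] = {}
    term_sums = {t: 0.0 for t in aln.taxa}
    all_taxa = frozenset(aln.taxa)
    ref = min(all_taxa)

    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep = Alignment(taxa=list(aln.taxa), rows=_rows_from(mat[:, cols]))
        dm = poisson_distance_matrix(rep, deletion=deletion)
        tree = neighbor_joining(dm)
        for _, child in tree.edges():
            if child.is_leaf:
                term_sums[child.name] += child.length or 0.0
                continue
            if child.length is None or child.length <= 0:
                continue  # zero-length internal edge: ties, not signal
            clade = frozenset(_leaf_names_under(child))
            if len(clade) < 2 or len(clade) > len(all_taxa) - 2:
                continue
            side = all_taxa - clade if ref in clade else clade
            counts[side] = counts.get(side, 0) + 1
            length_sums[side] = length_sums.get(side, 0.0) + (child.length or 0.0)

    pct = {clade: 100.0 * c / n_reps for clade, c in counts.items()}
    mean_lengths = {clade: length_sums[clade] / counts[clade] for clade in counts}
    terminal = {t: term_sums[t] / n_reps for t in aln.taxa}
    return majority_rule_consensus(
        pct,
        taxa=list(aln.taxa),
        collapse_pct=collapse_pct,
        branch_lengths=mean_lengths,
        terminal_lengths=terminal,
    )


def _rows_from(mat: np.ndarray) -> list[str]:
    alphabet = np.frombuffer((AMINO_ACIDS + "-").encode(), dtype=np.uint8)
    return [bytes(alphabet[row]).decode() for row in mat]
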