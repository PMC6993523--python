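import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gonadscreen.phylo import (
    Alignment,
    AlignmentError,
    DistanceError,
    DistanceMatrix,
    Tree,
    TreeNode,
    bootstrap_consensus,
    majority_rule_consensus,
    neighbor_joining,
    pairwise_p_distance,
    poisson_distance,
    poisson_distance_matrix,
    read_newick,
    write_newick,
)
from gonadscreen.synthetic import generate_alignment


# ---------------------------------------------------------------------------
# distances


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,p,n",
        [
            ("ACDE", "ACDE", 0.0, 4),
            ("ACDE", "ACDK", 0.25, 4),
            ("ACD-", "ACDE", 0.0, 3),  # pairwise deletion removes site 4
            ("AXDE", "ACD-", 0.0, 2),
        ],
    )
    def test_examples(self, a, b, p, n):
        assert pairwise_p_distance(a, b) == (p, n)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(DistanceError, match="comparable"):
            pairwise_p_distance("--XX", "AC--")

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            pairwise_p_distance("AC", "ACD")


class TestPoissonCorrection:
    @pytest.mark.parametrize(
        "p,d",
        [(0.0, 0.0), (0.5, 0.6931), (0.1, 0.1054)],
    )
    def test_closed_forms(self, p, d):
        assert poisson_distance(p) == pytest.approx(d, abs=5e-5)

    @pytest.mark.parametrize("p", [1.0, 1.5, -0.1])
    def test_out_of_domain_rejected(self, p):
        with pytest.raises(DistanceError):
            poisson_distance(p)

    @given(st.floats(0, 0.99))
    def test_increasing_and_at_least_p(self, p):
        d = poisson_distance(p)
        assert d >= p
        assert poisson_distance(min(p + 0.005, 0.995)) > d


def test_alignment_rejects_other_ambiguity_codes():
    with pytest.raises(AlignmentError, match="B"):
        Alignment(taxa=["t1", "t2"], rows=["AB", "AC"])
    with pytest.raises(AlignmentError, match=r"\*"):
        Alignment(taxa=["t1", "t2"], rows=["A*", "AC"])


def test_complete_deletion_drops_columns_globally():
    aln = Alignment(taxa=["a", "b", "c"], rows=["ACDE", "AC-E", "ACDE"])
    pairwise = poisson_distance_matrix(aln, deletion="pairwise")
    complete = poisson_distance_matrix(aln, deletion="complete")
    assert pairwise.comparable_sites[0, 2] == 4
    off_diag = complete.comparable_sites[~np.eye(3, dtype=bool)]
    assert (off_diag == 3).all()


# ---------------------------------------------------------------------------
# neighbor joining


def tree_path_matrix(tree: Tree, order):
    names, dist = tree.path_lengths()
    idx = {n: i for i, n in enumerate(names)}
    return np.array([[dist[idx[a], idx[b]] for b in order] for a in order])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            taxa=["A", "B", "C"], d=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}
        assert tree.to_newick() == "(A:1,B:2,C:3);"

    def test_four_taxon_additive_matrix_recovers_generating_tree(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(taxa=list("ABCD"), d=d)
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert np.allclose(tree_path_matrix(tree, "ABCD"), d)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_random_additive_six_taxon_matrix_reproduced_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            tree = random_binary_tree(list("ABCDEF"), rng)
            order = sorted(tree.leaf_names())
            d = tree_path_matrix(tree, order)
            nj = neighbor_joining(DistanceMatrix(taxa=order, d=d))
            assert np.allclose(tree_path_matrix(nj, order), d, atol=1e-9)

    def test_asymmetric_and_negative_matrices_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            DistanceMatrix(taxa=["A", "B", "C"],
                           d=np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))
        with pytest.raises(ValueError, match="negative"):
            DistanceMatrix(taxa=["A", "B", "C"],
                           d=np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]]))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(DistanceMatrix(taxa=["A", "B"], d=np.zeros((2, 2))))


# --- exhaustive least-squares oracle -------------------------------------


def random_binary_tree(taxa, rng) -> Tree:
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=t, length=float(rng.uniform(0.5, 3.0))) for t in taxa]
    rng.shuffle(nodes)
    while len(nodes) > 3:
        a = nodes.pop()
        b = nodes.pop()
        parent = TreeNode(length=float(rng.uniform(0.5, 3.0)), children=[a, b])
        nodes.append(parent)
        rng.shuffle(nodes)
    root = TreeNode(children=nodes)
    for child in nodes:
        if child.length is None:
            child.length = float(rng.uniform(0.5, 3.0))
    return Tree(root=root)


def enumerate_topologies(taxa):
    """All unrooted binary topologies as edge lists (leaves are taxon
    labels, internal nodes negative ints)."""
    first = [(taxa[0], -1), (taxa[1], -1), (taxa[2], -1)]
    topologies = [first]
    next_internal = -2
    for taxon in taxa[3:]:
        grown = []
        for edges in topologies:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:i] + edges[i + 1:]
                new_edges += [(u, w), (v, w), (taxon, w)]
                grown.append(new_edges)
        topologies = grown
        next_internal -= 1
    return topologies


def topology_bipartitions(edges, taxa):
    ref = min(taxa)
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
    parts = set()
    for u, v in edges:
        # leaves on v's side after removing edge (u, v)
        seen, stack = {u, v}, [v]
        side = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nxt in adjacency[node] - seen:
                seen.add(nxt)
                stack.append(nxt)
        if 2 <= len(side) <= len(taxa) - 2:
            parts.add(frozenset(side) if ref not in side else frozenset(taxa) - frozenset(side))
    return parts


def least_squares_residual(edges, taxa, d):
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)

    def path_edges(a, b):
        prev = {a: None}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nxt in adjacency[node]:
                if nxt not in prev:
                    prev[nxt] = node
                    stack.append(nxt)
        path = []
        node = b
        while prev[node] is not None:
            path.append(frozenset({node, prev[node]}))
            node = prev[node]
        return path

    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d[taxa.index(a), taxa.index(b)] for a, b in pairs])
    for row, (a, b) in enumerate(pairs):
        for e in path_edges(a, b):
            A[row, edge_index[e]] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_topology_is_least_squares_optimum_on_additive_inputs(n_taxa):
    """For <=6 taxa, NJ picks the topology with the (zero) least-squares
    residual among all unrooted binary topologies."""
    rng = np.random.default_rng(100 + n_taxa)
    taxa = [chr(65 + i) for i in range(n_taxa)]
    tree = random_binary_tree(list(taxa), rng)
    d = tree_path_matrix(tree, taxa)
    nj = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    residuals = {}
    for edges in enumerate_topologies(taxa):
        parts = frozenset(topology_bipartitions(edges, taxa))
        res = least_squares_residual(edges, taxa, d)
        residuals[parts] = min(res, residuals.get(parts, math.inf))
    best = min(residuals, key=residuals.get)
    assert residuals[best] == pytest.approx(0.0, abs=1e-16)
    assert frozenset(nj.bipartitions()) == best


def test_nj_matches_independent_implementation():
    """Cross-check topology against scikit-bio's neighbor joining."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(8)
    tree = random_binary_tree(list("ABCDEFG"), rng)
    order = sorted(tree.leaf_names())
    d = tree_path_matrix(tree, order)
    ours = neighbor_joining(DistanceMatrix(taxa=order, d=d))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=order))
    their_parts = set()
    all_taxa = frozenset(order)
    ref = min(order)
    for node in theirs.non_tips():
        clade = frozenset(t.name for t in node.tips())
        if 2 <= len(clade) <= len(order) - 2:
            their_parts.add(clade if ref not in clade else all_taxa - clade)
    assert ours.bipartitions() == their_parts


# ---------------------------------------------------------------------------
# newick


class TestNewick:
    def test_three_taxon_star_string(self):
        tree = Tree(
            root=TreeNode(
                children=[
                    TreeNode(name="A", length=1.0),
                    TreeNode(name="B", length=2.0),
                    TreeNode(name="C", length=3.0),
                ]
            )
        )
        assert tree.to_newick() == "(A:1,B:2,C:3);"

    def test_round_trip_recovers_topology_lengths_supports(self, tmp_path):
        rng = np.random.default_rng(2)
        tree = random_binary_tree(list("ABCDE"), rng)
        for _, child in tree.edges():
            if not child.is_leaf:
                child.support = 87.0
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.bipartitions() == tree.bipartitions()
        lengths_orig = sorted(c.length for _, c in tree.edges())
        lengths_back = sorted(c.length for _, c in back.edges())
        assert np.allclose(lengths_orig, lengths_back, atol=1e-9)
        supports = [c.support for _, c in back.edges() if not c.is_leaf]
        assert supports and all(s == 87.0 for s in supports)

    def test_metacharacter_labels_survive_quoting(self, tmp_path):
        tree = Tree(
            root=TreeNode(
                children=[
                    TreeNode(name="sp. (1)", length=1.0),
                    TreeNode(name="B", length=2.0),
                    TreeNode(name="C", length=3.0),
                ]
            )
        )
        path = tmp_path / "q.nwk"
        write_newick(tree, path)
        assert "'sp. (1)'" in path.read_text()
        back = read_newick(path)
        assert sorted(back.leaf_names()) == ["B", "C", "sp. (1)"]


# ---------------------------------------------------------------------------
# bootstrap consensus


TRUE_TREE = "((A:0.1,B:0.1):0.06,(C:0.1,D:0.1):0.06,E:0.16);"
TRUE_PARTS = {frozenset({"C", "D"}), frozenset({"C", "D", "E"})}


class TestBootstrapConsensus:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_true_bipartitions_strongly_supported(self, seed):
        """Long simulated alignments recover every generating bipartition
        with high support."""
        aln = generate_alignment(read_newick(TRUE_TREE), length=2000, seed=seed)
        consensus = bootstrap_consensus(aln, n_reps=500, collapse_pct=50, seed=seed)
        supports = {
            frozenset(sorted(_leaves_under(child))): child.support
            for _, child in consensus.edges()
            if not child.is_leaf
        }
        for part in TRUE_PARTS:
            assert part in consensus.bipartitions()
        retained = [c.support for _, c in consensus.edges() if not c.is_leaf]
        assert all(s >= 95 for s in retained)

    def test_supports_bounded_and_above_threshold(self):
        aln = generate_alignment(read_newick(TRUE_TREE), length=200, seed=0)
        consensus = bootstrap_consensus(aln, n_reps=100, collapse_pct=50, seed=0)
        for _, child in consensus.edges():
            if not child.is_leaf:
                assert 0 <= child.support <= 100
                assert child.support >= 50

    def test_support_exactly_at_threshold_retained(self):
        """'Less than 50%' is strict: a bipartition at exactly 50 stays."""
        taxa = ["A", "B", "C", "D"]
        consensus = majority_rule_consensus(
            {frozenset({"C", "D"}): 50.0}, taxa=taxa, collapse_pct=50.0
        )
        assert frozenset({"C", "D"}) in consensus.bipartitions()
        collapsed = majority_rule_consensus(
            {frozenset({"C", "D"}): 49.9}, taxa=taxa, collapse_pct=50.0
        )
        assert collapsed.bipartitions() == set()

    def test_identical_rows_collapse_to_star(self):
        aln = Alignment(taxa=list("ABCDE"), rows=["ACDEFGHIKL"] * 5)
        consensus = bootstrap_consensus(aln, n_reps=50, seed=0)
        assert consensus.bipartitions() == set()
        assert len(consensus.root.children) == 5

    def test_zero_replicates_rejected(self):
        aln = Alignment(taxa=list("ABC"), rows=["ACDE", "ACDK", "ACKE"])
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_consensus(aln, n_reps=0)

    def test_incompatible_equal_support_resolved_deterministically(self):
        taxa = ["A", "B", "C", "D", "E"]
        parts = {
            frozenset({"B", "C"}): 60.0,
            frozenset({"C", "D"}): 60.0,  # incompatible with {B,C}
        }
        consensus = majority_rule_consensus(parts, taxa=taxa)
        # lexicographic tie-break admits {B,C} first; {C,D} conflicts
        assert consensus.bipartitions() == {frozenset({"B", "C"})}


def _leaves_under(node):
    if node.is_leaf:
        return [node.name]
    out = []
    for child in node.children:
        out.extend(_leaves_under(child))
    return out
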