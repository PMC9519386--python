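import numpy as np
import pytest

from caseinlab import phylo
from caseinlab.align import Alignment
from caseinlab.phylo import (
    Clade,
    DistanceMatrix,
    UndefinedDistanceError,
    bipartitions,
    bootstrap_supports,
    nj_tree,
    p_distance_matrix,
    parse_newick,
    root_on_outgroup,
    similarity_matrix,
)


def aln_of(**rows) -> Alignment:
    return Alignment(ids=tuple(rows), rows=rows)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_similarity_identical_rows():
    sim = similarity_matrix(aln_of(a="ACDE", b="ACDE"))
    assert sim[("a", "b")] == 100.0


def test_similarity_hand_count():
    sim = similarity_matrix(aln_of(a="ACDE", b="ACDF"))
    assert sim[("a", "b")] == pytest.approx(75.0)
    p = p_distance_matrix(aln_of(a="ACDE", b="ACDF"))
    assert p[("a", "b")] == pytest.approx(0.25)


def test_pairwise_deletion_ignores_gapped_columns():
    sim = similarity_matrix(aln_of(a="AC-E", b="ACDE"))
    assert sim[("a", "b")] == pytest.approx(100.0)


def test_all_gap_pair_raises_named_error():
    with pytest.raises(UndefinedDistanceError, match="a.*b"):
        p_distance_matrix(aln_of(a="--AC", b="AC--"))


def test_similarity_and_p_distance_are_complements(make_protein):
    rows = {f"s{i}": make_protein(40) for i in range(4)}
    aln = aln_of(**rows)
    sim, p = similarity_matrix(aln), p_distance_matrix(aln)
    assert np.allclose(sim.values, 100.0 * (1.0 - p.values))
    assert np.allclose(sim.values, sim.values.T)
    assert np.allclose(np.diag(sim.values), 100.0)
    assert np.allclose(np.diag(p.values), 0.0)


def test_column_subsampling_preserves_matrix_invariants(make_protein, rng):
    rows = {f"s{i}": make_protein(60) for i in range(4)}
    aln = aln_of(**rows)
    cols = rng.integers(0, 60, 30)
    sub = aln_of(**{k: "".join(v[c] for c in cols) for k, v in rows.items()})
    p = p_distance_matrix(sub)
    assert np.allclose(p.values, p.values.T)
    assert np.allclose(np.diag(p.values), 0.0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def dm(labels, arr):
    return DistanceMatrix(tuple(labels), np.asarray(arr, float), "p-distance")


def tree_path_lengths(tree: Clade) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths via root-to-leaf accumulation."""
    depths: dict[str, float] = {}
    paths: dict[str, list[int]] = {}

    def walk(node, depth, path):
        if node.is_leaf:
            depths[node.name] = depth
            paths[node.name] = path
            return
        for c in node.children:
            walk(c, depth + (c.length or 0.0), path + [id(c)])

    walk(tree, 0.0, [])
    out = {}
    names = list(depths)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = 0.0
            node, depth = tree, 0.0
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] == pb[k]:
                k += 1
            # depth of last common ancestor
            lca_depth = 0.0
            node = tree
            for step in pa[:k]:
                child = next(c for c in node.children if id(c) == step)
                lca_depth += child.length or 0.0
                node = child
            out[frozenset((a, b))] = depths[a] + depths[b] - 2 * lca_depth
    return out


def test_three_taxon_closed_form():
    d = dm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = nj_tree(d)
    lengths = {c.name: c.length for c in tree.children}
    assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_nj_recovers_additive_four_taxon_tree_exactly():
    # tree ((A:1,B:2):1,(C:3,D:4)) scaled by 0.1
    d = dm("ABCD", np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                             [5, 6, 0, 7], [6, 7, 7, 0]]) * 0.1)
    tree = nj_tree(d)
    assert bipartitions(tree) == {frozenset({"C", "D"})}
    paths = tree_path_lengths(tree)
    for pair, expected in {("A", "B"): 0.3, ("A", "C"): 0.5, ("A", "D"): 0.6,
                           ("B", "C"): 0.6, ("B", "D"): 0.7, ("C", "D"): 0.7}.items():
        assert paths[frozenset(pair)] == pytest.approx(expected, abs=1e-9)


def test_nj_recovers_additive_five_taxon_tree_exactly():
    # unrooted caterpillar ((A:1,B:2):1,C:3,(D:4,E:5):1) scaled by 0.05
    true = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 7, ("A", "E"): 8,
            ("B", "C"): 6, ("B", "D"): 8, ("B", "E"): 9,
            ("C", "D"): 8, ("C", "E"): 9, ("D", "E"): 9}
    labels = "ABCDE"
    arr = np.zeros((5, 5))
    for (a, b), v in true.items():
        i, j = labels.index(a), labels.index(b)
        arr[i, j] = arr[j, i] = v * 0.05
    tree = nj_tree(dm(labels, arr))
    assert bipartitions(tree) == {frozenset({"C", "D", "E"}), frozenset({"D", "E"})}
    paths = tree_path_lengths(tree)
    for pair, v in true.items():
        assert paths[frozenset(pair)] == pytest.approx(v * 0.05, abs=1e-9)


def test_nj_matches_scikit_bio_topology(rng):
    """Independent oracle: scikit-bio's NJ on noisy additive matrices."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    base = np.array([[0, 2, 7, 8, 9], [2, 0, 7, 8, 9], [7, 7, 0, 5, 8],
                     [8, 8, 5, 0, 7], [9, 9, 8, 7, 0]], float) * 0.05
    for _ in range(5):
        noise = rng.uniform(0, 0.01, base.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        d = base + noise
        labels = tuple("ABCDE")
        ours = bipartitions(nj_tree(dm(labels, d)))
        sk_tree = skbio_nj(SkbioDM(d, ids=labels))
        theirs = set()
        all_leaves = frozenset(labels)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if "A" in side:
                side = all_leaves - side
            if 2 <= len(side) <= 3:
                theirs.add(side)
        assert ours == theirs


def test_nj_requires_three_taxa_and_symmetry():
    with pytest.raises(ValueError):
        nj_tree(dm("AB", [[0, 1], [1, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]), "p-distance")


def test_branch_lengths_non_negative_after_clamping(make_protein):
    rows = {f"s{i}": make_protein(30) for i in range(6)}
    tree = nj_tree(p_distance_matrix(aln_of(**rows)))
    assert all((c.length or 0.0) >= 0.0 for c in tree.walk() if c is not tree)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


def test_rooting_three_taxon_tree_on_outgroup():
    tree = nj_tree(dm("ABC", [[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]))
    rooted = root_on_outgroup(tree, "A")
    assert len(rooted.children) == 2
    names = sorted(c.name or "internal" for c in rooted.children)
    assert "A" in names
    other = next(c for c in rooted.children if c.name != "A")
    assert sorted(other.leaf_names()) == ["B", "C"]


def test_rooting_is_idempotent():
    tree = nj_tree(dm("ABCD", np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                                        [5, 6, 0, 7], [6, 7, 7, 0]]) * 0.1))
    once = root_on_outgroup(tree, "D")
    twice = root_on_outgroup(once, "D")
    assert once.to_newick() == twice.to_newick()


def test_rooting_preserves_unrooted_splits(make_protein):
    rows = {f"s{i}": make_protein(50) for i in range(6)}
    tree = nj_tree(p_distance_matrix(aln_of(**rows)))
    before = bipartitions(tree)
    rooted = root_on_outgroup(tree, "s0")
    assert bipartitions(rooted) == before


def test_rooting_unknown_label_rejected():
    tree = nj_tree(dm("ABC", [[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]))
    with pytest.raises(ValueError):
        root_on_outgroup(tree, "Z")


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def test_newick_cherry():
    tree = Clade(children=[Clade(name="A", length=1.0), Clade(name="B", length=1.0)])
    assert tree.to_newick() == "(A:1.000000,B:1.000000);"


def test_newick_round_trip_preserves_everything():
    text = "((A:0.100000,B:0.200000)95:0.050000,(C:0.300000,D:0.400000)100:0.060000);"
    tree = parse_newick(text)
    assert tree.to_newick() == text
    inner = [c for c in tree.children]
    assert {c.support for c in inner} == {95.0, 100.0}


def test_newick_round_trip_preserves_split_set(make_protein):
    rows = {f"s{i}": make_protein(80) for i in range(6)}
    tree = nj_tree(p_distance_matrix(aln_of(**rows)))
    again = parse_newick(tree.to_newick())
    assert bipartitions(again) == bipartitions(tree)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def separated_pairs_alignment() -> Alignment:
    a = "A" * 30
    b = "W" * 15 + "A" * 15
    return aln_of(p1=a, p2=a, q1=b, q2=b)


def test_bootstrap_trivially_separated_pairs_get_full_support():
    tree = bootstrap_supports(separated_pairs_alignment(), n_reps=50, seed=0)
    supports = [c.support for c in tree.walk()
                if c is not tree and not c.is_leaf and c.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_supports_bounded_and_deterministic(make_protein):
    rows = {f"s{i}": make_protein(40) for i in range(5)}
    aln = aln_of(**rows)
    t1 = bootstrap_supports(aln, n_reps=30, seed=42)
    t2 = bootstrap_supports(aln, n_reps=30, seed=42)
    assert t1.to_newick() == t2.to_newick()
    for c in t1.walk():
        if c.support is not None:
            assert 0.0 <= c.support <= 100.0


def test_bootstrap_supports_invariant_to_label_order(make_protein):
    rows = {f"s{i}": make_protein(60) for i in range(5)}
    aln1 = Alignment(ids=tuple(rows), rows=rows)
    rev = tuple(reversed(list(rows)))
    aln2 = Alignment(ids=rev, rows=rows)
    def support_map(tree):
        out = {}
        all_leaves = frozenset(tree.leaf_names())
        ref = min(all_leaves)
        for node in tree.walk():
            if node is tree or node.is_leaf or node.support is None:
                continue
            side = frozenset(node.leaf_names())
            if ref in side:
                side = all_leaves - side
            out[side] = node.support
        return out
    s1 = support_map(bootstrap_supports(aln1, n_reps=40, seed=3))
    s2 = support_map(bootstrap_supports(aln2, n_reps=40, seed=3))
    assert s1 == s2


def test_confirmed_edges_use_strict_90_threshold():
    tree = bootstrap_supports(separated_pairs_alignment(), n_reps=20, seed=1)
    confirmed = phylo.confirmed_edges(tree)
    assert confirmed  # both internal edges at 100% > 90%
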