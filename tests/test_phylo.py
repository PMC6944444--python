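"""Distances, neighbour joining (with additive-matrix oracles), bootstrap
supports and clade flagging."""

import itertools

import numpy as np
import pytest

from madascan import phylo
from madascan.align import Alignment


def test_distances_identical_rows_zero():
    msa = Alignment(ids=["a", "b", "c"], rows=["MADAV"] * 3)
    dm = phylo.compute_distances(msa)
    assert np.allclose(dm.matrix, 0.0)


def test_distances_simple_fraction():
    msa = Alignment(ids=["a", "b"], rows=["AAAAAAAAAA", "AAACCCAAAA"])
    dm = phylo.compute_distances(msa)
    assert dm.matrix[0, 1] == pytest.approx(0.3)


def test_distances_match_counting_oracle():
    rng = np.random.default_rng(4)
    aa = "ACDEFGHIKLMNPQRSTVWY-"
    rows = ["".join(aa[i] for i in rng.integers(0, 21, size=50)) for _ in range(5)]
    # ensure every pair has comparable columns
    rows = [r[:10].replace("-", "A") + r[10:] for r in rows]
    msa = Alignment(ids=[f"t{i}" for i in range(5)], rows=rows)
    dm = phylo.compute_distances(msa)
    for i, j in itertools.combinations(range(5), 2):
        comp = diff = 0
        for x, y in zip(rows[i], rows[j]):
            if x != "-" and y != "-":
                comp += 1
                diff += x != y
        assert dm.matrix[i, j] == pytest.approx(diff / comp)


def test_distances_no_comparable_columns_error():
    msa = Alignment(ids=["a", "b"], rows=["A-", "-A"])
    with pytest.raises(ValueError, match="non-gap columns"):
        phylo.compute_distances(msa)


def _tree_distances_from_topology(split, lengths):
    """Additive distances for 4 taxa under topology ((i,j),(k,l)) with
    leaf branch lengths and one internal branch."""
    (i, j), (k, l) = split
    la, lb, lc, ld, lm = lengths
    d = np.zeros((4, 4))
    leaf_len = {i: la, j: lb, k: lc, l: ld}
    for x, y in itertools.combinations(range(4), 2):
        same = {x, y} in ({i, j}, {k, l})
        d[x, y] = d[y, x] = leaf_len[x] + leaf_len[y] + (0 if same else lm)
    return d


def test_nj_recovers_additive_four_taxon_tree():
    """NJ recovers the generating topology and branch lengths exactly; the
    oracle fits all three unrooted topologies by least squares and the
    generating one must be the unique perfect fit."""
    ids = list("ABCD")
    split = ((0, 1), (2, 3))
    d = _tree_distances_from_topology(split, (2.0, 3.0, 4.0, 5.0, 1.0))
    dm = phylo.DistanceMatrix(ids=ids, matrix=d)
    tree = phylo.nj_tree(dm)
    bps = set(tree.bipartitions())
    assert bps == {frozenset({"C", "D"})}  # canonical side excludes A
    # branch lengths: every leaf-to-leaf path equals the input distance
    for x, y in itertools.combinations(range(4), 2):
        assert tree.path_length(ids[x], ids[y]) == pytest.approx(d[x, y])
    # oracle: enumerate all three topologies, the generating one fits best
    best_fit, best_topo = None, None
    for topo in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        residuals = []
        for lengths in [np.linalg.lstsq(
                _design_matrix(topo), _upper(d), rcond=None)[0]]:
            pred = _design_matrix(topo) @ lengths
            residuals.append(np.sum((pred - _upper(d)) ** 2))
        if best_fit is None or residuals[0] < best_fit:
            best_fit, best_topo = residuals[0], topo
    assert best_topo == split and best_fit == pytest.approx(0.0, abs=1e-18)


def _upper(d):
    return np.array([d[x, y] for x, y in itertools.combinations(range(4), 2)])


def _design_matrix(topo):
    """Pairwise-path design matrix over (4 leaf branches + internal)."""
    (i, j), (k, l) = topo
    rows = []
    for x, y in itertools.combinations(range(4), 2):
        row = np.zeros(5)
        row[x] = row[y] = 1
        if {x, y} not in ({i, j}, {k, l}):
            row[4] = 1
        rows.append(row)
    return np.array(rows)


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
    tree = phylo.nj_tree(phylo.DistanceMatrix(ids=list("ABC"), matrix=d))
    lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
    assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
    assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
    assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)


def test_nj_star_matrix_zero_internal_branches():
    n = 5
    d = np.full((n, n), 2.0)
    np.fill_diagonal(d, 0.0)
    tree = phylo.nj_tree(phylo.DistanceMatrix(
        ids=[f"t{i}" for i in range(n)], matrix=d))

    def internal_lengths(node):
        for child in node.children:
            if not child.is_leaf():
                yield child.length
                yield from internal_lengths(child)

    assert all(abs(x) < 1e-9 for x in internal_lengths(tree.root))


def test_nj_matches_skbio_on_random_matrices():
    """Independent cross-check: scikit-bio's NJ yields the same topology
    (bipartition set) on random additive-ish matrices."""
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(11)
    for _ in range(5):
        n = 6
        coords = rng.random((n, 4)) * 5
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        mine = phylo.nj_tree(phylo.DistanceMatrix(ids=ids, matrix=d))
        ref_tree = skbio_nj(skbio.DistanceMatrix(d, ids))
        ref_bps = set()
        all_leaves = frozenset(ids)
        ref_leaf = min(ids)
        for node in ref_tree.non_tips():
            clade = frozenset(t.name for t in node.tips())
            if 1 < len(clade) < n - 1:
                side = clade if ref_leaf not in clade else all_leaves - clade
                ref_bps.add(side)
        assert set(mine.bipartitions()) == ref_bps


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    n = 7
    coords = rng.random((n, 3))
    d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    ids = [f"t{i}" for i in range(n)]
    base = phylo.nj_tree(phylo.DistanceMatrix(ids=ids, matrix=d))
    perm = rng.permutation(n)
    permuted = phylo.nj_tree(phylo.DistanceMatrix(
        ids=[ids[p] for p in perm], matrix=d[np.ix_(perm, perm)]))
    assert set(base.bipartitions()) == set(permuted.bipartitions())


def test_nj_additive_path_lengths():
    """On an additive matrix the tree's leaf-to-leaf path lengths equal
    the input distances to 1e-9 (6 taxa, caterpillar tree)."""
    ids = list("ABCDEF")
    # caterpillar: A,B | C | D | E,F along a chain of internal edges
    leaf_len = dict(A=1.0, B=2.0, C=1.5, D=2.5, E=1.2, F=0.7)
    attach = dict(A=0, B=0, C=1, D=2, E=3, F=3)  # internal node index
    internal = [0.8, 0.9, 1.1]  # edges between consecutive internal nodes
    d = np.zeros((6, 6))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                lo, hi = sorted((attach[a], attach[b]))
                d[i, j] = d[j, i] = (leaf_len[a] + leaf_len[b]
                                    + sum(internal[lo:hi]))
    tree = phylo.nj_tree(phylo.DistanceMatrix(ids=ids, matrix=d))
    for i, j in itertools.combinations(range(6), 2):
        assert abs(tree.path_length(ids[i], ids[j]) - d[i, j]) < 1e-9


def _two_family_msa():
    rows = ["AAAAAAAAAA", "AAAAAAAAAC", "TTTTTTTTTT", "TTTTTTTTTG"]
    return Alignment(ids=["a1", "a2", "b1", "b2"], rows=rows)


def test_bootstrap_clear_split_full_support():
    tree = phylo.bootstrap_support(_two_family_msa(), n_replicates=50, seed=0)
    bps = tree.bipartitions()
    assert len(bps) == 1
    assert list(bps.values()) == [1.0]


def test_bootstrap_zero_replicates_no_support():
    tree = phylo.bootstrap_support(_two_family_msa(), n_replicates=0)
    assert all(s is None for s in tree.bipartitions().values())


def test_bootstrap_seeded_determinism():
    rng = np.random.default_rng(9)
    aa = "ACDEFG"
    rows = ["".join(aa[i] for i in rng.integers(0, 6, size=30)) for _ in range(6)]
    msa = Alignment(ids=[f"s{i}" for i in range(6)], rows=rows)
    t1 = phylo.bootstrap_support(msa, n_replicates=30, seed=123)
    t2 = phylo.bootstrap_support(msa, n_replicates=30, seed=123)
    assert t1.bipartitions() == t2.bipartitions()


def test_flag_clade_trivial_cases():
    tree = phylo.bootstrap_support(_two_family_msa(), n_replicates=20, seed=0)
    leaves = set(tree.leaf_names())
    assert phylo.flag_clade(tree, sorted(leaves)) == leaves
    assert phylo.flag_clade(tree, ["a1"]) == {"a1"}
    with pytest.raises(KeyError):
        phylo.flag_clade(tree, ["ghost"])


def test_flag_clade_planted_family(pipeline_result):
    """On the synthetic NB-ARC tree, anchoring two helpers flags exactly
    the helper family."""
    truth_of = {t.record_id: t for t in pipeline_result.truths}
    clade = phylo.flag_clade(pipeline_result.tree,
                             ["helper_f1_001", "helper_f1_002"], 0.7)
    roles = {truth_of[i].role for i in clade}
    assert roles == {"helper"}
    helpers_in_tree = {i for i in pipeline_result.tree.leaf_names()
                       if truth_of[i].role == "helper"}
    assert clade == helpers_in_tree


def test_newick_roundtrip(tmp_path):
    d = np.array([[0, 2, 3, 4], [2, 0, 3.5, 4.5], [3, 3.5, 0, 5], [4, 4.5, 5, 0]])
    tree = phylo.nj_tree(phylo.DistanceMatrix(ids=list("ABCD"), matrix=d))
    path = tmp_path / "t.nwk"
    phylo.write_newick(tree, path)
    back = phylo.read_newick(path)
    assert set(back.leaf_names()) == set("ABCD")
    assert set(back.bipartitions()) == set(tree.bipartitions())


def test_phylip_roundtrip(tmp_path):
    d = np.array([[0, 0.5, 0.25], [0.5, 0, 0.75], [0.25, 0.75, 0]])
    dm = phylo.DistanceMatrix(ids=["x", "y", "z"], matrix=d)
    path = tmp_path / "d.phy"
    phylo.write_phylip(dm, path)
    back = phylo.read_phylip(path)
    assert back.ids == dm.ids
    assert np.allclose(back.matrix, dm.matrix)
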