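"""Distances, neighbor joining, bootstrap support, clade assignment."""

import math

import numpy as np
import pytest

from familyscope import phylo as ph
from familyscope.align import Alignment


def random_additive_matrix(rng, n_taxa):
    """Random binary tree -> path-length matrix + its topology."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # random topology built by sequential attachment; edges > 0
    nodes = {i: ph.TreeNode(name=ids[i]) for i in range(3)}
    root = ph.TreeNode(children=list(nodes.values()))
    edges = []  # (child, parent)
    for c in root.children:
        edges.append((c, root))
    for i in range(3, n_taxa):
        child, parent = edges[rng.integers(0, len(edges))]
        mid = ph.TreeNode()
        parent.children.remove(child)
        parent.children.append(mid)
        leaf = ph.TreeNode(name=ids[i])
        mid.children = [child, leaf]
        edges.remove((child, parent))
        edges.extend([(child, mid), (leaf, mid), (mid, parent)])
    # assign branch lengths
    lengths = {}
    for child, _ in edges:
        child.length = float(rng.uniform(0.1, 1.0))
    # path lengths between tips
    def paths(node, acc):
        if node.is_leaf():
            yield node.name, acc
        for c in node.children:
            yield from paths(c, acc + c.length)
    D = np.zeros((n_taxa, n_taxa))
    # distance via recursive pairing at each internal node
    def tipdist(node):
        below = {}
        for c in node.children:
            if c.is_leaf():
                part = {c.name: c.length}
            else:
                part = {t: d + c.length for t, d in tipdist(c).items()}
            for t1, d1 in part.items():
                for grp in below.values():
                    for t2, d2 in grp.items():
                        i, j = ids.index(t1), ids.index(t2)
                        D[i, j] = D[j, i] = d1 + d2
            below[id(c)] = part
        merged = {}
        for part in below.values():
            merged.update(part)
        return merged
    tipdist(root)
    tree = ph.PhyloTree(root=root)
    return ph.DistanceMatrix(ids, D), tree


class TestComputeDistances:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b", "c"], ["MKVA", "MKVA", "MKVC"])
        dm = ph.compute_distances(aln)
        assert dm.values[0, 1] == 0.0

    def test_poisson_closed_form(self):
        # p = 0.5 over 4 shared columns -> d = ln 2
        aln = Alignment(["a", "b", "c"], ["MKVA", "MRVC", "MKVA"])
        dm = ph.compute_distances(aln)
        assert dm.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_counted_mismatch_fraction(self, rng):
        # 200 shared columns with exactly 40 mismatches -> d = -ln(0.8)
        a = list("ACDEF" * 40)
        b = list(a)
        flip = rng.choice(200, size=40, replace=False)
        for i in flip:
            b[i] = "W" if a[i] != "W" else "Y"
        aln = Alignment(["a", "b", "c"],
                        ["".join(a), "".join(b), "".join(a)])
        dm = ph.compute_distances(aln)
        assert dm.values[0, 1] == pytest.approx(-math.log(0.8), rel=1e-12)

    def test_no_shared_columns_is_error(self):
        aln = Alignment(["a", "b", "c"], ["M-A-", "-K-C", "MKAC"])
        with pytest.raises(ValueError, match="share"):
            ph.compute_distances(aln)


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        D = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        tree = ph.build_nj_tree(ph.DistanceMatrix(["a", "b", "c"], D))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": 3.0, "b": 2.0, "c": 6.0}

    def test_four_taxon_additive_vs_exhaustive_fit(self, rng):
        # oracle: least-squares fit of all three quartet topologies
        for _ in range(20):
            dm, true_tree = random_additive_matrix(rng, 4)
            nj = ph.build_nj_tree(dm)
            nj_split = {frozenset(s) for s in nj.bipartitions()}
            ids = dm.ids
            best_split, best_err = None, None
            for x in (1, 2, 3):
                # topology {t0, tx} | rest: four-point residual
                a, b = ids[0], ids[x]
                c, d = [ids[i] for i in (1, 2, 3) if i != x]
                i = {t: ids.index(t) for t in ids}
                err = abs((dm.values[i[a], i[c]] + dm.values[i[b], i[d]])
                          - (dm.values[i[a], i[d]] + dm.values[i[b], i[c]]))
                split = frozenset({a, b})
                if best_err is None or err < best_err:
                    best_split, best_err = split, err
            anchor = min(ids)
            canon = (frozenset(ids) - best_split
                     if anchor in best_split else best_split)
            assert canon in nj_split

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_additive_matrix_recovered(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            dm, true_tree = random_additive_matrix(rng, n_taxa)
            nj = ph.build_nj_tree(dm)
            assert (set(nj.bipartitions())
                    == set(true_tree.bipartitions()))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            ph.build_nj_tree(ph.DistanceMatrix(["a", "b", "c"], D))

    def test_agrees_with_skbio_on_random_matrices(self):
        # independent cross-check against an established NJ implementation
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(77)
        for _ in range(5):
            dm, _ = random_additive_matrix(rng, 7)
            ours = ph.build_nj_tree(dm)
            sk_tree = sk_nj(skbio.DistanceMatrix(dm.values, dm.ids))
            all_tips = frozenset(dm.ids)
            anchor = min(all_tips)
            sk_splits = set()
            for node in sk_tree.non_tips(include_self=False):
                below = frozenset(t.name for t in node.tips())
                side = all_tips - below if anchor in below else below
                if 0 < len(side) < len(all_tips):
                    sk_splits.add(side)
            assert set(ours.bipartitions()) == sk_splits


def _family_alignment(rng, n_per_family=4, n_cols=120, divergence=0.3):
    """Two well-separated families of similar rows."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    anc1 = rng.choice(list(alphabet), size=n_cols)
    anc2 = anc1.copy()
    flip = rng.choice(n_cols, size=int(divergence * n_cols), replace=False)
    for i in flip:
        anc2[i] = alphabet[(alphabet.index(anc2[i]) + 1) % 20]
    rows, ids = [], []
    for fam, anc in (("x", anc1), ("y", anc2)):
        for i in range(n_per_family):
            row = anc.copy()
            for j in rng.choice(n_cols, size=3, replace=False):
                row[j] = alphabet[(alphabet.index(row[j]) + 2) % 20]
            ids.append(f"{fam}{i}")
            rows.append("".join(row))
    return Alignment(ids, rows)


class TestBootstrapSupport:
    def test_separating_edge_full_support(self, rng):
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=50, seed=1)
        fam_x = frozenset(t for t in tree.tip_names if t.startswith("x"))
        all_tips = frozenset(tree.tip_names)
        anchor = min(all_tips)
        side = all_tips - fam_x if anchor in fam_x else fam_x
        bip = tree.bipartitions()
        assert side in bip
        assert bip[side].support == 1.0

    def test_single_replicate_supports_binary(self, rng):
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=1, seed=2)
        sups = {n.support for n in tree.internal_nodes()}
        assert sups <= {0.0, 1.0}

    def test_star_data_low_internal_support(self):
        # rows mutually equidistant: no bipartition should be strongly
        # supported (exchangeability -> supports spread thin)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        rng = np.random.default_rng(3)
        n, L = 8, 400
        rows = []
        base = rng.choice(list(alphabet), size=L)
        for i in range(n):
            row = base.copy()
            own = rng.choice(L, size=60, replace=False)
            for j in own:
                row[j] = alphabet[(alphabet.index(row[j]) + 1 + i) % 20]
            rows.append("".join(row))
        aln = Alignment([f"s{i}" for i in range(n)], rows)
        tree = ph.bootstrap_support(aln, n_replicates=100, seed=4)
        sups = [n.support for n in tree.internal_nodes()]
        assert np.mean(sups) < 0.8

    def test_invalid_replicates(self, rng):
        aln = _family_alignment(rng)
        with pytest.raises(ValueError):
            ph.bootstrap_support(aln, n_replicates=0)

    def test_support_invariant_to_row_order(self, rng):
        aln = _family_alignment(rng)
        rev = Alignment(list(reversed(aln.ids)), list(reversed(aln.rows)))
        t1 = ph.bootstrap_support(aln, n_replicates=30, seed=5)
        t2 = ph.bootstrap_support(rev, n_replicates=30, seed=5)
        s1 = {s: n.support for s, n in t1.bipartitions().items()}
        s2 = {s: n.support for s, n in t2.bipartitions().items()}
        assert set(s1) == set(s2)


class TestCladeAssignment:
    def _supported_tree(self):
        # three labelled clades (III, XII, V) plus the stray tip q4 at the
        # trifurcating root
        r_a = ph.TreeNode(name="r_a", length=0.1)
        q1 = ph.TreeNode(name="q1", length=0.1)
        n1 = ph.TreeNode(children=[q1, r_a], length=0.2, support=0.95)
        r_b1 = ph.TreeNode(name="r_b1", length=0.1)
        r_b2 = ph.TreeNode(name="r_b2", length=0.1)
        q2 = ph.TreeNode(name="q2", length=0.1)
        n2 = ph.TreeNode(children=[q2, r_b2], length=0.2, support=0.9)
        n3 = ph.TreeNode(children=[r_b1, n2], length=0.2, support=0.85)
        r_c = ph.TreeNode(name="r_c", length=0.1)
        q5 = ph.TreeNode(name="q5", length=0.1)
        n4 = ph.TreeNode(children=[q5, r_c], length=0.2, support=0.8)
        q4 = ph.TreeNode(name="q4", length=0.4)
        inner = ph.TreeNode(children=[n3, n4], length=0.1, support=0.3)
        root = ph.TreeNode(children=[n1, inner, q4])
        return ph.PhyloTree(root=root)

    def test_query_joins_homogeneous_supported_clade(self):
        tree = self._supported_tree()
        labels = {"r_a": "III", "r_b1": "XII", "r_b2": "XII",
                  "r_c": "V"}
        out = ph.assign_subfamily_groups(tree, labels, 0.70)
        assert out["q1"] == "III"
        assert out["q2"] == "XII"
        assert out["q5"] == "V"

    def test_reference_tips_keep_labels(self):
        tree = self._supported_tree()
        labels = {"r_a": "III", "r_b1": "XII", "r_b2": "XII",
                  "r_c": "V"}
        out = ph.assign_subfamily_groups(tree, labels, 0.70)
        assert out["r_a"] == "III" and out["r_b1"] == "XII"

    def test_tip_outside_any_supported_clade_unassigned(self):
        tree = self._supported_tree()
        labels = {"r_a": "III", "r_b1": "XII", "r_b2": "XII",
                  "r_c": "V"}
        out = ph.assign_subfamily_groups(tree, labels, 0.70)
        assert out["q4"] == "unassigned"

    def test_no_references_is_error(self):
        tree = self._supported_tree()
        with pytest.raises(ValueError):
            ph.assign_subfamily_groups(tree, {"zz": "I"}, 0.70)

    def test_split_xii_by_exemplar_clades(self):
        tree = self._supported_tree()
        labels = {"r_a": "III", "r_b1": "XIIb", "r_b2": "XIIb",
                  "r_c": "V"}
        coarse = ph.assign_subfamily_groups(
            tree, {"r_a": "III", "r_b1": "XII", "r_b2": "XII",
                   "r_c": "V"}, 0.70)
        fine = ph.split_group_xii(tree, coarse, labels, 0.70)
        assert fine["q2"] == "XIIb"
        assert fine["r_b1"] == "XIIb"

    def test_split_without_xiib_reference_warns_all_xiia(self, caplog):
        tree = self._supported_tree()
        coarse = ph.assign_subfamily_groups(
            tree, {"r_a": "III", "r_b1": "XII", "r_b2": "XII",
                   "r_c": "V"}, 0.70)
        fine = ph.split_group_xii(tree, coarse,
                                  {"r_b1": "XIIa", "r_a": "III"}, 0.70)
        xii_tips = [t for t, lab in coarse.items() if lab == "XII"]
        assert xii_tips and all(fine[t] == "XIIa" for t in xii_tips)


class TestWellSupportedClades:
    def test_all_supports_high_every_internal_edge(self):
        rng = np.random.default_rng(11)
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=20, seed=6)
        for n in tree.internal_nodes():
            n.support = 1.0
        clades = ph.find_well_supported_clades(tree, 0.70)
        assert len(clades) == len(tree.internal_nodes())

    def test_all_supports_low_empty(self):
        rng = np.random.default_rng(12)
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=20, seed=7)
        for n in tree.internal_nodes():
            n.support = 0.5
        assert ph.find_well_supported_clades(tree, 0.70) == []

    def test_matches_exhaustive_edge_scan(self):
        rng = np.random.default_rng(13)
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=40, seed=8)
        expected = {frozenset(n.tips()) for n in tree.internal_nodes()
                    if n.support is not None and n.support > 0.70}
        got = {c.tips for c in ph.find_well_supported_clades(tree, 0.70)}
        assert got == expected

    def test_parent_links_nest(self):
        rng = np.random.default_rng(14)
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=40, seed=9)
        clades = ph.find_well_supported_clades(tree, 0.0)
        for c in clades:
            if c.parent is not None:
                assert c.tips < clades[c.parent].tips


class TestNewickRoundTrip:
    def test_write_read_preserves_tips_and_supports(self, tmp_path, rng):
        aln = _family_alignment(rng)
        tree = ph.bootstrap_support(aln, n_replicates=10, seed=10)
        p = tmp_path / "t.nwk"
        tree.write(p)
        back = ph.read_newick(p)
        assert sorted(back.tip_names) == sorted(tree.tip_names)
        assert set(back.bipartitions()) == set(tree.bipartitions())
        orig = {s: n.support for s, n in tree.bipartitions().items()}
        redo = {s: n.support for s, n in back.bipartitions().items()}
        for s in orig:
            assert redo[s] == pytest.approx(orig[s], abs=1e-4)
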