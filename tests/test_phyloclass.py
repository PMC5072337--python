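"""Trimming, distances, neighbor joining, assignment, presence/absence."""

import itertools

import dendropy
import numpy as np
import pytest

from famforge.formats import AMINO_ACIDS, Alignment, tree_to_newick
from famforge.phyloclass import (D_MAX, DistanceMatrix, assign_subfamilies,
                                 build_nj, distance_matrix, poisson_distance,
                                 presence_absence, trim_alignment)


class TestTrim:
    def test_gapless_identity(self):
        aln = Alignment({"a": "ACDEF", "b": "ACDEG"})
        trimmed, kept = trim_alignment(aln)
        assert trimmed == aln and kept == [0, 1, 2, 3, 4]

    def test_all_gap_column_always_removed(self):
        aln = Alignment({"a": "A-C", "b": "A-C", "c": "A-D"})
        trimmed, kept = trim_alignment(aln, max_gap_fraction=0.99)
        assert kept == [0, 2] and trimmed.n_cols == 2

    def test_kept_columns_match_brute_force_gap_count(self):
        rng = np.random.default_rng(6)
        rows = {}
        for i in range(8):
            rows[f"r{i}"] = "".join(
                "-" if rng.random() < 0.4 else str(rng.choice(list(AMINO_ACIDS)))
                for _ in range(30))
        rows["anchor"] = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        aln = Alignment(rows)
        frac = 0.5
        _, kept = trim_alignment(aln, max_gap_fraction=frac)
        expected = [c for c in range(30)
                    if sum(aln.rows[r][c] == "-" for r in aln.rows) / 9 <= frac]
        assert kept == expected

    def test_all_columns_gone_error(self):
        aln = Alignment({"a": "A-", "b": "-C", "c": "-C"})
        with pytest.raises(ValueError):
            trim_alignment(aln, max_gap_fraction=0.0)


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment({"a": "ACDEFGHIKLMN", "b": "ACDEFGHIKLMN",
                         "c": "ACDEFGHIKLMN"})
        dm = distance_matrix(aln)
        assert np.allclose(dm.values, 0.0)

    def test_poisson_half_closed_form(self):
        assert poisson_distance(0.5) == pytest.approx(-np.log(0.5), abs=1e-12)
        # and through the matrix path: 6 of 12 shared columns differ
        a = "ACDEFGHIKLMN"
        b = "ACDEFGWWWWWW"
        aln = Alignment({"a": a, "b": b, "c": a})
        dm = distance_matrix(aln)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.values[i, j] == pytest.approx(0.693147, abs=1e-6)

    def test_saturation_cap(self):
        assert poisson_distance(1.0) == D_MAX

    def test_symmetry_zero_diagonal_random(self):
        rng = np.random.default_rng(9)
        rows = {f"r{i}": "".join(rng.choice(list(AMINO_ACIDS), size=25))
                for i in range(6)}
        dm = distance_matrix(Alignment(rows))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_too_few_shared_columns_error_names_pair(self):
        aln = Alignment({"a": "ACDEF-----", "b": "-----GHIKL",
                         "c": "ACDEFGHIKL"})
        with pytest.raises(ValueError, match="'a' and 'b'"):
            distance_matrix(aln)

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            distance_matrix(Alignment({"a": "ACDEFGHIKLMN", "b": "ACDEFGHIKLMN"}))


def random_additive_case(rng, n=6):
    """A random bifurcating tree with branch lengths and its exact
    path-length (additive) distance matrix."""
    taxa = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=taxa.new_taxon(f"t{i}")) for i in range(n)]
    active = list(nodes)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        p = dendropy.Node()
        for idx in (i, j):
            c = active[idx]
            p.add_child(c)
            c.edge.length = float(rng.uniform(0.1, 1.0))
        active = [active[k] for k in range(len(active)) if k not in (i, j)] + [p]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = active[0]
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    ids = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.distance(taxa.get_taxon(ids[i]),
                                         taxa.get_taxon(ids[j]))
    return DistanceMatrix(ids, D), tree


def same_topology(t1, t2) -> bool:
    back = dendropy.Tree.get(data=tree_to_newick(t1), schema="newick",
                             taxon_namespace=t2.taxon_namespace)
    return dendropy.calculate.treecompare.symmetric_difference(back, t2) == 0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = build_nj(dm)
        assert tree_to_newick(tree) == "(a:1.0,b:2.0,c:3.0);"

    def test_four_taxon_additive_vs_least_squares_oracle(self):
        """NJ recovers the generating quartet topology; cross-checked by
        brute-force least-squares fit of all 3 unrooted quartets."""
        # quartet ((a,b),(c,d)) with internal branch 1.0
        ids = ["a", "b", "c", "d"]
        D = np.array([[0.0, 0.6, 1.9, 2.1],
                      [0.6, 0.0, 1.9, 2.1],
                      [1.9, 1.9, 0.0, 0.8],
                      [2.1, 2.1, 0.8, 0.0]])
        dm = DistanceMatrix(ids, D)

        # oracle: for each of the 3 quartets solve the 5-branch least
        # squares and keep the best fit
        def quartet_rss(pair):
            (i, j), (k, l) = pair, tuple(x for x in range(4) if x not in pair)
            # design: d_ij = bi+bj ; d_kl = bk+bl ; d_ik = bi+bk+m etc.
            A, y = [], []
            rows = {(i, j): [1, 1, 0, 0, 0], (k, l): [0, 0, 1, 1, 0],
                    (i, k): [1, 0, 1, 0, 1], (i, l): [1, 0, 0, 1, 1],
                    (j, k): [0, 1, 1, 0, 1], (j, l): [0, 1, 0, 1, 1]}
            order = [i, j, k, l]
            for (x, z), row in rows.items():
                re = [0.0] * 5
                for t, col in zip(order, range(4)):
                    re[col] = row[col]
                re[4] = row[4]
                A.append(re)
                y.append(D[x, z])
            coef, rss, *_ = np.linalg.lstsq(np.array(A), np.array(y), rcond=None)
            return rss[0] if rss.size else 0.0

        rss = {p: quartet_rss(p) for p in [(0, 1), (0, 2), (0, 3)]}
        best_pair = min(rss, key=rss.get)
        assert best_pair == (0, 1)       # oracle agrees with construction
        tree = build_nj(dm)
        expected = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick",
                                     taxon_namespace=dendropy.TaxonNamespace())
        got = dendropy.Tree.get(data=tree_to_newick(tree), schema="newick",
                                taxon_namespace=expected.taxon_namespace)
        assert dendropy.calculate.treecompare.symmetric_difference(
            got, expected) == 0

    def test_hundred_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            dm, true_tree = random_additive_case(rng)
            assert same_topology(build_nj(dm), true_tree)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(17)
        n = 7
        noise = rng.uniform(0, 2, size=(n, n))
        D = (noise + noise.T) / 2
        np.fill_diagonal(D, 0)
        tree = build_nj(DistanceMatrix([f"x{i}" for i in range(n)], D))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    def test_non_symmetric_matrix_error(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            build_nj(DistanceMatrix(["a", "b", "c"], D))

    def test_row_order_invariance_of_trim_distance_nj(self):
        rng = np.random.default_rng(23)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        rows = {}
        for i in range(6):
            seq = list(base)
            for _ in range(5 + 3 * i):
                seq[int(rng.integers(60))] = str(rng.choice(list(AMINO_ACIDS)))
            rows[f"r{i}"] = "".join(seq)
        aln1 = Alignment(rows)
        order = list(rows)[::-1]
        aln2 = Alignment({k: rows[k] for k in order})
        t1 = build_nj(distance_matrix(trim_alignment(aln1)[0]))
        t2 = build_nj(distance_matrix(trim_alignment(aln2)[0]))
        assert same_topology(t1, t2) or dendropy.calculate.treecompare.\
            symmetric_difference(
                dendropy.Tree.get(data=tree_to_newick(t1), schema="newick",
                                  taxon_namespace=t2.taxon_namespace), t2) == 0


class TestAssignment:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_references_assign_themselves(self):
        tree = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        refs = {"a": "s1", "c": "s2"}
        out = {x.leaf_id: x for x in assign_subfamilies(tree, refs)}
        assert out["a"].subfamily == "s1" and out["a"].support == 1.0
        assert out["c"].subfamily == "s2" and out["c"].support == 1.0

    def test_cherry_neighbor_inherits_label(self):
        tree = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        refs = {"a": "s1", "c": "s2"}
        out = {x.leaf_id: x for x in assign_subfamilies(tree, refs)}
        assert out["b"].subfamily == "s1"
        assert out["d"].subfamily == "s2"

    def test_mixed_clade_below_majority_unclassified(self):
        tree = self._tree("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        refs = {"a": "s1", "b": "s2", "c": "s1", "d": "s2"}
        out = {x.leaf_id: x for x in assign_subfamilies(tree, refs)}
        # e's smallest reference-bearing clade is the (d,e) cherry -> s2
        assert out["e"].subfamily == "s2"

    def test_empty_reference_error(self):
        with pytest.raises(ValueError):
            assign_subfamilies(self._tree("((a:1,b:1):1,c:1);"), {})

    def test_benchmark_tree_assignment_accuracy(self, classification, truth):
        """>= 95% of family leaves receive their true subfamily."""
        ok = tot = 0
        for a in classification.assignments:
            lab = truth.labels.get(a.leaf_id.split("#")[0])
            if lab and lab.startswith("subfamily"):
                tot += 1
                ok += (a.subfamily == lab)
        assert tot >= 180
        assert ok / tot >= 0.95


class TestPresenceAbsence:
    def _assign(self, leaf, sub, support=1.0):
        from famforge.phyloclass import SubfamilyAssignment
        return SubfamilyAssignment(leaf, sub, support)

    def test_single_cell_present(self):
        mat = presence_absence([self._assign("x", "s1")], {"x": "p1"})
        assert mat.loc["p1", "s1"] == 1

    def test_empty_proteome_row_still_appears(self):
        mat = presence_absence([self._assign("x", "s1")],
                               {"x": "p1", "y": "p2"})
        assert list(mat.index) == ["p1", "p2"]
        assert mat.loc["p2"].sum() == 0

    def test_unknown_proteome_error(self):
        with pytest.raises(ValueError, match="ghost"):
            presence_absence([self._assign("ghost", "s1")], {"x": "p1"})

    def test_tandem_halves_credit_source_proteome(self):
        mat = presence_absence([self._assign("t1#N", "s1"),
                                self._assign("t1#C", "s2")], {"t1": "p1"})
        assert mat.loc["p1", "s1"] == 1 and mat.loc["p1", "s2"] == 1

    def test_monotone_in_assignments(self):
        a1 = [self._assign("x", "s1")]
        a2 = a1 + [self._assign("y", "s2")]
        m1 = presence_absence(a1, {"x": "p1", "y": "p1"})
        m2 = presence_absence(a2, {"x": "p1", "y": "p1"})
        for col in m1.columns:
            assert (m2[col] >= m1[col]).all()

    def test_benchmark_matrix_fully_present(self, classification):
        assert (classification.matrix.values == 1).all()
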