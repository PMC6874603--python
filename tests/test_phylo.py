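"""Jukes-Cantor distances, diploid distances, NJ trees, midpoint, genealogies."""

import itertools
import math
import random

import dendropy
import dendropy.simulate
import numpy as np
import pytest
from dendropy.calculate import treecompare

from pelletpop import (AlignedLocus, DistanceMatrix, SaturationError,
                       build_distance_tree, collapse_to_genealogy,
                       diploid_distance, distance_matrix_diploid, jc69_distance,
                       jc69_from_p, midpoint_root, tree_path_distances)


class TestJc69:
    def test_identical_sequences_zero(self):
        assert jc69_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_value(self):
        assert jc69_from_p(0.1) == pytest.approx(0.107326, abs=1e-6)

    def test_closed_form_grid(self):
        for p in np.linspace(0.0, 0.74, 75):
            expect = -0.75 * math.log(1 - 4 * p / 3)
            assert abs(jc69_from_p(p) - expect) < 1e-12

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc69_from_p(0.75)
        seq_a = "A" * 100
        seq_b = "C" * 75 + "A" * 25
        with pytest.raises(SaturationError):
            jc69_distance(seq_a, seq_b)

    def test_correction_inflates_and_monotone(self):
        grid = np.linspace(0.01, 0.74, 50)
        vals = [jc69_from_p(p) for p in grid]
        assert all(v >= p for v, p in zip(vals, grid))
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestDiploidDistance:
    def test_four_pair_enumeration(self):
        x = "A" * 200
        y = "T" + "A" * 199
        locus = AlignedLocus("l", {"i1": (x, x), "i2": (x, y)})
        d = jc69_from_p(1 / 200)
        # pairs: (x,x)=0, (x,y)=d, (x,x)=0, (x,y)=d -> mean d/2
        assert diploid_distance("i1", "i2", [locus]) == pytest.approx(d / 2)
        assert d / 2 == pytest.approx(0.0025084, abs=1e-6)

    def test_homozygous_identical_zero(self):
        x = "ACGT" * 50
        locus = AlignedLocus("l", {"i1": (x, x), "i2": (x, x)})
        assert diploid_distance("i1", "i2", [locus]) == 0.0

    def test_length_weighted_combination(self):
        x1, y1 = "A" * 200, "T" * 4 + "A" * 196
        x2, y2 = "C" * 100, "G" + "C" * 99
        l1 = AlignedLocus("l1", {"i1": (x1, x1), "i2": (y1, y1)})
        l2 = AlignedLocus("l2", {"i1": (x2, x2), "i2": (y2, y2)})
        v1 = diploid_distance("i1", "i2", [l1])
        v2 = diploid_distance("i1", "i2", [l2])
        combined = diploid_distance("i1", "i2", [l1, l2])
        assert combined == pytest.approx((200 * v1 + 100 * v2) / 300)

    def test_symmetric_and_allele_swap_invariant(self):
        x, y, z = "A" * 100, "T" + "A" * 99, "TT" + "A" * 98
        l1 = AlignedLocus("l", {"i1": (x, y), "i2": (z, x)})
        l2 = AlignedLocus("l", {"i1": (y, x), "i2": (x, z)})
        assert diploid_distance("i1", "i2", [l1]) == \
            pytest.approx(diploid_distance("i2", "i1", [l2]))

    def test_no_shared_loci_fails_loudly(self):
        l1 = AlignedLocus("l1", {"i1": ("ACGT", "ACGT")})
        l2 = AlignedLocus("l2", {"i2": ("ACGT", "ACGT")})
        with pytest.raises(ValueError, match="share no loci"):
            diploid_distance("i1", "i2", [l1, l2])
        with pytest.raises(ValueError, match="share no loci"):
            distance_matrix_diploid(["i1", "i2"], [l1, l2])


def random_additive_matrix(n_taxa, seed):
    """An additive distance matrix from a random binary tree (the oracle)."""
    pyrng = random.Random(seed)
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
        num_extant_tips=n_taxa, rng=pyrng)
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length = rng.uniform(0.05, 0.6)
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tns)
    taxa = {t.label: t for t in tns}
    d = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels=labels, d=d), tree


class TestDistanceTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            d=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = build_distance_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 1), (6, 2), (7, 3), (8, 4)])
    def test_additive_matrix_recovered_exactly(self, n_taxa, seed):
        dm, true_tree = random_additive_matrix(n_taxa, seed)
        rec = build_distance_tree(dm)
        np.testing.assert_allclose(tree_path_distances(rec).d, dm.d, atol=1e-9)
        # topology identical: same unrooted bipartitions
        rec2 = rec.clone(depth=1)
        rec2.migrate_taxon_namespace(true_tree.taxon_namespace)
        true_tree.is_rooted = False
        rec2.is_rooted = False
        true_tree.encode_bipartitions()
        rec2.encode_bipartitions()
        assert treecompare.symmetric_difference(true_tree, rec2) == 0

    def test_matches_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        dm, _ = random_additive_matrix(7, seed=11)
        ours = build_distance_tree(dm)
        sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.labels)
        sk_tree = skbio.tree.nj(sk_dm)
        sk_dendro = dendropy.Tree.get(data=str(sk_tree), schema="newick",
                                      taxon_namespace=ours.taxon_namespace)
        ours = ours.clone(depth=1)
        ours.is_rooted = False
        sk_dendro.is_rooted = False
        ours.encode_bipartitions()
        sk_dendro.encode_bipartitions()
        assert treecompare.symmetric_difference(ours, sk_dendro) == 0

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            build_distance_tree(dm)

    def test_tie_break_deterministic(self):
        # fully symmetric matrix: every Q entry ties; label order must decide
        d = np.full((4, 4), 0.2)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(labels=list("ABCD"), d=d)
        n1 = build_distance_tree(dm).as_string(schema="newick")
        n2 = build_distance_tree(dm).as_string(schema="newick")
        assert n1 == n2


class TestMidpointRoot:
    def test_three_taxon_path_arithmetic(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            d=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = midpoint_root(build_distance_tree(dm))
        # longest path B-C = 0.4; root 0.20 from each, i.e. 0.05 into C's branch
        depths = {}
        for lf in tree.leaf_node_iter():
            depth, nd = 0.0, lf
            while nd.parent_node is not None:
                depth += nd.edge.length
                nd = nd.parent_node
            depths[lf.taxon.label] = depth
        assert depths["B"] == pytest.approx(0.2)
        assert depths["C"] == pytest.approx(0.2)

    def test_matches_dendropy_midpoint(self):
        dm, _ = random_additive_matrix(6, seed=21)
        ours = midpoint_root(build_distance_tree(dm))
        ref = build_distance_tree(dm)
        ref.reroot_at_midpoint(update_bipartitions=True)
        our_d = tree_path_distances(ours)
        ref_d = tree_path_distances(ref)
        np.testing.assert_allclose(our_d.d, ref_d.d, atol=1e-9)
        # same root position: max root-to-leaf depth equal
        def max_depth(tree):
            out = 0.0
            for lf in tree.leaf_node_iter():
                depth, nd = 0.0, lf
                while nd.parent_node is not None:
                    depth += nd.edge.length or 0.0
                    nd = nd.parent_node
                out = max(out, depth)
            return out
        assert max_depth(ours) == pytest.approx(max_depth(ref))

    def test_idempotent(self):
        dm, _ = random_additive_matrix(5, seed=31)
        once = midpoint_root(build_distance_tree(dm))
        twice = midpoint_root(once)
        np.testing.assert_allclose(tree_path_distances(once).d,
                                   tree_path_distances(twice).d, atol=1e-12)

        def depths(tree):
            out = {}
            for lf in tree.leaf_node_iter():
                d, nd = 0.0, lf
                while nd.parent_node is not None:
                    d += nd.edge.length or 0.0
                    nd = nd.parent_node
                out[lf.taxon.label] = d
            return out

        d1, d2 = depths(once), depths(twice)
        assert d1.keys() == d2.keys()
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-12)

    def test_newick_round_trip_stable(self, tmp_path):
        from pelletpop.phylo import read_newick, write_newick
        dm, _ = random_additive_matrix(6, seed=41)
        tree = midpoint_root(build_distance_tree(dm))
        p1 = tmp_path / "t1.nwk"
        p2 = tmp_path / "t2.nwk"
        write_newick(tree, p1)
        write_newick(read_newick(p1), p2)
        assert p1.read_text() == p2.read_text()


class TestHaplotypeGenealogy:
    def test_all_identical_single_node(self):
        locus = AlignedLocus("l", {f"i{k}": ("ACGT", "ACGT") for k in range(5)})
        gen = collapse_to_genealogy(locus, {f"i{k}": "g" for k in range(5)})
        assert len(gen.nodes) == 1
        assert gen.nodes[0].frequency == 10
        assert gen.edges == []

    def test_three_haplotype_path(self):
        # AA x3, AT x2, TT x1 -> path AA-AT-TT with edge weights 1, 1
        locus = AlignedLocus("l", {
            "i1": ("AA", "AA"), "i2": ("AA", "AT"), "i3": ("AT", "TT"),
        })
        gen = collapse_to_genealogy(locus, {k: "g" for k in ("i1", "i2", "i3")})
        seq_of = {n.hap_id: n.sequence for n in gen.nodes}
        freq_of = {n.sequence: n.frequency for n in gen.nodes}
        assert freq_of == {"AA": 3, "AT": 2, "TT": 1}
        edge_seqs = sorted(tuple(sorted((seq_of[a], seq_of[b]))) + (w,)
                           for a, b, w in gen.edges)
        assert edge_seqs == [("AA", "AT", 1), ("AT", "TT", 1)]

    def test_frequency_conservation_and_connected(self):
        rng = np.random.default_rng(7)
        from pelletpop import simulate_coalescent_locus
        seqs = simulate_coalescent_locus(rng, [12], 4.0, 120)
        locus = AlignedLocus("l", {f"i{k}": (seqs[2 * k], seqs[2 * k + 1])
                                   for k in range(6)})
        gen = collapse_to_genealogy(locus, {f"i{k}": "g" for k in range(6)})
        assert gen.total_alleles == 12
        assert gen.is_connected()

    def test_group_composition(self):
        locus = AlignedLocus("l", {"a1": ("AA", "AA"), "b1": ("AA", "AT")})
        gen = collapse_to_genealogy(locus, {"a1": "north", "b1": "south"})
        node_aa = next(n for n in gen.nodes if n.sequence == "AA")
        assert node_aa.group_counts == {"north": 2, "south": 1}
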