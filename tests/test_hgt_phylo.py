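import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from microevo import gc_islands as gi
from microevo import hgt_phylo as hp
from microevo import synthetic_clade as sc
from oracles import rf_bruteforce


def _tree(newick, taxa=None):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, taxon_namespace=taxa
    )


class TestCenterStar:
    def test_identical_sequences_align_without_gaps(self):
        msa = hp.center_star_msa({"a": "MKLV", "b": "MKLV", "c": "MKLV"})
        assert set(msa.values()) == {"MKLV"}

    def test_planted_insertion_is_gapped_in_other_rows(self):
        seqs = {
            "a": "MKLVHEAGAW",
            "b": "MKLVHEAGAW",
            "c": "MKLVGGHEAGAW",  # 2-residue insertion after MKLV
        }
        msa = hp.center_star_msa(seqs)
        width = len(msa["c"])
        assert width == 12
        assert msa["a"].count("-") == 2 and msa["b"].count("-") == 2
        assert msa["c"].count("-") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_width_at_least_longest_input(self, seed):
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {
            f"s{i}": "".join(rng.choice(aa, size=rng.integers(20, 40))) for i in range(4)
        }
        msa = hp.center_star_msa(seqs)
        widths = {len(r) for r in msa.values()}
        assert len(widths) == 1
        assert widths.pop() >= max(len(s) for s in seqs.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hp.center_star_msa({})


class TestDistances:
    def test_identical_rows_are_zero_under_all_models(self):
        msa = {"a": "MKLV", "b": "MKLV"}
        for model in ("p", "poisson", "jc_nt"):
            _, D = hp.distance_matrix(msa, model)
            assert D[0, 1] == 0.0

    def test_poisson_closed_form(self):
        msa = {"a": "A" * 10, "b": "A" * 9 + "C"}
        _, D = hp.distance_matrix(msa, "poisson")
        assert D[0, 1] == pytest.approx(0.10536051565782628)

    def test_jc_saturation_is_infinite(self):
        msa = {"a": "AAAA", "b": "CCCA"}  # p = 0.75
        _, D = hp.distance_matrix(msa, "jc_nt")
        assert D[0, 1] == float("inf")

    def test_gap_only_overlap_rejected(self):
        with pytest.raises(ValueError, match="a.*b|comparable"):
            hp.distance_matrix({"a": "M-", "b": "-M"})


class TestNeighborJoining:
    def test_additive_four_taxon_distances_recovered_exactly(self):
        # tree ((a:1,b:2):1,(c:3,d:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = hp.nj_tree(["a", "b", "c", "d"], D)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        assert hp.rf_distance(tree, _tree("((a:1,b:2):1,c:3,d:4);")) == (0, 0.0)

    def test_three_taxon_star_lengths(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = hp.nj_tree(["a", "b", "c"], D)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    @pytest.mark.parametrize("n_taxa", [5, 8, 10])
    def test_random_additive_matrices_recover_topology(self, n_taxa):
        rnd = random.Random(n_taxa)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
        true = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
            taxon_namespace=taxa, rng=rnd,
        )
        for e in true.preorder_edge_iter():
            if e.length is not None:
                e.length = max(e.length, 0.05)
        pdm = true.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in taxa)
        D = np.array(
            [
                [
                    0.0 if a == b else pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                    for b in labels
                ]
                for a in labels
            ]
        )
        mine = hp.nj_tree(labels, D)
        assert hp.rf_distance(mine, true) == (0, 0.0)

    def test_infinite_entries_rejected(self):
        D = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="prune"):
            hp.nj_tree(["a", "b", "c"], D)


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = _tree("((a,b),(c,d),e);")
        assert hp.rf_distance(t, t) == (0, 0.0)

    def test_four_taxon_alternatives_are_maximally_distant(self):
        taxa = dendropy.TaxonNamespace()
        t1 = _tree("((a,b),c,d);", taxa)
        t2 = _tree("((a,c),b,d);", taxa)
        assert hp.rf_distance(t1, t2) == (2, 1.0)

    def test_caterpillar_vs_balanced_matches_bruteforce(self):
        taxa = dendropy.TaxonNamespace()
        cat = _tree("(a,(b,(c,(d,(e,f)))));", taxa)
        bal = _tree("(((a,b),c),((d,e),f));", taxa)
        raw, norm = hp.rf_distance(cat, bal)
        assert raw == rf_bruteforce(cat, bal)
        assert norm == raw / (2 * (6 - 3))

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_properties_on_random_trees(self, seed):
        rnd = random.Random(seed)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
        trees = [
            dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=6,
                taxon_namespace=taxa, rng=rnd,
            )
            for _ in range(3)
        ]
        for t in trees:
            t.is_rooted = False
            t.update_bipartitions()
        a, b, c = trees
        assert hp.rf_distance(a, a)[0] == 0
        assert hp.rf_distance(a, b)[0] == hp.rf_distance(b, a)[0]
        assert (
            hp.rf_distance(a, c)[0]
            <= hp.rf_distance(a, b)[0] + hp.rf_distance(b, c)[0]
        )
        # cross-check against the library implementation
        assert hp.rf_distance(a, b)[0] == treecompare.symmetric_difference(a, b)

    def test_leaf_set_mismatch_lists_difference(self):
        t1 = _tree("((a,b),c,d);")
        t2 = _tree("((a,b),c,e);")
        with pytest.raises(ValueError, match="d.*e|e.*d"):
            hp.rf_distance(t1, t2)


class TestBootstrap:
    @staticmethod
    def _clean_msa():
        # two clades separated by many concordant columns
        return {
            "a": "A" * 40 + "C" * 40,
            "b": "A" * 40 + "C" * 40,
            "c": "C" * 40 + "A" * 40,
            "d": "C" * 40 + "A" * 40,
            "e": "C" * 40 + "C" * 40,
        }

    def test_concordant_alignment_gives_full_support(self, rng):
        tree = hp.bootstrap_support(self._clean_msa(), n=50, rng=rng, model="p")
        supports = [
            int(node.label)
            for node in tree.preorder_internal_node_iter()
            if node.label is not None
        ]
        assert supports and all(s == 100 for s in supports)

    def test_supports_are_percent_integers(self, rng):
        seqs = sc.simulate_gene_family(sc.HGT_TEST_SPECIES_TREE, 100, rng)
        tree = hp.bootstrap_support(hp.center_star_msa(seqs), n=20, rng=rng)
        for node in tree.preorder_internal_node_iter():
            if node.label is not None:
                assert 0 <= int(node.label) <= 100

    def test_deep_split_outscores_shallow_split(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            # deep split supported by 60 columns; shallow split by 1
            msa = {
                "a": "A" * 60 + "A",
                "b": "A" * 60 + "C",
                "c": "C" * 60 + "A",
                "d": "C" * 60 + "A",
                "e": "G" * 60 + "A",
            }
            tree = hp.bootstrap_support(msa, n=50, rng=rng, model="p")
            sup = {
                frozenset(lf.taxon.label for lf in node.leaf_iter()): int(node.label)
                for node in tree.preorder_internal_node_iter()
                if node.label is not None
            }
            deep = max(
                (v for k, v in sup.items() if k in ({"a", "b"}, {"c", "d", "e"})),
                default=0,
            )
            shallow = min(v for v in sup.values())
            if deep >= shallow:
                wins += 1
        assert wins >= 4

    def test_invalid_replicate_count_rejected(self, rng):
        with pytest.raises(ValueError):
            hp.bootstrap_support(self._clean_msa(), n=0, rng=rng)


class TestFlagHgt:
    @staticmethod
    def _island(with_markers=True, delta=-6.3):
        island = gi.IslandCall("c1", 0, 25_000, 38.0 + delta, 38.0, -6.0)
        if with_markers:
            island.mge_markers = [("g1", "transposase")]
        return island

    @staticmethod
    def _trees(rng, transfer=True):
        seqs = sc.simulate_gene_family(
            sc.HGT_TEST_SPECIES_TREE,
            200,
            rng,
            transfer=("m2_6", "donorA", 0.02) if transfer else None,
        )
        gene_tree = hp.bootstrap_support(hp.center_star_msa(seqs), n=100, rng=rng)
        species_tree = _tree(sc.HGT_TEST_SPECIES_TREE)
        return gene_tree, species_tree

    def test_congruent_gene_tree_gives_no_phylo_signal(self, rng):
        species_tree = _tree(sc.HGT_TEST_SPECIES_TREE)
        gene_tree = _tree(sc.HGT_TEST_SPECIES_TREE)
        for node in gene_tree.preorder_internal_node_iter():
            node.label = "100"
        ev = hp.flag_hgt("locus", None, gene_tree, species_tree, "m2_6")
        assert not ev.phylo_signal and ev.verdict == "none"

    def test_transferred_family_fires_phylo_signal(self):
        fired = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            gene_tree, species_tree = self._trees(rng, transfer=True)
            ev = hp.flag_hgt("locus", None, gene_tree, species_tree, "m2_6")
            fired += ev.phylo_signal
        assert fired >= 9

    def test_full_evidence_yields_supported_verdict(self, rng):
        gene_tree, species_tree = self._trees(rng, transfer=True)
        ev = hp.flag_hgt("GIm2d", self._island(), gene_tree, species_tree, "m2_6")
        assert ev.n_signals == 3 and ev.verdict == "supported"

    def test_verdict_is_monotone_in_signals(self, rng):
        gene_tree, species_tree = self._trees(rng, transfer=True)
        rank = {"none": 0, "partial": 1, "supported": 2}
        islands = [None, self._island(with_markers=False, delta=-6.3), self._island()]
        verdicts = [
            hp.flag_hgt("x", isl, gene_tree, species_tree, "m2_6").verdict
            for isl in islands
        ]
        assert rank[verdicts[0]] <= rank[verdicts[1]] <= rank[verdicts[2]]

    def test_missing_focal_rejected(self, rng):
        gene_tree, species_tree = self._trees(rng)
        with pytest.raises(ValueError, match="absent"):
            hp.flag_hgt("x", None, gene_tree, species_tree, "not_a_taxon")
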