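import numpy as np
import pytest
from Bio.Align import substitution_matrices

from microevo import orthology as orth
from microevo import synthetic_clade as sc
from microevo.io_formats import Genome, proteome
from oracles import adjacency_fraction_bruteforce, sw_affine_bruteforce

BL62 = substitution_matrices.load("BLOSUM62")
BL50 = substitution_matrices.load("BLOSUM50")


def _sub(matrix):
    return lambda x, y: matrix[x][y]


class TestLocalAlign:
    def test_identical_sequences(self):
        h = orth.local_align("M" + "ACDEFGHIKL" * 10, "M" + "ACDEFGHIKL" * 10)
        assert h.identity == 1.0 and h.qcov == 1.0 and h.scov == 1.0

    def test_textbook_example_matches_bruteforce(self):
        # linear gap penalty of 8 per gapped residue, BLOSUM50
        params = orth.ScoringParams(matrix="BLOSUM50", gap_open=0, gap_extend=8)
        h = orth.local_align("HEAGAWGHEE", "PAWHEAE", params)
        assert h.raw_score == sw_affine_bruteforce("HEAGAWGHEE", "PAWHEAE", _sub(BL50), 0, 8)
        assert h.raw_score == 28.0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_short_pairs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aa), size=rng.integers(3, 13)))
        b = "".join(rng.choice(list(aa), size=rng.integers(3, 13)))
        params = orth.ScoringParams()
        h = orth.local_align(a, b, params)
        expected = sw_affine_bruteforce(a, b, _sub(BL62), params.gap_open, params.gap_extend)
        assert h.raw_score == expected

    def test_unrelated_sequences_fail_evalue_cut(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        above = 0
        for _ in range(100):
            a = "".join(rng.choice(aa, size=50))
            b = "".join(rng.choice(aa, size=50))
            if orth.local_align(a, b, m=5000, n=5000).evalue > 1e-6:
                above += 1
        assert above == 100

    def test_non_protein_input_rejected(self):
        with pytest.raises(ValueError, match="non-protein"):
            orth.local_align("ACGT123", "ACDE")


class TestBestHits:
    def test_exact_copies_beat_decoys(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        A = {f"a{i}": "".join(rng.choice(aa, size=80)) for i in range(5)}
        B = {f"b{i}": A[f"a{i}"] for i in range(5)}
        B.update({f"decoy{i}": "".join(rng.choice(aa, size=80)) for i in range(5)})
        hits = orth.best_hits(A, B)
        assert {q: h.subject_id for q, h in hits.items()} == {
            f"a{i}": f"b{i}" for i in range(5)
        }

    def test_tie_breaks_to_smaller_subject_id(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(aa, size=80))
        A = {"q": seq}
        B = {"z_copy": seq, "a_copy": seq}
        hits = orth.best_hits(A, B)
        assert hits["q"].subject_id == "a_copy"


class TestBBH:
    def test_identical_proteomes_pair_completely(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        A = {f"g{i}": "".join(rng.choice(aa, size=100)) for i in range(8)}
        B = {f"h{i}": A[f"g{i}"] for i in range(8)}
        pairs = orth.bidirectional_best_hits(A, B)
        assert len(pairs) == len(A)

    def test_low_coverage_direction_excluded(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        full = "".join(rng.choice(aa, size=100))
        A = {"q": full}
        B = {"s": full[:55]}  # qcov 0.55 in the A->B direction
        assert orth.bidirectional_best_hits(A, B, min_cov=0.60) == []
        assert len(orth.bidirectional_best_hits(A, B, min_cov=0.50)) == 1

    def test_symmetry_as_unordered_pairs(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        A = {f"g{i}": "".join(rng.choice(aa, size=90)) for i in range(6)}
        B = {f"h{i}": A[f"g{i}"] for i in range(6)}
        ab = {
            frozenset((p[0].query_id, p[0].subject_id))
            for p in orth.bidirectional_best_hits(A, B)
        }
        ba = {
            frozenset((p[0].query_id, p[0].subject_id))
            for p in orth.bidirectional_best_hits(B, A)
        }
        assert ab == ba

    def test_threshold_monotonicity(self, rng):
        clade = sc.generate_clade(
            sc.CladeConfig(
                strain_ids=("a", "b"),
                n_core=25,
                branch_sub_rate={"a": 0.01, "b": 0.01},
                seed=2,
            )
        )
        A, B = (proteome(clade.genomes[s]) for s in ("a", "b"))
        loose = len(orth.bidirectional_best_hits(A, B, min_cov=0.5, max_eval=1e-3))
        tight_cov = len(orth.bidirectional_best_hits(A, B, min_cov=0.9, max_eval=1e-3))
        tight_eval = len(orth.bidirectional_best_hits(A, B, min_cov=0.5, max_eval=1e-30))
        assert tight_cov <= loose and tight_eval <= loose

    def test_invalid_min_cov_rejected(self):
        with pytest.raises(ValueError):
            orth.bidirectional_best_hits({"a": "MKL"}, {"b": "MKL"}, min_cov=1.5)


def _hit(q, s, bits=100.0):
    return (
        orth.AlignmentHit(q, s, 0, bits, 0.0, 1.0, 1.0, 1.0),
        orth.AlignmentHit(s, q, 0, bits, 0.0, 1.0, 1.0, 1.0),
    )


class TestFamilies:
    def test_triangle_is_one_core_family(self):
        proteomes = {s: {f"{s}1": "MKL"} for s in ("a", "b", "c")}
        bbh = {
            frozenset(("a", "b")): [_hit("a1", "b1")],
            frozenset(("a", "c")): [_hit("a1", "c1")],
            frozenset(("b", "c")): [_hit("b1", "c1")],
        }
        fams = orth.build_families(proteomes, bbh)
        assert len(fams) == 1 and fams[0].category == "core"

    def test_chain_without_closing_edge_is_still_core(self):
        proteomes = {s: {f"{s}1": "MKL"} for s in ("a", "b", "c")}
        bbh = {
            frozenset(("a", "b")): [_hit("a1", "b1")],
            frozenset(("b", "c")): [_hit("b1", "c1")],
            frozenset(("a", "c")): [],
        }
        fams = orth.build_families(proteomes, bbh)
        assert len(fams) == 1 and fams[0].category == "core"

    def test_paralogs_resolved_by_summed_bitscore(self):
        proteomes = {"a": {"a1": "MKL", "a2": "MKL"}, "b": {"b1": "MKL"}}
        bbh = {
            frozenset(("a", "b")): [_hit("a1", "b1", bits=50.0), _hit("a2", "b1", bits=80.0)]
        }
        fams = orth.build_families(proteomes, bbh)
        cats = sorted((f.category, sorted(f.members.values())) for f in fams)
        # a2 wins the per-strain paralog resolution; a1 is re-seated alone
        assert cats == [("core", ["a2", "b1"]), ("specific", ["a1"])]

    def test_every_gene_in_exactly_one_family(self, default_clade):
        partition, _ = orth.pangenome(default_clade.genomes)
        placed = [
            (s, g) for fam in partition.families for s, g in fam.members.items()
        ]
        total_genes = sum(len(g.features) for g in default_clade.genomes.values())
        assert len(placed) == len(set(placed)) == total_genes


class TestPangenomeCounts:
    def test_published_counts_give_82_percent_core(self):
        assert orth.core_fraction_percent(2893, [3556, 3500, 3530]) == 82
        assert 100 - orth.core_fraction_percent(2893, [3556, 3500, 3530]) == 18

    def test_partition_arithmetic_from_printed_totals(self):
        # pangenome 4,416 with core 2,893 leaves 1,523 accessory families
        assert 4416 - 2893 == 1523

    def test_empty_families_rejected(self):
        with pytest.raises(ValueError):
            orth.pangenome_counts([], {"a": 10})


class TestSynteny:
    @staticmethod
    def _linear_genome(strain, gene_order):
        from microevo.io_formats import GeneFeature, SequenceRecord

        feats = [
            GeneFeature(f"{strain}_{fam}", f"{strain}_c1", 100 * i, 100 * i + 90, "+")
            for i, fam in enumerate(gene_order)
        ]
        seq = "A" * (100 * len(gene_order))
        return Genome(strain, [SequenceRecord(f"{strain}_c1", seq)], feats)

    @staticmethod
    def _families(order_a, order_b):
        fams = []
        for fam in order_a:
            fams.append(
                orth.OrthologFamily(fam, {"A": f"A_{fam}", "B": f"B_{fam}"}, "core")
            )
        return fams

    def test_identical_order_scores_one(self):
        order = [f"f{i}" for i in range(10)]
        gA = self._linear_genome("A", order)
        gB = self._linear_genome("B", order)
        assert orth.synteny_conservation(gA, gB, self._families(order, order)) == 1.0

    def test_single_relocation_matches_bruteforce(self):
        order_a = [f"f{i}" for i in range(10)]
        order_b = order_a[:3] + order_a[4:] + [order_a[3]]  # relocate one gene
        gA = self._linear_genome("A", order_a)
        gB = self._linear_genome("B", order_b)
        got = orth.synteny_conservation(gA, gB, self._families(order_a, order_b))
        assert got == pytest.approx(adjacency_fraction_bruteforce(order_a, order_b))

    def test_clade_without_rearrangement_is_highly_syntenic(self, default_clade):
        partition, _ = orth.pangenome(default_clade.genomes)
        g = default_clade.genomes
        value = orth.synteny_conservation(g["m4_4"], g["p1_1_43"], partition.families)
        assert value >= 0.95

    def test_undefined_without_core_adjacencies(self):
        gA = self._linear_genome("A", ["f0"])
        gB = self._linear_genome("B", ["f0"])
        with pytest.raises(ValueError, match="undefined"):
            orth.synteny_conservation(gA, gB, self._families(["f0"], ["f0"]))
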