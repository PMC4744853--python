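import numpy as np
import pytest

from microevo import synthetic_clade as sc
from microevo.io_formats import gc_percent, proteome, translate_cds


def small_config(seed=0, **overrides):
    cfg = dict(
        strain_ids=("a", "b", "c"),
        n_core=30,
        shared_pattern_counts={frozenset(("a", "b")): 4},
        n_specific={"a": 2, "b": 1, "c": 3},
        branch_sub_rate={"a": 0.005, "b": 0.004, "c": 0.008},
        seed=seed,
    )
    cfg.update(overrides)
    return sc.CladeConfig(**cfg)


class TestSequenceSampling:
    def test_orfs_are_translatable_without_internal_stops(self, rng):
        for length in (90, 300, 901 - 1):
            seq = sc.random_orf(900, 0.315, rng)
            assert seq.startswith("ATG")
            assert seq[-3:] in sc.STOP_CODONS
            translate_cds(seq)  # raises on internal stop

    def test_orf_gc_matches_target(self, rng):
        seqs = [sc.random_orf(3000, 0.38, rng) for _ in range(30)]
        realized = gc_percent("".join(seqs))
        assert realized == pytest.approx(38.0, abs=1.0)

    def test_exact_composition_sampler(self, rng):
        seq = sc.random_dna_exact(10_000, 0.315, rng)
        assert gc_percent(seq) == pytest.approx(31.5, abs=0.01)

    def test_infeasible_gc_raises(self, rng):
        with pytest.raises(sc.ConfigError):
            sc._codon_base_gc(0.999)


class TestAncestor:
    def test_generated_gc_within_one_point(self, rng):
        cfg = small_config(n_core=100)
        genome, _ = sc.generate_ancestor(cfg, rng)
        assert gc_percent(genome.contigs[0].seq) == pytest.approx(38.0, abs=1.0)

    def test_all_genes_are_orfs(self, rng):
        genome, _ = sc.generate_ancestor(small_config(), rng)
        for f in genome.features:
            translate_cds(genome.feature_seq(f))

    def test_determinism(self):
        g1, _ = sc.generate_ancestor(small_config(), np.random.default_rng(7))
        g2, _ = sc.generate_ancestor(small_config(), np.random.default_rng(7))
        assert g1.contigs[0].seq == g2.contigs[0].seq


class TestEvolve:
    def test_rate_zero_is_identity(self, rng):
        anc, _ = sc.generate_ancestor(small_config(), rng)
        desc = sc.evolve_genome(anc, 0.0, set(), [], np.random.default_rng(1), "d")
        assert desc.contigs[0].seq == anc.contigs[0].seq
        assert len(desc.features) == len(anc.features)

    def test_realized_identity_tracks_rate(self, rng):
        cfg = small_config(n_core=400, gene_len_mean=300)  # >= 100 kb
        anc, _ = sc.generate_ancestor(cfg, rng)
        desc = sc.evolve_genome(anc, 0.01, set(), [], np.random.default_rng(2), "d")
        a, d = anc.contigs[0].seq, desc.contigs[0].seq
        assert len(a) == len(d) and len(a) >= 100_000
        ident = np.mean([x == y for x, y in zip(a, d)])
        assert ident == pytest.approx(0.99, abs=0.002)

    def test_loss_removes_family(self, rng):
        anc, order = sc.generate_ancestor(small_config(), rng)
        lost = order[0]
        desc = sc.evolve_genome(anc, 0.0, {lost}, [], np.random.default_rng(3), "d")
        assert all(not f.gene_id.endswith(lost) for f in desc.features)
        assert len(desc.features) == len(anc.features) - 1

    def test_unknown_loss_rejected(self, rng):
        anc, _ = sc.generate_ancestor(small_config(), rng)
        with pytest.raises(sc.ConfigError, match="unknown"):
            sc.evolve_genome(anc, 0.0, {"nope"}, [], np.random.default_rng(0), "d")

    def test_excessive_rate_rejected(self, rng):
        anc, _ = sc.generate_ancestor(small_config(), rng)
        with pytest.raises(sc.ConfigError):
            sc.evolve_genome(anc, 0.3, set(), [], np.random.default_rng(0), "d")


class TestIsland:
    def test_island_gc_and_repeats(self, rng):
        cfg = small_config(n_core=200)
        anc, _ = sc.generate_ancestor(cfg, rng)
        anc.strain_id = "a"
        spec = sc.IslandSpec(recipient="a", length_bp=12_000, gc=0.315, flank_repeat_len=20)
        g, truth = sc.plant_island(anc, spec, rng)
        island_seq = g.contig_map()[truth["contig_id"]].seq[truth["start"] : truth["end"]]
        assert gc_percent(island_seq) == pytest.approx(31.5, abs=1.0)
        assert island_seq[:20] == island_seq[-20:]  # planted direct repeats
        assert len(island_seq) == spec.length_bp

    def test_marker_products_carry_lexicon_keywords(self, rng):
        anc, _ = sc.generate_ancestor(small_config(n_core=200), rng)
        g, truth = sc.plant_island(anc, sc.IslandSpec(recipient="a", length_bp=12_000), rng)
        products = {f.gene_id: f.product for f in g.features}
        for gid in truth["marker_gene_ids"]:
            assert any(kw.lower() in products[gid].lower() for kw in sc.MGE_KEYWORDS)

    def test_oversized_island_rejected(self, rng):
        anc, _ = sc.generate_ancestor(small_config(n_core=10), rng)
        with pytest.raises(sc.ConfigError):
            sc.plant_island(anc, sc.IslandSpec(recipient="a", length_bp=10**6), rng)


class TestClade:
    def test_category_counts_match_configuration(self, default_clade):
        counts = default_clade.manifest.category_counts()
        assert counts["core"] == 290
        assert counts["shared"] == 30
        # 12 + 11 + 9 planted specific genes plus the island's marker and
        # cargo genes, which are strain-specific by construction
        island = default_clade.manifest.islands[0]
        n_island_specific = len(island["marker_gene_ids"]) + len(island["cargo_families"])
        assert counts["specific"] == 32 + n_island_specific

    def test_manifest_and_files_are_consistent(self, default_clade):
        seen = {}
        for strain, genome in default_clade.genomes.items():
            for f in genome.features:
                fam = f.gene_id.removeprefix(f"{strain}_")
                assert fam in default_clade.manifest.families
                assert default_clade.manifest.families[fam]["members"][strain] == f.gene_id
                seen.setdefault(fam, set()).add(strain)
        for fam, strains in seen.items():
            assert set(default_clade.manifest.families[fam]["members"]) == strains

    def test_island_coordinates_contain_planted_markers(self, default_clade):
        island = default_clade.manifest.islands[0]
        g = default_clade.genomes[island["recipient"]]
        for f in g.features:
            if f.gene_id in island["marker_gene_ids"]:
                assert island["start"] <= f.start and f.end <= island["end"]

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        cfg = small_config(seed=11)
        sc.generate_clade(cfg, tmp_path / "x")
        sc.generate_clade(small_config(seed=11), tmp_path / "y")
        for name in ("a.fna", "a.gff", "a.faa", "manifest.json"):
            assert (tmp_path / "x" / name).read_bytes() == (tmp_path / "y" / name).read_bytes()

    def test_written_clade_round_trips(self, tmp_path, rng):
        from microevo.io_formats import read_genome

        cfg = small_config(seed=4)
        clade = sc.generate_clade(cfg, tmp_path)
        back = read_genome(tmp_path, "b")
        orig = clade.genomes["b"]
        assert back.contigs == orig.contigs
        assert [f.gene_id for f in back.features] == [f.gene_id for f in orig.features]
        assert proteome(back) == proteome(orig)


class TestCalibration:
    def test_star_rates_invert_the_identity_formula(self):
        rates = sc.star_rates_from_identities(sc.PAIR_IDENTITY_TARGETS)
        for pair, target in sc.PAIR_IDENTITY_TARGETS.items():
            a, b = sorted(pair)
            assert sc.expected_pair_identity(rates[a], rates[b]) == pytest.approx(
                target, abs=1e-12
            )

    def test_unachievable_identities_rejected(self):
        bad = {k: 0.2 for k in sc.PAIR_IDENTITY_TARGETS}
        with pytest.raises(sc.ConfigError):
            sc.star_rates_from_identities(bad)


class TestGeneFamilySimulation:
    def test_transfer_moves_recipient_next_to_donor(self, rng):
        seqs = sc.simulate_gene_family(
            sc.HGT_TEST_SPECIES_TREE, 200, rng, transfer=("m2_6", "donorA", 0.02)
        )
        def ident(x, y):
            return np.mean([a == b for a, b in zip(seqs[x], seqs[y])])

        assert ident("m2_6", "donorA") > ident("m2_6", "m4_4")

    def test_vertical_family_tracks_species_tree(self, rng):
        seqs = sc.simulate_gene_family(sc.HGT_TEST_SPECIES_TREE, 200, rng)
        def ident(x, y):
            return np.mean([a == b for a, b in zip(seqs[x], seqs[y])])

        assert ident("m2_6", "m4_4") > ident("m2_6", "donorA")
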