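"""End-to-end orchestration: simulate or ingest, then run every analysis.

One root seed feeds named substreams (one per stage), so a run is
byte-reproducible: identical seed and configuration give identical report
files.  Reports are plain TSV/BED/JSON under the output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani as ani_mod
from . import gc_islands, hgt_phylo, orthology, profile_search, synthetic_clade
from .io_formats import Genome, proteome, read_genome
from .trait_concordance import concordance, load_packaged_table, summarize_auxotrophies

STAGES = ("simulate", "pangenome", "ani", "islands", "hgt", "scan", "traits")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    input_dir: str | None = None  # read strains instead of simulating
    clade: synthetic_clade.CladeConfig | None = None
    min_cov: float = 0.60
    max_eval: float = 1e-6
    frag_len: int = 1020
    window: int = 5000
    step: int = 500
    z_cut: float = -3.0
    min_island_len: int = 8000
    support_min: float = 70.0
    evalue_cut: float = 1e-6
    bootstrap_n: int = 100


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_families_tsv(partition, path):
    rows = []
    for fam in partition.families:
        for strain, gid in sorted(fam.members.items()):
            rows.append((fam.family_id, strain, gid, fam.category))
    pd.DataFrame(rows, columns=["family_id", "strain", "gene_id", "category"]).to_csv(
        path, sep="\t", index=False
    )


def _write_counts_tsv(partition, path):
    rows = [
        ("pangenome", partition.n_pangenome),
        ("core", partition.n_core),
        ("shared", partition.n_shared),
    ]
    for strain, n in sorted(partition.per_strain_specific.items()):
        rows.append((f"specific_{strain}", n))
    rows.append(("core_fraction_of_mean_cds_percent", partition.core_fraction_of_mean_cds))
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(path, sep="\t", index=False)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a dict of output paths and key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(cfg.seed)
    results: dict = {}

    # --- simulate or ingest -------------------------------------------------
    stage = "simulate"
    try:
        if cfg.input_dir is not None:
            in_dir = Path(cfg.input_dir)
            stems = sorted(p.stem for p in in_dir.glob("*.fna"))
            genomes = {s: read_genome(in_dir, s) for s in stems}
            clade = None
        else:
            clade_cfg = cfg.clade or synthetic_clade.default_config(seed=cfg.seed)
            clade = synthetic_clade.generate_clade(clade_cfg, out / "genomes")
            genomes = clade.genomes
        results["genomes"] = sorted(genomes)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e

    # --- pangenome ----------------------------------------------------------
    stage = "pangenome"
    try:
        partition, bbh = orthology.pangenome(genomes, cfg.min_cov, cfg.max_eval)
        _write_families_tsv(partition, out / "pangenome_families.tsv")
        _write_counts_tsv(partition, out / "pangenome_counts.tsv")
        results["partition"] = partition
        results["bbh"] = bbh
    except Exception as e:
        raise StageError(stage, e) from e

    # --- ANI ----------------------------------------------------------------
    stage = "ani"
    try:
        matrix = ani_mod.ani_matrix(genomes, frag_len=cfg.frag_len)
        matrix.round(2).to_csv(out / "ani_matrix.tsv", sep="\t")
        results["ani"] = matrix
    except Exception as e:
        raise StageError(stage, e) from e

    # --- islands ------------------------------------------------------------
    stage = "islands"
    try:
        calls = {}
        bed_rows, tsv_rows = [], []
        for strain, g in sorted(genomes.items()):
            strain_calls = gc_islands.scan_and_call(
                g, cfg.window, cfg.step, cfg.z_cut, cfg.min_island_len
            )
            calls[strain] = strain_calls
            for i, c in enumerate(strain_calls):
                name = f"{strain}_GI{i + 1}"
                bed_rows.append((c.contig_id, c.start, c.end, name))
                tsv_rows.append(
                    (
                        name,
                        c.contig_id,
                        c.start,
                        c.end,
                        round(c.mean_gc, 2),
                        round(c.genome_gc, 2),
                        round(c.z_min, 2),
                        len(c.mge_markers),
                        len(c.flank_repeats),
                    )
                )
        pd.DataFrame(bed_rows).to_csv(out / "islands.bed", sep="\t", index=False, header=False)
        pd.DataFrame(
            tsv_rows,
            columns=[
                "island", "contig", "start", "end", "mean_gc", "genome_gc",
                "z_min", "n_mge_markers", "n_flank_repeats",
            ],
        ).to_csv(out / "islands.tsv", sep="\t", index=False)
        results["islands"] = calls
    except Exception as e:
        raise StageError(stage, e) from e

    # --- HGT ----------------------------------------------------------------
    stage = "hgt"
    try:
        evidence = []
        rng = rngs["hgt"]
        for strain, strain_calls in sorted(calls.items()):
            for i, island in enumerate(strain_calls):
                seqs = synthetic_clade.simulate_gene_family(
                    synthetic_clade.HGT_TEST_SPECIES_TREE,
                    length=200,
                    rng=rng,
                    transfer=(strain, "donorA", 0.02) if strain in ("m4_4", "m2_6", "p1_1_43") else None,
                )
                msa = hgt_phylo.center_star_msa(seqs, "protein")
                gene_tree = hgt_phylo.bootstrap_support(
                    msa, n=cfg.bootstrap_n, rng=rng, model="poisson"
                )
                species_tree = hgt_phylo.dendropy.Tree.get(
                    data=synthetic_clade.HGT_TEST_SPECIES_TREE,
                    schema="newick",
                    preserve_underscores=True,
                )
                ev = hgt_phylo.flag_hgt(
                    f"{strain}_GI{i + 1}", island, gene_tree, species_tree, strain,
                    cfg.support_min,
                )
                evidence.append(ev)
        pd.DataFrame(
            [
                (
                    e.locus_id, e.gc_signal, round(e.delta_gc, 2), e.context_signal,
                    e.n_markers, e.n_flank_repeats, e.phylo_signal,
                    ";".join(e.gene_sister), e.n_signals, e.verdict,
                )
                for e in evidence
            ],
            columns=[
                "locus", "gc_signal", "delta_gc", "context_signal", "n_markers",
                "n_flank_repeats", "phylo_signal", "gene_sister", "n_signals", "verdict",
            ],
        ).to_csv(out / "hgt_evidence.tsv", sep="\t", index=False)
        results["hgt"] = evidence
    except Exception as e:
        raise StageError(stage, e) from e

    # --- marker repertoire ---------------------------------------------------
    stage = "scan"
    try:
        rng = rngs["scan"]
        proteomes = {s: proteome(g) for s, g in genomes.items()}
        profiles = []
        if clade is not None:
            # seed profiles from planted families: island cargo + one core family
            targets = list(dict.fromkeys(clade.manifest.transferred_families))
            core_fams = sorted(
                f for f, e in clade.manifest.families.items() if e["category"] == "core"
            )
            targets += core_fams[:1]
            for fam in targets:
                members = clade.manifest.families.get(fam, {}).get("members", {})
                if not members:
                    continue
                strain, gid = sorted(members.items())[0]
                seed = synthetic_clade.seed_alignment_for_family(
                    proteomes[strain][gid], rng
                )
                profiles.append(profile_search.build_profile(seed, family=fam))
        if profiles:
            table = profile_search.repertoire(
                proteomes, profiles, rng, evalue_cut=cfg.evalue_cut
            )
            table.to_csv(out / "repertoire.tsv", sep="\t")
            results["repertoire"] = table
    except Exception as e:
        raise StageError(stage, e) from e

    # --- traits ---------------------------------------------------------------
    stage = "traits"
    try:
        observed = load_packaged_table("table2_observed")
        predicted = load_packaged_table("table2_predicted")
        report = concordance(observed, predicted)
        aux = summarize_auxotrophies(observed)
        pd.DataFrame(
            [(x.strain, x.trait, x.observed, x.predicted) for x in report.inconsistencies],
            columns=["strain", "trait", "observed", "predicted"],
        ).to_csv(out / "trait_inconsistencies.tsv", sep="\t", index=False)
        aux.rename("n_auxotrophies").to_csv(out / "auxotrophies.tsv", sep="\t")
        results["trait_report"] = report
        results["auxotrophies"] = aux
    except Exception as e:
        raise StageError(stage, e) from e

    manifest = {
        "seed": cfg.seed,
        "stages": list(STAGES),
        "config": {
            k: v
            for k, v in vars(cfg).items()
            if k != "out_dir" and isinstance(v, (int, float, str, type(None)))
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["out_dir"] = str(out)
    return results
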