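"""Simulate clades of conspecific bacterial genomes with known ground truth.

The generator builds an ancestral genome of open reading frames separated by
intergenic spacers, evolves one descendant per strain on a star phylogeny
under an equal-rates (Jukes-Cantor style) substitution model, applies gene
loss and strain-specific gene gain, and optionally inserts GC-anomalous
genomic islands carrying mobile-element marker genes, flanking direct
repeats, and cargo gene families.  Every simulated gene, island, and
expected pairwise identity is recorded in a :class:`TruthManifest`, so the
downstream pangenome, ANI, island, and HGT analyses can be scored against
planted truth without any external data.

Defaults model a three-strain clade of *Bacillus coahuilensis*-like genomes:
~38% GC background, pairwise nucleotide identities between 98.88 and 99.37%,
a dominant core genome, a small two-strain shared accessory, a few percent
strain-specific genes, and one 25-kb island whose GC is ~6 percentage points
below background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product as iproduct
from math import exp, log
from pathlib import Path

import numpy as np

from .io_formats import (
    GeneFeature,
    Genome,
    SequenceRecord,
    reverse_complement,
    write_genome,
)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

# keyword lexicon for mobile-genetic-element products; shared with the
# island-annotation module, which imports it from here
MGE_KEYWORDS = ("integrase", "transposase", "insertion sequence", "phage", "recombinase", "IS")

_MARKER_PRODUCTS = (
    "IS643 transposase",
    "phage integrase",
    "site-specific recombinase",
    "insertion sequence protein",
)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneSpec:
    """A gene to be gained by one strain."""

    family_id: str
    length_bp: int = 300  # multiple of 3, incl. start and stop codons
    gc: float | None = None  # None -> recipient background
    product: str = "hypothetical protein"
    strand: str = "+"


@dataclass
class IslandSpec:
    """A genomic island to plant in one recipient strain."""

    recipient: str
    length_bp: int = 25_000
    gc: float = 0.3168
    n_marker_genes: int = 2
    flank_repeat_len: int = 20
    cargo_families: tuple[str, ...] = ("kdsA", "kdsB")
    cargo_products: tuple[str, ...] = (
        "kdsA 2-dehydro-3-deoxyphosphooctonate aldolase",
        "kdsB 3-deoxy-manno-octulosonate cytidylyltransferase",
    )
    cargo_gene_len: int = 900

    def __post_init__(self):
        if self.length_bp < 1000:
            raise ConfigError("island length must be >= 1 kb")


@dataclass
class CladeConfig:
    strain_ids: tuple[str, ...]
    n_core: int
    shared_pattern_counts: dict[frozenset, int] = field(default_factory=dict)
    n_specific: dict[str, int] = field(default_factory=dict)
    gene_len_mean: float = 300.0
    gene_len_sd: float = 60.0
    spacer_len_range: tuple[int, int] = (50, 500)
    background_gc: float = 0.3797
    branch_sub_rate: dict[str, float] = field(default_factory=dict)
    donor_gc: float | None = None  # composition of gained genes
    islands: tuple[IslandSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.strain_ids) < 2:
            raise ConfigError("need at least 2 strains")
        if not 0.2 < self.background_gc < 0.8:
            raise ConfigError("background_gc outside (0.2, 0.8)")
        if self.n_core < 0 or any(v < 0 for v in self.n_specific.values()):
            raise ConfigError("counts must be >= 0")
        strains = set(self.strain_ids)
        for pattern, count in self.shared_pattern_counts.items():
            if count < 0:
                raise ConfigError("counts must be >= 0")
            if not set(pattern) < strains or len(pattern) < 2:
                raise ConfigError(f"bad shared pattern {set(pattern)}")
        for s, r in self.branch_sub_rate.items():
            if s not in strains:
                raise ConfigError(f"rate for unknown strain {s!r}")
            if not 0.0 <= r <= 0.25:
                raise ConfigError("substitution rates must lie in [0, 0.25]")
        for isl in self.islands:
            if isl.recipient not in strains:
                raise ConfigError(f"island recipient {isl.recipient!r} unknown")


# the modeled strain triplet and its observed pairwise nucleotide identities
STRAINS = ("m4_4", "m2_6", "p1_1_43")
PAIR_IDENTITY_TARGETS = {
    frozenset(("m4_4", "m2_6")): 0.9937,
    frozenset(("m2_6", "p1_1_43")): 0.9893,
    frozenset(("m4_4", "p1_1_43")): 0.9888,
}


def expected_pair_identity(rate_a: float, rate_b: float) -> float:
    """Expected per-site identity between two leaves of a star tree whose
    branches substitute each site with the given probabilities (equal-rates
    model): p = 1/4 + 3/4 * (1 - 4*ra/3) * (1 - 4*rb/3)."""
    return 0.25 + 0.75 * (1 - 4 * rate_a / 3) * (1 - 4 * rate_b / 3)


def star_rates_from_identities(targets: dict[frozenset, float]) -> dict[str, float]:
    """Per-branch substitution probabilities for a 3-strain star phylogeny
    that realize the three requested pairwise identities exactly (in
    expectation).  Inverts the equal-rates identity formula pairwise."""
    strains = sorted(set().union(*targets))
    if len(strains) != 3 or len(targets) != 3:
        raise ConfigError("exactly 3 strains and 3 pairwise targets required")
    a, b, c = strains

    def L(x, y):
        p = targets[frozenset((x, y))]
        g = (4 * p - 1) / 3
        if g <= 0:
            raise ConfigError(f"pair identity {p} too low for the model")
        return -log(g)

    ab, bc, ac = L(a, b), L(b, c), L(a, c)
    Ls = {a: (ab + ac - bc) / 2, b: (ab + bc - ac) / 2, c: (bc + ac - ab) / 2}
    rates = {s: 0.75 * (1 - exp(-v)) for s, v in Ls.items()}
    for s, r in rates.items():
        if not 0 <= r <= 0.25:
            raise ConfigError(f"implied branch rate for {s} out of range: {r}")
    return rates


def ani_calibration_config(seed: int = 0) -> CladeConfig:
    """A three-strain clade of ~1 Mb genomes with no gene gain/loss, used to
    check that measured ANI reproduces the calibrated pairwise identities
    (99.37 / 98.93 / 98.88) on genomes long enough for the sampling error of
    the mean fragment identity to be well below 0.1 percentage points."""
    return CladeConfig(
        strain_ids=STRAINS,
        n_core=1000,
        gene_len_mean=900.0,
        gene_len_sd=150.0,
        spacer_len_range=(50, 150),
        branch_sub_rate=star_rates_from_identities(PAIR_IDENTITY_TARGETS),
        seed=seed,
    )


def default_config(seed: int = 0, scale: float = 1.0) -> CladeConfig:
    """Desk-scale study conditions: a 1/10-scale analogue of the observed
    clade (290 core, 30 two-strain shared, 12/11/9 strain-specific genes)
    with branch rates calibrated to the observed ANI triplet and one
    GIm2d-like low-GC island in strain m2_6."""
    m4, m2, p1 = STRAINS

    def sc(x):
        return max(0, round(x * scale))

    return CladeConfig(
        strain_ids=STRAINS,
        n_core=sc(290),
        shared_pattern_counts={
            frozenset((m4, m2)): sc(14),
            frozenset((m2, p1)): sc(8),
            frozenset((m4, p1)): sc(8),
        },
        n_specific={m4: sc(11), m2: sc(9), p1: sc(12)},
        branch_sub_rate=star_rates_from_identities(PAIR_IDENTITY_TARGETS),
        islands=(IslandSpec(recipient=m2),),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sequence sampling


@lru_cache(maxsize=64)
def _codon_base_gc(target_gc: float) -> float:
    """Per-base GC probability such that stop-free codons sampled i.i.d.
    realize the target GC in expectation (stop rejection enriches GC, so the
    base probability must be corrected downward)."""

    def expected(gc):
        pr = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
        num = den = 0.0
        for codon in iproduct(BASES, repeat=3):
            c = "".join(codon)
            if c in STOP_CODONS:
                continue
            w = pr[c[0]] * pr[c[1]] * pr[c[2]]
            num += w * sum(b in "GC" for b in c) / 3
            den += w
        return num / den

    lo, hi = 0.01, 0.99
    if not expected(lo) <= target_gc <= expected(hi):
        raise ConfigError(f"GC {target_gc} not achievable by codon sampling")
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in _sample_bases(n, gc, rng))


def random_dna_exact(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with an exact GC base count (gc*n rounded), so a
    planted segment realizes its nominal composition without sampling noise."""
    n_gc = int(round(gc * n))
    arr = np.concatenate(
        [
            rng.choice([_B2I_G, _B2I_C], size=n_gc),
            rng.choice([_B2I_A, _B2I_T], size=n - n_gc),
        ]
    )
    rng.shuffle(arr)
    return "".join(BASES[i] for i in arr)


_B2I_A, _B2I_C, _B2I_G, _B2I_T = 0, 1, 2, 3


def random_orf(length_bp: int, gc: float, rng: np.random.Generator) -> str:
    """An open reading frame: ATG start, stop-free interior, one stop codon.

    length_bp counts the whole ORF including start and stop; must be a
    multiple of 3 and >= 9.
    """
    if length_bp % 3 != 0 or length_bp < 9:
        raise ConfigError(f"ORF length must be a multiple of 3 >= 9, got {length_bp}")
    n_interior = length_bp // 3 - 2
    base_gc = _codon_base_gc(gc)
    codons = _sample_bases(3 * n_interior, base_gc, rng).reshape(-1, 3)
    arr = np.array([list(c) for c in STOP_CODONS])
    stop_codes = {tuple(BASES.index(b) for b in c) for c in STOP_CODONS}
    for _ in range(100):
        bad = np.array([tuple(row) in stop_codes for row in codons])
        if not bad.any():
            break
        codons[bad] = _sample_bases(3 * int(bad.sum()), base_gc, rng).reshape(-1, 3)
    interior = "".join(BASES[i] for i in codons.ravel())
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    return "ATG" + interior + stop


def _sample_gene_len(cfg_mean: float, cfg_sd: float, rng: np.random.Generator) -> int:
    n = int(round(rng.normal(cfg_mean, cfg_sd)))
    n = max(90, n)
    return n - n % 3


# ---------------------------------------------------------------------------
# segment representation (internal): a contig is an alternating list of
# spacers and genes; building a Genome concatenates segments and emits
# features with exact coordinates.


@dataclass
class _Gene:
    family: str
    seq: str  # reading orientation, full ORF
    strand: str
    product: str


@dataclass
class _Spacer:
    seq: str


def _build_genome(strain_id: str, contigs_segments: list[list]) -> Genome:
    contigs, features = [], []
    for ci, segments in enumerate(contigs_segments):
        parts, pos = [], 0
        contig_id = f"{strain_id}_c{ci + 1}"
        for seg in segments:
            if isinstance(seg, _Spacer):
                parts.append(seg.seq)
                pos += len(seg.seq)
            else:
                nt = seg.seq if seg.strand == "+" else reverse_complement(seg.seq)
                features.append(
                    GeneFeature(
                        gene_id=f"{strain_id}_{seg.family}",
                        contig_id=contig_id,
                        start=pos,
                        end=pos + len(nt),
                        strand=seg.strand,
                        product=seg.product,
                    )
                )
                parts.append(nt)
                pos += len(nt)
        contigs.append(SequenceRecord(contig_id, "".join(parts), "dna"))
    g = Genome(strain_id, contigs, features)
    g.validate()
    return g


def _segments_from_genome(g: Genome, family_of: dict[str, str]) -> list[list]:
    """Recover the segment view of a genome built by this module."""
    out = []
    for contig in g.contigs:
        feats = sorted(
            (f for f in g.features if f.contig_id == contig.id), key=lambda f: f.start
        )
        segments, pos = [], 0
        for f in feats:
            if f.start > pos:
                segments.append(_Spacer(contig.seq[pos : f.start]))
            segments.append(
                _Gene(
                    family=family_of.get(f.gene_id, f.gene_id),
                    seq=g.feature_seq(f),
                    strand=f.strand,
                    product=f.product,
                )
            )
            pos = f.end
        if pos < len(contig.seq):
            segments.append(_Spacer(contig.seq[pos:]))
        out.append(segments)
    return out


# ---------------------------------------------------------------------------
# core operations

_B2I = {b: i for i, b in enumerate(BASES)}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Equal-rates substitutions: each site changes with probability `rate`
    to one of the three other bases, uniformly."""
    if rate == 0 or not seq:
        return seq
    arr = np.array([_B2I[b] for b in seq], dtype=np.int8)
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=n)) % 4
    return "".join(BASES[i] for i in arr)


def _destop_codon(mut: str, orig: str) -> str:
    """Redirect one substituted position of a stop codon to a different base
    so the site stays substituted (relative to the original codon) but the
    codon is no longer a stop; keeps the realized substitution rate equal to
    the nominal one."""
    diffs = [k for k in range(3) if mut[k] != orig[k]]
    for k in reversed(diffs):
        for b in BASES:
            if b in (mut[k], orig[k]):
                continue
            cand = mut[:k] + b + mut[k + 1 :]
            if cand not in STOP_CODONS:
                return cand
    return orig


def _mutate_orf(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute within an ORF; substitutions that would create a premature
    stop are redirected to another base, and the terminal stop is kept."""
    mut = _mutate(seq, rate, rng)
    if mut == seq:
        return mut
    codons = [mut[i : i + 3] for i in range(0, len(mut), 3)]
    orig = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i in range(len(codons) - 1):
        if codons[i] in STOP_CODONS:
            codons[i] = _destop_codon(codons[i], orig[i])
    if codons[-1] not in STOP_CODONS:
        codons[-1] = orig[-1]
    return "".join(codons)


def generate_ancestor(cfg: CladeConfig, rng: np.random.Generator, families=None):
    """Build the ancestral genome holding the given families (default: all
    core + shared families).  Returns (Genome, family_order)."""
    if families is None:
        families = [f"core{i:04d}" for i in range(cfg.n_core)]
        for pi, pattern in enumerate(sorted(cfg.shared_pattern_counts, key=sorted)):
            for j in range(cfg.shared_pattern_counts[pattern]):
                families.append(f"shared{pi}_{j:03d}")
    order = list(families)
    rng.shuffle(order)
    lo, hi = cfg.spacer_len_range
    segments = []
    for fam in order:
        segments.append(_Spacer(random_dna(int(rng.integers(lo, hi + 1)), cfg.background_gc, rng)))
        segments.append(
            _Gene(
                family=fam,
                seq=random_orf(
                    _sample_gene_len(cfg.gene_len_mean, cfg.gene_len_sd, rng),
                    cfg.background_gc,
                    rng,
                ),
                strand="+" if rng.random() < 0.5 else "-",
                product="hypothetical protein",
            )
        )
    segments.append(_Spacer(random_dna(int(rng.integers(lo, hi + 1)), cfg.background_gc, rng)))
    return _build_genome("ancestor", [segments]), order


def evolve_segments(
    segments: list[list],
    rate: float,
    losses: set[str],
    gains: list[GeneSpec],
    rng: np.random.Generator,
    background_gc: float,
    spacer_len_range=(50, 500),
) -> list[list]:
    """Evolve a segment view: substitutions everywhere, lost families excised
    with their preceding spacer, gained genes inserted at random intergenic
    points.  Gene order is otherwise preserved (high synteny)."""
    if rate > 0.25:
        raise ConfigError("substitution rate above 0.25 is outside model validity")
    known = {seg.family for contig in segments for seg in contig if isinstance(seg, _Gene)}
    unknown = losses - known
    if unknown:
        raise ConfigError(f"losses reference unknown families: {sorted(unknown)}")
    out = []
    for contig in segments:
        new = []
        skip_spacer = False
        for seg in contig:
            if isinstance(seg, _Spacer):
                if skip_spacer:
                    skip_spacer = False
                    continue
                new.append(_Spacer(_mutate(seg.seq, rate, rng)))
            else:
                if seg.family in losses:
                    # drop the gene together with the spacer that follows it
                    skip_spacer = True
                    continue
                new.append(
                    _Gene(seg.family, _mutate_orf(seg.seq, rate, rng), seg.strand, seg.product)
                )
        out.append(new)
    # gains: insert each new gene (with a fresh spacer) at a random boundary
    lo, hi = spacer_len_range
    for spec in gains:
        gc = spec.gc if spec.gc is not None else background_gc
        gene = _Gene(
            spec.family_id,
            random_orf(spec.length_bp, gc, rng),
            spec.strand,
            spec.product,
        )
        contig = out[int(rng.integers(len(out)))]
        # boundaries after spacer segments keep the spacer/gene alternation
        slots = [i + 1 for i, seg in enumerate(contig) if isinstance(seg, _Spacer)]
        at = slots[int(rng.integers(len(slots)))]
        contig[at:at] = [gene, _Spacer(random_dna(int(rng.integers(lo, hi + 1)), gc, rng))]
    return out


def evolve_genome(
    ancestor: Genome,
    rate: float,
    losses: set[str],
    gains: list[GeneSpec],
    rng: np.random.Generator,
    strain_id: str = "descendant",
    background_gc: float = 0.38,
    family_of: dict[str, str] | None = None,
) -> Genome:
    """Genome-level wrapper around :func:`evolve_segments`.

    `family_of` maps the ancestor's gene ids to family ids; by default the
    ancestor's ``ancestor_`` prefix is stripped.
    """
    if family_of is None:
        family_of = {
            f.gene_id: f.gene_id.removeprefix(f"{ancestor.strain_id}_")
            for f in ancestor.features
        }
    segs = _segments_from_genome(ancestor, family_of)
    segs = evolve_segments(segs, rate, losses, gains, rng, background_gc)
    return _build_genome(strain_id, segs)


def plant_island(
    g: Genome, spec: IslandSpec, rng: np.random.Generator, family_of=None
) -> tuple[Genome, dict]:
    """Insert a GC-defined island into a genome; returns (genome, truth).

    The island consists of optional exact direct repeats at both ends,
    mobile-element marker genes whose products carry lexicon keywords, cargo
    gene families, and spacer fill, all sampled at the island's GC.
    """
    if family_of is None:
        family_of = {f.gene_id: f.gene_id.removeprefix(f"{g.strain_id}_") for f in g.features}
    segs = _segments_from_genome(g, family_of)

    genes = []
    for i in range(spec.n_marker_genes):
        genes.append(
            _Gene(
                family=f"mge_{spec.recipient}_{i}",
                seq=random_orf(900, spec.gc, rng),
                strand="+",
                product=_MARKER_PRODUCTS[i % len(_MARKER_PRODUCTS)],
            )
        )
    for fam, prod in zip(spec.cargo_families, spec.cargo_products):
        genes.append(
            _Gene(fam, random_orf(spec.cargo_gene_len, spec.gc, rng), "+", prod)
        )
    fixed = 2 * spec.flank_repeat_len + sum(len(x.seq) for x in genes)
    fill = spec.length_bp - fixed
    if fill < len(genes) + 1:
        raise ConfigError("island length too small for its genes and repeats")
    cuts = np.sort(rng.integers(0, fill + 1, size=len(genes)))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [fill]]))

    repeat = random_dna_exact(spec.flank_repeat_len, spec.gc, rng) if spec.flank_repeat_len else ""
    island_segs = []
    if repeat:
        island_segs.append(_Spacer(repeat))
    order = list(genes)
    rng.shuffle(order)
    for ln, gene in zip(spacer_lens, order):
        island_segs.append(_Spacer(random_dna_exact(int(ln), spec.gc, rng)))
        island_segs.append(gene)
    island_segs.append(_Spacer(random_dna_exact(int(spacer_lens[-1]), spec.gc, rng)))
    if repeat:
        island_segs.append(_Spacer(repeat))
    island_len = sum(
        len(s.seq) for s in island_segs
    )

    # insert into the largest contig at a random spacer boundary
    sizes = [sum(len(s.seq) for s in contig) for contig in segs]
    ci = int(np.argmax(sizes))
    contig = segs[ci]
    if island_len > sizes[ci]:
        raise ConfigError("island longer than the recipient contig")
    slots = [i + 1 for i, seg in enumerate(contig) if isinstance(seg, _Spacer)]
    at = slots[int(rng.integers(len(slots)))]
    start = sum(len(s.seq) for s in contig[:at])
    contig[at:at] = island_segs

    new = _build_genome(g.strain_id, segs)
    truth = {
        "recipient": spec.recipient,
        "contig_id": new.contigs[ci].id,
        "start": start,
        "end": start + island_len,
        "gc": spec.gc,
        "marker_gene_ids": [f"{g.strain_id}_{x.family}" for x in genes if x.family.startswith("mge_")],
        "cargo_families": list(spec.cargo_families),
        "flank_repeat_len": spec.flank_repeat_len,
    }
    return new, truth


# ---------------------------------------------------------------------------
# manifest and whole-clade generation


@dataclass
class TruthManifest:
    families: dict  # family_id -> {"category": ..., "members": {strain: gene_id}}
    islands: list  # island truth dicts
    expected_pair_identity: dict  # "a|b" (sorted) -> expected per-site identity
    species_tree: str  # newick over strain ids (star topology, branch rates)
    transferred_families: list
    seed: int

    def category_counts(self) -> dict:
        counts = {"core": 0, "shared": 0, "specific": 0}
        for fam in self.families.values():
            counts[fam["category"]] += 1
        return counts

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Clade:
    genomes: dict[str, Genome]
    manifest: TruthManifest


def generate_clade(cfg: CladeConfig, out_dir=None) -> Clade:
    """Generate the full clade with planted truth; optionally write per-strain
    FASTA/GFF3/protein-FASTA plus the JSON manifest to `out_dir`."""
    rng = np.random.default_rng(cfg.seed)
    ancestor, order = generate_ancestor(cfg, rng)
    anc_family_of = {f.gene_id: f.gene_id.removeprefix("ancestor_") for f in ancestor.features}

    # which strains carry each ancestral family
    carriers = {}
    for fam in order:
        if fam.startswith("core"):
            carriers[fam] = set(cfg.strain_ids)
    patterns = sorted(cfg.shared_pattern_counts, key=sorted)
    for pi, pattern in enumerate(patterns):
        for fam in order:
            if fam.startswith(f"shared{pi}_"):
                carriers[fam] = set(pattern)

    genomes, islands, transferred = {}, [], []
    families: dict[str, dict] = {}
    for strain in cfg.strain_ids:
        losses = {fam for fam, who in carriers.items() if strain not in who}
        gains = [
            GeneSpec(
                family_id=f"{strain}_sp{j:03d}",
                length_bp=_sample_gene_len(cfg.gene_len_mean, cfg.gene_len_sd, rng),
                gc=cfg.donor_gc,
                product="hypothetical protein",
                strand="+" if rng.random() < 0.5 else "-",
            )
            for j in range(cfg.n_specific.get(strain, 0))
        ]
        rate = cfg.branch_sub_rate.get(strain, 0.0)
        g = evolve_genome(
            ancestor, rate, losses, gains, rng, strain, cfg.background_gc, anc_family_of
        )
        for isl in cfg.islands:
            if isl.recipient == strain:
                g, truth = plant_island(g, isl, rng)
                islands.append(truth)
                for fam in isl.cargo_families:
                    transferred.append(fam)
        genomes[strain] = g

    # assemble the family table from what was actually generated
    for strain, g in genomes.items():
        for f in g.features:
            fam = f.gene_id.removeprefix(f"{strain}_")
            entry = families.setdefault(fam, {"members": {}, "category": None})
            entry["members"][strain] = f.gene_id
    for fam, entry in families.items():
        ns = len(entry["members"])
        entry["category"] = (
            "core" if ns == len(cfg.strain_ids) else ("specific" if ns == 1 else "shared")
        )

    pair_ids = {}
    ids = sorted(cfg.strain_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pair_ids[f"{a}|{b}"] = expected_pair_identity(
                cfg.branch_sub_rate.get(a, 0.0), cfg.branch_sub_rate.get(b, 0.0)
            )
    newick = (
        "("
        + ",".join(f"{s}:{cfg.branch_sub_rate.get(s, 0.0):.6f}" for s in cfg.strain_ids)
        + ");"
    )
    manifest = TruthManifest(
        families=families,
        islands=islands,
        expected_pair_identity=pair_ids,
        species_tree=newick,
        transferred_families=transferred,
        seed=cfg.seed,
    )
    clade = Clade(genomes, manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for strain, g in genomes.items():
            write_genome(g, out_dir)
        manifest.to_json(out_dir / "manifest.json")
    return clade


# ---------------------------------------------------------------------------
# protein-family simulation for gene-tree / species-tree tests

AA = "ACDEFGHIKLMNPQRSTVWY"


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array([AA.index(a) for a in seq], dtype=np.int8)
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        arr[hit] = (arr[hit] + rng.integers(1, 20, size=n)) % 20
    return "".join(AA[i] for i in arr)


# Species tree used for gene-family simulations in HGT tests: the three
# conspecific strains, three relatives, a two-taxon donor clade, and an
# outgroup; branch lengths are per-site substitution probabilities.
HGT_TEST_SPECIES_TREE = (
    "((((m4_4:0.010,m2_6:0.008):0.005,p1_1_43:0.012):0.10,"
    "((rel1:0.05,rel2:0.06):0.08,(donorA:0.03,donorB:0.04):0.18):0.03):0.05,"
    "outg:0.25);"
)


def seed_alignment_for_family(
    protein: str, rng: np.random.Generator, n_rows: int = 4, rate: float = 0.05
) -> dict[str, str]:
    """A synthetic seed alignment for a planted family: the representative
    protein plus mutated homologs (equal length, hence trivially aligned)."""
    rows = {"seed0": protein}
    for i in range(1, n_rows):
        rows[f"seed{i}"] = _mutate_protein(protein, rate, rng)
    return rows


def simulate_gene_family(
    species_tree_newick: str,
    length: int,
    rng: np.random.Generator,
    transfer: tuple[str, str, float] | None = None,
) -> dict[str, str]:
    """Evolve a protein family down a species tree whose branch lengths are
    per-site substitution probabilities.  `transfer=(recipient, donor, r)`
    replaces the recipient's sequence with a copy of the donor's leaf
    sequence evolved by a further substitution probability r, emulating a
    horizontal transfer from the donor lineage."""
    import dendropy

    tree = dendropy.Tree.get(
        data=species_tree_newick, schema="newick", preserve_underscores=True
    )
    root_seq = "".join(AA[i] for i in rng.integers(0, 20, size=length))
    seqs: dict = {}
    node_seq = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        rate = node.edge.length or 0.0
        node_seq[node] = _mutate_protein(node_seq[node.parent_node], rate, rng)
        if node.is_leaf():
            seqs[node.taxon.label] = node_seq[node]
    if transfer is not None:
        recipient, donor, r = transfer
        if recipient not in seqs or donor not in seqs:
            raise ConfigError("transfer taxa absent from the species tree")
        seqs[recipient] = _mutate_protein(seqs[donor], r, rng)
    return seqs
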