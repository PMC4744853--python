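"""Protein orthology by bidirectional best hits and pangenome partitioning.

All-vs-all Smith-Waterman local alignment (affine gaps, BLOSUM62) produces
best-hit maps per proteome pair; reciprocal best hits passing an E-value
ceiling and a mutual-coverage floor (defaults: 1e-6 and 60%, the thresholds
used for the strain comparison this package models) define orthology edges.
Ortholog families are the connected components of the union BBH graph, with
per-strain paralog resolution, and are classified core / shared /
strain-specific by the set of strains represented.

Alignment itself is delegated to Biopython's PairwiseAligner; bit scores and
E-values use fixed Karlin-Altschul constants, since here they act as a
filter rather than a calibrated statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import PROTEIN_ALPHABET, Genome


@dataclass
class ScoringParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11  # cost of a length-1 gap is gap_open + gap_extend
    gap_extend: int = 1
    # gapped BLOSUM62 Karlin-Altschul constants
    lambda_: float = 0.267
    k: float = 0.041


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    identity: float  # identical positions / aligned columns (gaps included)
    qcov: float  # aligned query span / query length
    scov: float


def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{name}: non-protein characters {sorted(bad)}")


def bitscore_from_raw(raw: float, scoring: ScoringParams) -> float:
    return (scoring.lambda_ * raw - math.log(scoring.k)) / math.log(2)


def local_align(
    a: str,
    b: str,
    scoring: ScoringParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    m: int | None = None,
    n: int | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> AlignmentHit:
    """Optimal local alignment of two proteins with affine gap penalties.

    `m` and `n` are the effective query/database residue totals for the
    E-value (default: the two sequence lengths)."""
    scoring = scoring or ScoringParams()
    _check_protein(a, query_id)
    _check_protein(b, subject_id)
    aligner = _aligner or _make_aligner(scoring)
    aln = aligner.align(a, b)[0]
    raw = aln.score
    qblocks, sblocks = aln.aligned
    matches = columns = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_q is not None:
            columns += (qs - prev_q) + (ss - prev_s)  # gap columns between blocks
        columns += qe - qs
        matches += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
        prev_q, prev_s = qe, se
    qspan = qblocks[-1][1] - qblocks[0][0] if len(qblocks) else 0
    sspan = sblocks[-1][1] - sblocks[0][0] if len(sblocks) else 0
    bits = bitscore_from_raw(raw, scoring)
    m = m if m is not None else len(a)
    n = n if n is not None else len(b)
    evalue = m * n * 2.0 ** (-bits)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bitscore=bits,
        evalue=evalue,
        identity=matches / columns if columns else 0.0,
        qcov=qspan / len(a),
        scov=sspan / len(b),
    )


# ---------------------------------------------------------------------------
# best hits with a k-mer prefilter

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_hits(
    A: dict[str, str],
    B: dict[str, str],
    scoring: ScoringParams | None = None,
    max_eval: float = 1e-6,
    prefilter_k: int = 4,
    min_shared_kmers: int = 3,
) -> dict[str, AlignmentHit]:
    """Per query in A, the best-bitscore hit in B passing the E-value cut.

    Candidate subjects are prefiltered by shared amino-acid k-mer count
    (seed-and-extend heuristic); set min_shared_kmers=0 to align every pair
    exhaustively.  Ties on bitscore break to the higher identity, then the
    lexicographically smaller subject id.  Self hits (same id) are skipped.
    """
    if not A or not B:
        raise ValueError("proteomes must be non-empty")
    scoring = scoring or ScoringParams()
    aligner = _make_aligner(scoring)
    m_total = sum(len(s) for s in A.values())
    n_total = sum(len(s) for s in B.values())
    index: dict[str, set[str]] = {}
    if min_shared_kmers > 0:
        for sid, seq in B.items():
            for kmer in _kmers(seq, prefilter_k):
                index.setdefault(kmer, set()).add(sid)
    out: dict[str, AlignmentHit] = {}
    for qid, qseq in A.items():
        if min_shared_kmers > 0:
            votes: dict[str, int] = {}
            for kmer in _kmers(qseq, prefilter_k):
                for sid in index.get(kmer, ()):
                    votes[sid] = votes.get(sid, 0) + 1
            candidates = [s for s, v in votes.items() if v >= min_shared_kmers]
        else:
            candidates = list(B)
        best = None
        for sid in sorted(candidates):
            if sid == qid:
                continue
            hit = local_align(
                qseq, B[sid], scoring, qid, sid, m=m_total, n=n_total, _aligner=aligner
            )
            if hit.evalue > max_eval:
                continue
            if best is None or (hit.bitscore, hit.identity, [best.subject_id]) > (
                best.bitscore,
                best.identity,
                [sid],
            ):
                # note: subject-id comparison is inverted (smaller id wins)
                best = hit
        if best is not None:
            out[qid] = best
    return out


def bidirectional_best_hits(
    A: dict[str, str],
    B: dict[str, str],
    min_cov: float = 0.60,
    max_eval: float = 1e-6,
    scoring: ScoringParams | None = None,
    **kwargs,
) -> list[tuple[AlignmentHit, AlignmentHit]]:
    """Reciprocal best hits between two proteomes.

    (a, b) is a BBH iff a's best hit in B is b, b's best hit in A is a, the
    E-value passes in both directions, and min(qcov, scov) >= min_cov in
    both directions."""
    if not 0 < min_cov <= 1:
        raise ValueError("min_cov must lie in (0, 1]")
    fwd = best_hits(A, B, scoring, max_eval, **kwargs)
    rev = best_hits(B, A, scoring, max_eval, **kwargs)
    pairs = []
    for qid, hit in fwd.items():
        back = rev.get(hit.subject_id)
        if back is None or back.subject_id != qid:
            continue
        if min(hit.qcov, hit.scov, back.qcov, back.scov) < min_cov:
            continue
        pairs.append((hit, back))
    return pairs


# ---------------------------------------------------------------------------
# families and partition


@dataclass
class OrthologFamily:
    family_id: str
    members: dict[str, str]  # strain -> gene_id (<= 1 per strain)
    category: str  # {"core", "shared", "specific"}


@dataclass
class PangenomePartition:
    families: list[OrthologFamily]
    n_pangenome: int
    n_core: int
    n_shared: int
    per_strain_specific: dict[str, int]
    core_fraction_of_mean_cds: float  # percent, rounded for reporting


def build_families(
    proteomes: dict[str, dict[str, str]],
    bbh_pairs: dict[frozenset, list[tuple[AlignmentHit, AlignmentHit]]],
) -> list[OrthologFamily]:
    """Ortholog families as connected components of the union BBH graph.

    Components holding more than one gene from a strain keep, per strain,
    the gene with the highest summed bitscore to the other members; the
    displaced paralogs are re-seated as singleton families.  Genes with no
    BBH edge become strain-specific singletons."""
    graph = nx.Graph()
    for strain, prot in proteomes.items():
        for gid in prot:
            graph.add_node((strain, gid))
    for pair, hits in bbh_pairs.items():
        a_strain, b_strain = sorted(pair)
        for fwd, _back in hits:
            graph.add_edge(
                (a_strain, fwd.query_id),
                (b_strain, fwd.subject_id),
                weight=fwd.bitscore,
            )
    n_strains = len(proteomes)
    families: list[OrthologFamily] = []

    def categorize(strains: set[str]) -> str:
        if len(strains) == n_strains:
            return "core"
        return "specific" if len(strains) == 1 else "shared"

    singletons: list[tuple[str, str]] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c))
    for comp in comps:
        by_strain: dict[str, list] = {}
        for node in comp:
            by_strain.setdefault(node[0], []).append(node)
        kept = []
        for strain, nodes in sorted(by_strain.items()):
            if len(nodes) == 1:
                kept.append(nodes[0])
                continue
            scored = sorted(
                nodes,
                key=lambda nd: (
                    -sum(d["weight"] for _, _, d in graph.edges(nd, data=True)),
                    nd[1],
                ),
            )
            kept.append(scored[0])
            singletons.extend(scored[1:])
        if len(kept) == 1:
            singletons.append(kept[0])
            continue
        members = {s: g for s, g in sorted(kept)}
        families.append(
            OrthologFamily(
                family_id=f"OF{len(families) + 1:05d}",
                members=members,
                category=categorize(set(members)),
            )
        )
    for strain, gid in sorted(singletons):
        families.append(
            OrthologFamily(
                family_id=f"OF{len(families) + 1:05d}",
                members={strain: gid},
                category="specific",
            )
        )
    return families


def pangenome_counts(
    families: list[OrthologFamily], cds_counts: dict[str, int]
) -> PangenomePartition:
    """Partition summary; core fraction is reported against the mean CDS
    count of the compared strains."""
    if not families:
        raise ValueError("empty family list")
    n_core = sum(1 for f in families if f.category == "core")
    n_shared = sum(1 for f in families if f.category == "shared")
    specific: dict[str, int] = {s: 0 for s in cds_counts}
    for f in families:
        if f.category == "specific":
            (strain,) = f.members
            specific[strain] = specific.get(strain, 0) + 1
    mean_cds = sum(cds_counts.values()) / len(cds_counts)
    return PangenomePartition(
        families=families,
        n_pangenome=len(families),
        n_core=n_core,
        n_shared=n_shared,
        per_strain_specific=specific,
        core_fraction_of_mean_cds=round(100.0 * n_core / mean_cds),
    )


def core_fraction_percent(n_core: int, cds_counts: list[int]) -> int:
    """Core-genome share of the mean per-strain CDS count, in percent."""
    mean_cds = sum(cds_counts) / len(cds_counts)
    return round(100.0 * n_core / mean_cds)


# ---------------------------------------------------------------------------
# synteny


def synteny_conservation(
    gA: Genome, gB: Genome, families: list[OrthologFamily]
) -> float:
    """Fraction of adjacent core-gene pairs in A whose family images are also
    adjacent (either orientation) in B."""
    fam_of = {}
    for fam in families:
        if fam.category != "core":
            continue
        for strain, gid in fam.members.items():
            fam_of[(strain, gid)] = fam.family_id

    def ordered_core(g: Genome):
        per_contig: dict[str, list] = {}
        for f in sorted(g.features, key=lambda f: (f.contig_id, f.start)):
            fid = fam_of.get((g.strain_id, f.gene_id))
            if fid is not None:
                per_contig.setdefault(f.contig_id, []).append(fid)
        return per_contig

    a_order = ordered_core(gA)
    b_order = ordered_core(gB)
    b_adjacent = set()
    for fams in b_order.values():
        for x, y in zip(fams, fams[1:]):
            b_adjacent.add(frozenset((x, y)))
    total = kept = 0
    for fams in a_order.values():
        for x, y in zip(fams, fams[1:]):
            total += 1
            if frozenset((x, y)) in b_adjacent:
                kept += 1
    if total == 0:
        raise ValueError("synteny undefined: fewer than 2 core genes per contig")
    return kept / total


# ---------------------------------------------------------------------------
# whole-clade convenience


def pangenome(
    genomes: dict[str, Genome],
    min_cov: float = 0.60,
    max_eval: float = 1e-6,
    scoring: ScoringParams | None = None,
    **kwargs,
) -> tuple[PangenomePartition, dict[frozenset, list]]:
    """All pairwise BBH sets, families, and the partition for a strain set."""
    from .io_formats import proteome

    prots = {s: proteome(g) for s, g in genomes.items()}
    bbh: dict[frozenset, list] = {}
    strains = sorted(prots)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            bbh[frozenset((a, b))] = bidirectional_best_hits(
                prots[a], prots[b], min_cov, max_eval, scoring, **kwargs
            )
    families = build_families(prots, bbh)
    cds_counts = {s: len(g.features) for s, g in genomes.items()}
    return pangenome_counts(families, cds_counts), bbh
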