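"""Fragment-based average nucleotide identity (ANI) between genome pairs.

The query genome is cut into consecutive non-overlapping 1,020-nt fragments;
each fragment is mapped to the best location on either strand of the subject
(k-mer seeding, then alignment of the candidate window); fragments whose
best alignment reaches >= 30% identity over >= 70% of their length are
retained, and the directed ANI is the mean identity of retained fragments.
The symmetric ANI is the mean of the two directed values.  These constants
are the defining parameters of the fragment-mapping ANI flavor and are all
exposed as arguments.

Candidate windows are aligned with edlib (glocal, free target ends) and the
best local block within the glocal alignment is extracted from the CIGAR, so
fragments that overhang deleted or non-homologous subject regions are scored
only over their genuinely aligned span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

import edlib
import numpy as np
import pandas as pd

from .io_formats import Genome, reverse_complement


@dataclass
class Fragment:
    contig_id: str
    start: int
    end: int
    seq: str


@dataclass
class FragmentHit:
    identity: float  # matches / aligned columns of the best local block
    aligned_query_len: int  # query bases inside the best local block
    strand: str
    subject_start: int  # window coordinate, diagnostic only


@dataclass
class AniResult:
    query_strain: str
    subject_strain: str
    n_fragments: int
    n_retained: int
    identities: list[float]
    ani_directed: float  # percent; NaN when nothing retained

    @property
    def defined(self) -> bool:
        return self.n_retained > 0


def fragment_genome(g: Genome, frag_len: int = 1020) -> list[Fragment]:
    """Consecutive non-overlapping windows per contig; the trailing remainder
    shorter than frag_len is discarded."""
    if g.length() < frag_len:
        raise ValueError(
            f"{g.strain_id}: genome ({g.length()} bp) shorter than fragment length"
        )
    frags = []
    for contig in g.contigs:
        for start in range(0, len(contig.seq) - frag_len + 1, frag_len):
            frags.append(
                Fragment(contig.id, start, start + frag_len, contig.seq[start : start + frag_len])
            )
    return frags


class SubjectIndex:
    """Exact k-mer index over the forward strands of a subject genome.

    Fragments are looked up on both their own orientations, so the reverse
    strand of the subject is covered without a second index.
    """

    def __init__(self, g: Genome, k: int = 16, max_occ: int = 8):
        self.k = k
        self.contigs = [c.seq for c in g.contigs]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, seq in enumerate(self.contigs):
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i : i + k]
                occ = self.index.setdefault(kmer, [])
                if len(occ) < max_occ:
                    occ.append((ci, i))


def _cigar_runs(cigar: str):
    runs, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            runs.append((int(num), ch))
            num = ""
    return runs


_RUN_SCORE = {"=": 1.0, "X": -1.0, "I": -2.0, "D": -2.0}


def _best_local_block(runs):
    """Maximum-scoring contiguous run interval (match +1, mismatch -1,
    gap -2 per column) within a glocal alignment; returns
    (matches, columns, query_len) of that interval."""
    best = (0.0, 0, 0, 0)  # score, matches, columns, qlen
    cur_score, cur_m, cur_c, cur_q = 0.0, 0, 0, 0
    for n, op in runs:
        cur_score += n * _RUN_SCORE[op]
        cur_c += n
        if op == "=":
            cur_m += n
        if op in "=XI":
            cur_q += n
        if cur_score <= 0:
            cur_score, cur_m, cur_c, cur_q = 0.0, 0, 0, 0
        elif cur_score > best[0]:
            best = (cur_score, cur_m, cur_c, cur_q)
    return best[1], best[2], best[3]


def map_fragment(
    frag: Fragment,
    index: SubjectIndex,
    seed_stride: int = 64,
    pad: int = 200,
) -> FragmentHit | None:
    """Best placement of a fragment on the indexed subject, or None.

    Seeds are exact k-mers sampled along the fragment on both orientations;
    the most-voted candidate window is rescored by alignment."""
    k = index.k
    best_hit: FragmentHit | None = None
    for strand, seq in (("+", frag.seq), ("-", reverse_complement(frag.seq))):
        votes: dict[tuple[int, int], int] = {}
        for off in range(0, len(seq) - k + 1, seed_stride):
            for ci, pos in index.index.get(seq[off : off + k], ()):
                anchor = (ci, max(0, pos - off - pad))
                votes[anchor] = votes.get(anchor, 0) + 1
        if not votes:
            continue
        (ci, wstart), _ = max(votes.items(), key=lambda kv: (kv[1], -kv[0][1]))
        window = index.contigs[ci][wstart : wstart + len(seq) + 2 * pad]
        aln = edlib.align(seq, window, mode="HW", task="path")
        if aln["editDistance"] < 0 or not aln.get("cigar"):
            continue
        matches, columns, qlen = _best_local_block(_cigar_runs(aln["cigar"]))
        if columns == 0:
            continue
        hit = FragmentHit(
            identity=matches / columns,
            aligned_query_len=qlen,
            strand=strand,
            subject_start=wstart,
        )
        if best_hit is None or hit.identity * hit.aligned_query_len > (
            best_hit.identity * best_hit.aligned_query_len
        ):
            best_hit = hit
    return best_hit


def ani_directed(
    q: Genome,
    s: Genome,
    frag_len: int = 1020,
    min_id: float = 0.30,
    min_frac: float = 0.70,
    k: int = 16,
) -> AniResult:
    """One direction of the fragment-mapping ANI protocol."""
    for name, v in (("min_id", min_id), ("min_frac", min_frac)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    frags = fragment_genome(q, frag_len)
    index = SubjectIndex(s, k=k)
    retained = []
    for frag in frags:
        hit = map_fragment(frag, index)
        if hit is None:
            continue
        if hit.identity >= min_id and hit.aligned_query_len >= min_frac * frag_len:
            retained.append(hit.identity)
    return AniResult(
        query_strain=q.strain_id,
        subject_strain=s.strain_id,
        n_fragments=len(frags),
        n_retained=len(retained),
        identities=retained,
        ani_directed=100.0 * float(np.mean(retained)) if retained else nan,
    )


@dataclass
class AniPair:
    forward: AniResult
    reverse: AniResult

    @property
    def ani_symmetric(self) -> float:
        vals = [
            r.ani_directed for r in (self.forward, self.reverse) if r.defined
        ]
        return float(np.mean(vals)) if vals else nan


def ani_pair(q: Genome, s: Genome, **kwargs) -> AniPair:
    """Both directions plus the symmetric (mean) ANI."""
    return AniPair(ani_directed(q, s, **kwargs), ani_directed(s, q, **kwargs))


def ani_matrix(genomes: dict[str, Genome], **kwargs) -> pd.DataFrame:
    """Symmetric strain x strain ANI matrix in percent (diagonal 100)."""
    strains = sorted(genomes)
    mat = pd.DataFrame(100.0, index=strains, columns=strains)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            val = ani_pair(genomes[a], genomes[b], **kwargs).ani_symmetric
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat
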