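"""Log-odds profile models for marker-family detection in proteomes.

A profile is built from a seed alignment of a protein family: per kept
column (gap fraction < 0.5), the score of amino acid *a* is
log2((count_a + pc * bg_a) / (n + pc) / bg_a) with pseudocount weight pc and
background bg.  Scanning slides the profile ungapped along a protein and
reports the best placement score in bits; significance comes from a Gumbel
null fitted by moment matching to the best scores of composition-preserving
shuffles of the target proteome.  The end product is a strain x family
presence/absence repertoire at an E-value cut.

This is deliberately a position-specific scoring model, not a full profile
HMM: the families of interest (phosphonate transporters and related
phosphorus-acquisition enzymes, mobile-element proteins) are well conserved,
and presence/absence detection does not require insert-state modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log2, pi, sqrt

import numpy as np
import pandas as pd

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}


@dataclass
class ProfileModel:
    family: str
    scores: np.ndarray  # (length, 20) log-odds in bits
    background: np.ndarray  # (20,)
    pseudocount: float

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        return "".join(AA[i] for i in self.scores.argmax(axis=1))


@dataclass
class ProfileHit:
    family: str
    protein_id: str
    bitscore: float
    evalue: float
    start: int  # placement on the protein, 0-based
    end: int


def build_profile(
    seed_msa: dict[str, str],
    family: str = "family",
    pseudocount: float = 1.0,
    background: str = "uniform",
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Column log-odds profile from an aligned seed family.

    Columns with a gap fraction >= max_gap_fraction are dropped; background
    is uniform (1/20) or derived from the seed residue composition."""
    rows = list(seed_msa.values())
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("seed alignment rows differ in length")
    n = len(rows)
    cols = [
        [r[i] for r in rows]
        for i in range(width)
        if sum(r[i] == "-" for r in rows) / n < max_gap_fraction
    ]
    if not cols:
        raise ValueError("no columns left after gap filtering")
    if background == "uniform":
        bg = np.full(20, 1 / 20)
    elif background == "seed-derived":
        counts = np.zeros(20)
        for col in cols:
            for a in col:
                if a in _AA_INDEX:
                    counts[_AA_INDEX[a]] += 1
        bg = (counts + 1) / (counts.sum() + 20)
    else:
        raise ValueError(f"unknown background {background!r}")
    scores = np.zeros((len(cols), 20))
    for ci, col in enumerate(cols):
        counts = np.zeros(20)
        for a in col:
            if a in _AA_INDEX:
                counts[_AA_INDEX[a]] += 1
        m = counts.sum()
        freq = (counts + pseudocount * bg) / (m + pseudocount)
        scores[ci] = np.log2(freq / bg)
    return ProfileModel(family, scores, bg, pseudocount)


def _encode(protein: str) -> np.ndarray:
    # unknown residues (X) score as the column mean over the background: use
    # index -1 pointing at an appended neutral column
    return np.array([_AA_INDEX.get(a, 20) for a in protein], dtype=np.int64)


def scan_protein(
    profile: ProfileModel, protein: str, protein_id: str = "protein", glocal: bool = False
) -> ProfileHit:
    """Best ungapped placement of the profile along the protein.

    glocal=True additionally allows placements truncated at either protein
    terminus (the overhanging profile columns score zero)."""
    if not protein:
        raise ValueError("empty protein")
    L, W = len(protein), profile.length
    padded = np.hstack([profile.scores, np.zeros((W, 1))])  # X and overhangs score 0
    enc = _encode(protein)
    pad = W - 1 if glocal else 0
    enc_p = np.concatenate([np.full(pad, 20), enc, np.full(pad, 20)])
    if len(enc_p) < W:  # protein shorter than the profile: truncate at the end
        enc_p = np.concatenate([enc_p, np.full(W - len(enc_p), 20)])
    windows = np.lib.stride_tricks.sliding_window_view(enc_p, W)
    scores = padded[np.arange(W)[None, :], windows].sum(axis=1)
    i = int(scores.argmax())
    best = float(scores[i])
    off = i - pad  # placement of profile column 0 on the protein
    best_span = (max(0, off), min(L, off + W))
    return ProfileHit(
        family=profile.family,
        protein_id=protein_id,
        bitscore=best,
        evalue=float("nan"),
        start=best_span[0],
        end=best_span[1],
    )


# ---------------------------------------------------------------------------
# E-value calibration against composition-preserving decoys

_EULER_GAMMA = 0.5772156649015329


@dataclass
class GumbelNull:
    mu: float
    beta: float
    n_targets: int

    def evalue(self, score: float) -> float:
        # expected count of decoy proteins reaching `score`
        z = (score - self.mu) / self.beta
        if z > 700:
            return 0.0
        return self.n_targets * (1 - exp(-exp(-z)))


def shuffle_proteome(
    proteome: dict[str, str], rng: np.random.Generator
) -> dict[str, str]:
    """Per-protein residue shuffle: the composition-matched null."""
    out = {}
    for pid, seq in proteome.items():
        arr = np.array(list(seq))
        rng.shuffle(arr)
        out[pid] = "".join(arr)
    return out


def calibrate_evalue(
    profile: ProfileModel,
    proteome: dict[str, str],
    rng: np.random.Generator,
    n_decoys: int = 200,
    glocal: bool = True,
) -> GumbelNull:
    """Fit a Gumbel (mu, beta) to per-decoy best scores by moment matching.

    Decoys are composition-preserving shuffles of proteins drawn from the
    target proteome, so the null matches the search space.  Glocal scoring
    (terminal truncation allowed) is the default so that proteins shorter
    than the profile contribute a well-behaved max-score null instead of a
    forced full-width placement."""
    if n_decoys < 100:
        raise ValueError("need at least 100 decoys for a stable fit")
    ids = sorted(proteome)
    picks = rng.choice(len(ids), size=n_decoys, replace=True)
    scores = []
    for i in picks:
        seq = proteome[ids[int(i)]]
        arr = np.array(list(seq))
        rng.shuffle(arr)
        scores.append(scan_protein(profile, "".join(arr), glocal=glocal).bitscore)
    scores = np.array(scores)
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate decoy score variance")
    beta = sd * sqrt(6) / pi
    mu = float(scores.mean()) - _EULER_GAMMA * beta
    return GumbelNull(mu=mu, beta=beta, n_targets=len(proteome))


def scan_proteome(
    profile: ProfileModel,
    proteome: dict[str, str],
    null: GumbelNull | None = None,
    glocal: bool = True,
) -> list[ProfileHit]:
    hits = []
    for pid in sorted(proteome):
        hit = scan_protein(profile, proteome[pid], pid, glocal=glocal)
        if null is not None:
            hit.evalue = null.evalue(hit.bitscore)
        hits.append(hit)
    hits.sort(key=lambda h: (-h.bitscore, h.protein_id))
    return hits


def repertoire(
    proteomes: dict[str, dict[str, str]],
    profiles: list[ProfileModel],
    rng: np.random.Generator,
    evalue_cut: float = 1e-6,
    n_decoys: int = 200,
) -> pd.DataFrame:
    """Presence/absence table, families as rows, strains as columns; "+" iff
    at least one protein passes the E-value cut."""
    strains = sorted(proteomes)
    table = pd.DataFrame("-", index=[p.family for p in profiles], columns=strains)
    for profile in profiles:
        for strain in strains:
            null = calibrate_evalue(profile, proteomes[strain], rng, n_decoys)
            hits = scan_proteome(profile, proteomes[strain], null)
            if hits and hits[0].evalue <= evalue_cut:
                table.loc[profile.family, strain] = "+"
    return table
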