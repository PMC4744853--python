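"""Gene-tree / species-tree incongruence and multi-evidence HGT verdicts.

Gene trees are built by neighbor joining on model-corrected distances from a
center-star multiple alignment, with nodal support from bootstrap resampling
of alignment columns (default 100 pseudo-replicates; supports reported as
percentages).  A candidate locus is scored on three independent signals:

* composition - the locus lies in a GC-anomalous island call;
* genomic context - mobile-element marker genes or flanking direct repeats;
* phylogeny - the focal taxon's smallest well-supported sister clade in the
  gene tree is disjoint from its sister clade in the species tree.

Two or three positive signals give the verdict "supported", one "partial",
zero "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, log

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .gc_islands import IslandCall


# ---------------------------------------------------------------------------
# center-star multiple alignment


def _global_aligner(moltype: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if moltype == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -12, -1
    else:
        aligner.match_score, aligner.mismatch_score = 2, -3
        aligner.open_gap_score, aligner.extend_gap_score = -6, -2
    return aligner


def center_star_msa(seqs: dict[str, str], moltype: str = "protein") -> dict[str, str]:
    """Multiple alignment by the center-star heuristic.

    The center is the sequence maximizing summed pairwise alignment scores;
    all others are aligned to it pairwise and merged under the
    "once a gap, always a gap" rule.  Column count always reaches at least
    the longest input sequence.
    """
    if not seqs:
        raise ValueError("empty input")
    names = list(seqs)
    if len(names) == 1:
        return dict(seqs)
    aligner = _global_aligner(moltype)
    # choose the center
    totals = {n: 0.0 for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            s = aligner.score(seqs[a], seqs[b])
            totals[a] += s
            totals[b] += s
    center = max(names, key=lambda n: (totals[n], n))
    cseq = seqs[center]
    L = len(cseq)

    pair_rows: dict[str, tuple[list[str], list[int]]] = {}
    master_ins = [0] * (L + 1)  # insertion columns before center position i
    for name in names:
        if name == center:
            continue
        aln = aligner.align(cseq, seqs[name])[0]
        crow, srow = str(aln[0]), str(aln[1])
        # chars of s between consecutive center residues
        chunks: list[str] = [""]
        for cc, sc in zip(crow, srow):
            if cc == "-":
                chunks[-1] += sc
            else:
                chunks.append(sc)
        # chunks[0] = before center pos 0; chunks[i+1] starts with the char
        # aligned to center residue i followed by any insertions after it
        ins = [len(chunks[0])] + [len(c) - 1 for c in chunks[1:]]
        pair_rows[name] = (chunks, ins)
        for i in range(L + 1):
            master_ins[i] = max(master_ins[i], ins[i])

    out: dict[str, str] = {}
    for name in names:
        if name == center:
            row = "-" * master_ins[0]
            for i, ch in enumerate(cseq):
                row += ch + "-" * master_ins[i + 1]
        else:
            chunks, _ = pair_rows[name]
            row = chunks[0] + "-" * (master_ins[0] - len(chunks[0]))
            for i in range(L):
                chunk = chunks[i + 1]  # residue aligned to center pos i + insertions
                row += chunk + "-" * (master_ins[i + 1] - (len(chunk) - 1))
        out[name] = row
    width = master_ins[0] + L + sum(master_ins[1:])
    assert all(len(r) == width for r in out.values())
    return {n: out[n] for n in names}


# ---------------------------------------------------------------------------
# distances


def distance_matrix(
    msa: dict[str, str], model: str = "p"
) -> tuple[list[str], np.ndarray]:
    """Pairwise distances over jointly ungapped sites.

    models: "p" (mismatch fraction), "poisson" (-ln(1-p)), "jc_nt"
    (-(3/4) ln(1 - 4p/3)).  Saturated pairs get +inf.
    """
    names = list(msa)
    if len(names) < 2:
        raise ValueError("need at least 2 rows")
    rows = [np.frombuffer(msa[n].encode(), dtype="S1") for n in names]
    gap = np.bytes_(b"-")
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != gap) & (rows[j] != gap)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
            p = float((rows[i][ok] != rows[j][ok]).sum()) / total
            if model == "p":
                d = p
            elif model == "poisson":
                d = -log(1 - p) if p < 1 else inf
            elif model == "jc_nt":
                arg = 1 - 4 * p / 3
                d = -0.75 * log(arg) if arg > 0 else inf
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
    return names, D


# ---------------------------------------------------------------------------
# neighbor joining

class _Node:
    __slots__ = ("newick", "leaves")

    def __init__(self, newick: str, leaves: tuple[str, ...]):
        self.newick = newick
        self.leaves = leaves


def nj_tree(labels: list[str], D: np.ndarray) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking (lexicographic on the
    leaf sets of the joined nodes) and non-negative branch lengths: a
    negative estimate is clamped to zero and the deficit moved to the sister
    branch."""
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    if not np.all(np.isfinite(D)):
        raise ValueError("infinite distances: prune saturated taxa first")
    nodes = [_Node(lab, (lab,)) for lab in labels]
    D = D.astype(float).copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj, li = max(lj + li, 0.0), 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        return li, lj

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted(nodes[i].leaves)), tuple(sorted(nodes[j].leaves)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        merged = _Node(
            f"({nodes[i].newick}:{li:.10g},{nodes[j].newick}:{lj:.10g})",
            tuple(sorted(nodes[i].leaves + nodes[j].leaves)),
        )
        newD = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                newD[a, b] = D[ka, kb]
        for a, ka in enumerate(keep):
            d = (D[i, ka] + D[j, ka] - D[i, j]) / 2
            newD[a, m - 2] = newD[m - 2, a] = max(d, 0.0)
        nodes = [nodes[k] for k in keep] + [merged]
        D = newD
    # three-point termination
    (a, b, c) = nodes
    la = max((D[0, 1] + D[0, 2] - D[1, 2]) / 2, 0.0)
    lb = max((D[0, 1] + D[1, 2] - D[0, 2]) / 2, 0.0)
    lc = max((D[0, 2] + D[1, 2] - D[0, 1]) / 2, 0.0)
    newick = f"({a.newick}:{la:.10g},{b.newick}:{lb:.10g},{c.newick}:{lc:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# bipartitions, Robinson-Foulds, bootstrap


def _splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels (the
    side not containing the alphabetically first leaf)."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Symmetric-difference (Robinson-Foulds) distance and its normalization
    by 2(n-3), the maximum over fully resolved unrooted trees."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    raw = len(_splits(t1) ^ _splits(t2))
    n = len(l1)
    denom = 2 * (n - 3)
    return raw, (raw / denom if denom > 0 else 0.0)


def build_tree(msa: dict[str, str], model: str = "poisson") -> dendropy.Tree:
    labels, D = distance_matrix(msa, model)
    return nj_tree(labels, D)


def bootstrap_support(
    msa: dict[str, str],
    tree_builder=None,
    n: int = 100,
    rng: np.random.Generator | None = None,
    model: str = "poisson",
) -> dendropy.Tree:
    """Point-estimate tree with internal-node labels set to the percentage of
    column-resampled pseudo-replicates containing the same bipartition."""
    if n < 1:
        raise ValueError("need at least one pseudo-replicate")
    rng = rng if rng is not None else np.random.default_rng(0)
    builder = tree_builder or (lambda m: build_tree(m, model=model))
    tree = builder(msa)
    width = len(next(iter(msa.values())))
    counts: dict[frozenset, int] = {s: 0 for s in _splits(tree)}
    for _ in range(n):
        cols = rng.integers(0, width, size=width)
        rep = {name: "".join(row[c] for c in cols) for name, row in msa.items()}
        try:
            rep_splits = _splits(builder(rep))
        except ValueError:
            continue  # saturated replicate
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if side in counts:
            node.label = str(round(100 * counts[side] / n))
    return tree


def _node_support(node) -> int:
    try:
        return int(float(node.label))
    except (TypeError, ValueError):
        return 0


def supported_sister_set(
    tree: dendropy.Tree, focal: str, support_min: float | None
) -> frozenset:
    """Smallest set of taxa grouped with the focal leaf by a supported edge.

    Works on unrooted split semantics: over every internal edge whose support
    reaches the threshold (support_min=None accepts all edges), take the
    split side containing the focal taxon, minus the focal; return the
    smallest such set.  Falls back to all other leaves when no edge
    qualifies, which makes the incongruence test conservatively negative."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if focal not in leaves:
        raise ValueError(f"focal taxon {focal!r} absent from tree")
    best = None
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        if support_min is not None and _node_support(node) < support_min:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not 1 < len(side) < len(leaves):
            continue
        cand = (side if focal in side else leaves - side) - {focal}
        if cand and (best is None or (len(cand), sorted(cand)) < (len(best), sorted(best))):
            best = cand
    if best is None:
        best = leaves - {focal}
    return frozenset(best)


# ---------------------------------------------------------------------------
# combined evidence


@dataclass
class HgtEvidence:
    locus_id: str
    gc_signal: bool
    delta_gc: float
    context_signal: bool
    n_markers: int
    n_flank_repeats: int
    phylo_signal: bool
    rf_normalized: float
    gene_sister: tuple[str, ...]
    species_sister: tuple[str, ...]
    verdict: str  # {"supported", "partial", "none"}
    n_signals: int


def flag_hgt(
    locus_id: str,
    island: IslandCall | None,
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    focal: str,
    support_min: float = 70.0,
    gc_delta_min: float = 2.0,
) -> HgtEvidence:
    """Combine composition, context, and phylogeny into an HGT verdict.

    The species tree is pruned to the gene tree's taxa; the phylogenetic
    signal fires when the focal taxon's smallest supported sister clade in
    the gene tree shares no taxon with its species-tree sister clade."""
    gc_signal = island is not None and abs(island.delta_gc) >= gc_delta_min
    delta = island.delta_gc if island is not None else 0.0
    context_signal = island is not None and (
        len(island.mge_markers) > 0 or len(island.flank_repeats) > 0
    )
    n_markers = len(island.mge_markers) if island else 0
    n_repeats = len(island.flank_repeats) if island else 0

    gene_taxa = {lf.taxon.label for lf in gene_tree.leaf_node_iter()}
    if focal not in gene_taxa:
        raise ValueError(f"focal taxon {focal!r} absent from the gene tree")
    pruned = species_tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(gene_taxa))
    species_taxa = {lf.taxon.label for lf in pruned.leaf_node_iter()}
    if focal not in species_taxa:
        raise ValueError(f"focal taxon {focal!r} absent from the species tree")

    gene_sister = supported_sister_set(gene_tree, focal, support_min)
    species_sister = supported_sister_set(pruned, focal, None)
    phylo_signal = bool(species_sister) and gene_sister.isdisjoint(species_sister)
    if gene_taxa == species_taxa:
        rf_norm = rf_distance(gene_tree, pruned)[1]
    else:
        rf_norm = float("nan")

    n_signals = int(gc_signal) + int(context_signal) + int(bool(phylo_signal))
    verdict = "supported" if n_signals >= 2 else ("partial" if n_signals == 1 else "none")
    return HgtEvidence(
        locus_id=locus_id,
        gc_signal=gc_signal,
        delta_gc=delta,
        context_signal=context_signal,
        n_markers=n_markers,
        n_flank_repeats=n_repeats,
        phylo_signal=bool(phylo_signal),
        rf_normalized=rf_norm,
        gene_sister=tuple(sorted(gene_sister)) if gene_sister else (),
        species_sister=tuple(sorted(species_sister)),
        verdict=verdict,
        n_signals=n_signals,
    )
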