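"""Genomic-island candidates from GC anomaly, with mobile-element context.

A sliding-window scan z-scores each window's GC against the window
population of the same genome; maximal runs of strongly GC-depleted windows
(default z <= -3) that span at least `min_len` after gap merging become
island calls.  Calls are then annotated with mobile-genetic-element context:
genes near or inside the island whose product matches a keyword lexicon
(integrase, transposase, phage, ...), and exact direct repeats flanking the
island, both classic signatures of horizontally acquired regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneFeature, Genome, gc_percent
from .synthetic_clade import MGE_KEYWORDS


@dataclass
class WindowScan:
    genome_id: str
    window_bp: int
    step_bp: int
    contig_ids: list[str]
    starts: dict[str, np.ndarray]  # per contig
    gc: dict[str, np.ndarray]  # percent
    z: dict[str, np.ndarray]
    mean_gc: float
    sd_gc: float


@dataclass
class IslandCall:
    contig_id: str
    start: int
    end: int
    mean_gc: float  # recomputed over the exact island span, percent
    genome_gc: float
    z_min: float
    mge_markers: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, keyword)
    flank_repeats: list[tuple[int, int, int]] = field(default_factory=list)  # (left, right, len)
    contained_genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def delta_gc(self) -> float:
        return self.mean_gc - self.genome_gc


def window_scan(g: Genome, window: int = 5000, step: int = 500) -> WindowScan:
    """Per-window GC and z-score; contigs shorter than the window are
    skipped.  A compositionally uniform genome (scale = 0) yields all-zero z.

    The center and scale of the z-score are robust (median and
    MAD-derived sigma) so that large anomalous islands do not mask
    themselves by inflating the genome-wide spread."""
    starts, gcs = {}, {}
    for contig in g.contigs:
        if len(contig.seq) < window:
            continue
        st = np.arange(0, len(contig.seq) - window + 1, step)
        vals = np.array(
            [gc_percent(contig.seq[s : s + window]) for s in st]
        )
        starts[contig.id] = st
        gcs[contig.id] = vals
    if not starts:
        raise ValueError(f"{g.strain_id}: no contig reaches the window size")
    allv = np.concatenate(list(gcs.values()))
    # two-pass robust scale: MAD flags outlying (island) windows, then the
    # more efficient moment statistics are taken over the clean windows;
    # 1.003 corrects the slight variance loss from truncating at |z| <= 3.5
    mu = float(np.median(allv))
    sd = float(1.4826 * np.median(np.abs(allv - mu)))
    if sd > 0:
        clean = allv[np.abs(allv - mu) <= 3.5 * sd]
        if clean.size >= 10:
            mu = float(clean.mean())
            sd = float(clean.std()) * 1.003
    if sd == 0:
        sd = float(allv.std())
    # overlapping windows leave few independent samples, so the window-level
    # scale estimate is noisy; floor it with the scale implied by the many
    # non-overlapping step-sized tiles (sd_window = sd_tile * sqrt(step/window)
    # for sequence without long-range structure).  Structured genomes exceed
    # the floor and keep their window-level estimate.
    tiles = []
    for contig in g.contigs:
        if len(contig.seq) < window:
            continue
        tiles.extend(
            gc_percent(contig.seq[s : s + step])
            for s in range(0, len(contig.seq) - step + 1, step)
        )
    tiles = np.asarray(tiles)
    if tiles.size >= 30:
        tmu = float(np.median(tiles))
        tsd = float(1.4826 * np.median(np.abs(tiles - tmu)))
        if tsd > 0:
            tclean = tiles[np.abs(tiles - tmu) <= 3.5 * tsd]
            if tclean.size >= 30:
                tsd = float(tclean.std()) * 1.003
            sd = max(sd, tsd * (step / window) ** 0.5)
    z = {
        cid: (v - mu) / sd if sd > 0 else np.zeros_like(v) for cid, v in gcs.items()
    }
    return WindowScan(
        genome_id=g.strain_id,
        window_bp=window,
        step_bp=step,
        contig_ids=list(starts),
        starts=starts,
        gc=gcs,
        z=z,
        mean_gc=mu,
        sd_gc=sd,
    )


def call_islands(
    g: Genome,
    scan: WindowScan,
    z_cut: float = -3.0,
    min_len: int = 8000,
    merge_gap: int | None = None,
    mode: str = "low",
) -> list[IslandCall]:
    """Maximal runs of anomalous windows, merged across short gaps, kept if
    the merged span reaches min_len.  mode="low" keeps GC-depleted islands
    (z <= z_cut); mode="abs" calls both tails on |z|."""
    if mode == "low" and z_cut >= 0:
        raise ValueError("z_cut must be negative in low-GC mode")
    if merge_gap is None:
        merge_gap = 2 * scan.step_bp
    cmap = g.contig_map()
    calls = []
    for cid in scan.contig_ids:
        starts, z = scan.starts[cid], scan.z[cid]
        flag = z <= z_cut if mode == "low" else np.abs(z) >= abs(z_cut)
        spans = []
        for i in np.nonzero(flag)[0]:
            s, e = int(starts[i]), int(starts[i]) + scan.window_bp
            if spans and s - spans[-1][1] <= merge_gap:
                spans[-1][1] = e
                spans[-1][2] = min(spans[-1][2], float(z[i]))
            else:
                spans.append([s, e, float(z[i])])
        for s, e, zmin in spans:
            if e - s < min_len:
                continue
            s, e = _refine_boundaries(cmap[cid].seq, s, e, scan, mode)
            if e - s < min_len:  # refinement exposed a sub-threshold span
                continue
            seq = cmap[cid].seq[s:e]
            calls.append(
                IslandCall(
                    contig_id=cid,
                    start=s,
                    end=e,
                    mean_gc=gc_percent(seq),
                    genome_gc=scan.mean_gc,
                    z_min=zmin,
                )
            )
    return calls


def _refine_boundaries(seq: str, s: int, e: int, scan: WindowScan, mode: str):
    """Sharpen window-resolution boundaries to step resolution.

    The candidate span is extended by one window on both sides and trimmed
    inward tile by tile (tile = step) while the tile GC still looks like
    genome background, using the midpoint between the island's interior GC
    and the genome center as the decision line.  Only applied in low-GC
    mode; |z| mode keeps window-resolution boundaries."""
    if mode != "low":
        return s, e
    # interior GC from the central half of the candidate, which is least
    # diluted by background sequence at the edges
    quarter = (e - s) // 4
    interior = gc_percent(seq[s + quarter : e - quarter])
    threshold = (interior + scan.mean_gc) / 2
    step = scan.step_bp
    look = max(step, 2000)  # lookahead long enough to average out tile noise
    lo = max(0, s - scan.window_bp)
    hi = min(len(seq), e + scan.window_bp)
    # stop trimming only when both the immediate tile and the lookahead mean
    # look island-like: the tile pins the boundary to step resolution, the
    # lookahead guards against single-tile noise
    while lo + look <= hi and (
        gc_percent(seq[lo : lo + step]) > threshold
        or gc_percent(seq[lo : lo + look]) > threshold
    ):
        lo += step
    while hi - look >= lo and (
        gc_percent(seq[hi - step : hi]) > threshold
        or gc_percent(seq[hi - look : hi]) > threshold
    ):
        hi -= step
    return (lo, hi) if hi - lo >= step else (s, e)


def annotate_mge_context(
    island: IslandCall,
    features: list[GeneFeature],
    lexicon: tuple[str, ...] = MGE_KEYWORDS,
    margin: int = 5000,
) -> IslandCall:
    """Record genes overlapping the island (or within `margin` of it) whose
    product matches the keyword lexicon; bare "IS" matches only on word
    boundaries so that e.g. "isomerase" is not flagged."""
    lo, hi = island.start - margin, island.end + margin
    for f in features:
        if f.contig_id != island.contig_id or f.end <= lo or f.start >= hi:
            continue
        if island.start <= f.start and f.end <= island.end:
            island.contained_genes.append(f.gene_id)
        product = f.product.lower()
        for kw in lexicon:
            if kw == "IS":
                if re.search(r"\bIS\d*\b", f.product):
                    island.mge_markers.append((f.gene_id, kw))
                    break
            elif kw.lower() in product:
                island.mge_markers.append((f.gene_id, kw))
                break
    return island


def find_flank_repeats(
    g: Genome, island: IslandCall, min_len: int = 15, margin: int = 2000
) -> list[tuple[int, int, int]]:
    """Exact maximal direct repeats with one copy wholly inside the left
    margin and one wholly inside the right margin of the island."""
    seq = g.contig_map()[island.contig_id].seq
    left = seq[max(0, island.start - margin) : island.start]
    right = seq[island.end : island.end + margin]
    left_off = max(0, island.start - margin)
    seeds: dict[str, list[int]] = {}
    for i in range(len(left) - min_len + 1):
        seeds.setdefault(left[i : i + min_len], []).append(i)
    found = []
    for j in range(len(right) - min_len + 1):
        for i in seeds.get(right[j : j + min_len], ()):
            length = min_len
            while (
                i + length < len(left)
                and j + length < len(right)
                and left[i + length] == right[j + length]
            ):
                length += 1
            found.append((left_off + i, island.end + j, length))
    # keep maximal repeats only: drop pairs contained in a longer one
    found.sort(key=lambda t: -t[2])
    maximal = []
    for lpos, rpos, length in found:
        if any(
            ml <= lpos and lpos + length <= ml + mlen and mr <= rpos and rpos + length <= mr + mlen
            for ml, mr, mlen in maximal
        ):
            continue
        maximal.append((lpos, rpos, length))
    maximal.sort()
    island.flank_repeats = maximal
    return maximal


def scan_and_call(
    g: Genome,
    window: int = 5000,
    step: int = 500,
    z_cut: float = -3.0,
    min_len: int = 8000,
    repeat_min_len: int = 15,
    margin: int = 5000,
) -> list[IslandCall]:
    """Full island pipeline for one genome: scan, call, annotate."""
    scan = window_scan(g, window, step)
    calls = call_islands(g, scan, z_cut, min_len)
    for call in calls:
        annotate_mge_context(call, g.features, margin=margin)
        find_flank_repeats(g, call, min_len=repeat_min_len)
    return calls
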