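# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want written down.

## Genome model and formats

Contigs and coding features use 0-based half-open coordinates everywhere
inside the package; GFF3 (1-based inclusive) is converted at the read/write
boundary. GC content is computed over called bases only (N excluded from
numerator and denominator), matching how draft-assembly GC is reported. N50
is the contig length at which the descending cumulative length first reaches
half the assembly, ties resolved to the larger contig. Proteins may be
supplied in a `.faa` or derived by translating the feature span with the
bacterial genetic code (table 11), with alternative starts (GTG/TTG)
rendered as M.

## Synthetic clades

A clade is generated from one ancestor: ORFs (ATG start, stop-free interior,
one stop) separated by 50–500-bp spacers, with codon composition solved by
bisection so the realized GC matches the configured background (stop-codon
rejection enriches GC, so the per-base probability is corrected downward).
Each strain descends along its own branch of a star phylogeny under an
equal-rates (Jukes–Cantor-style) substitution model applied i.i.d. per site.
Substitutions that would create a premature stop are redirected to a
different base at the same site, so the realized substitution rate equals
the nominal rate while ORFs stay translatable; an earlier version that
reverted such codons biased measured ANI upward by ~0.05 points. Gene loss
excises the gene with its spacer; gains insert fresh ORFs at random
intergenic points; gene order is otherwise preserved, so synteny is
conserved by construction. No indels, recombination or rearrangements are
simulated — expected pairwise identity stays analytically computable:

p = 1/4 + 3/4 · (1 − 4·rₐ/3)(1 − 4·r_b/3)

for branch substitution probabilities rₐ, r_b. The default three-strain
clade inverts this formula to solve branch rates from the observed ANI
triplet (99.37 / 98.93 / 98.88 %), which three pairwise values determine
exactly on a three-taxon star. Defaults: 290 core families, 30 two-strain
shared (14 + 8 + 8), 12/11/9 strain-specific genes, 300 ± 60 bp genes,
background GC 37.97 % — a 1/10-scale analogue of the modeled strains. The
ANI-calibration configuration instead uses 1,000 genes of 900 ± 150 bp
(~1 Mb per genome) so the sampling error of mean fragment identity is far
below 0.1 points.

Islands are planted as a block of marker ORFs (products drawn from the MGE
keyword lexicon), cargo ORFs, and spacer fill, all at the island GC, with
optional exact direct repeats at both ends. Island spacers use
exact-composition sampling (fixed GC base count, shuffled) so a planted
island realizes its nominal GC without sampling noise; background and null
genomes stay i.i.d. because their window-to-window variance is exactly what
the island scan's null hypothesis describes. The default island models the
observed low-GC island: 25 kb at GC 31.68 % inside a 37.97 % genome, two
IS/integrase marker genes, 20-bp flanking repeats, Kdo-biosynthesis-style
cargo.

What the generator does not emulate: real intergenic structure (promoters,
RNAs), codon usage beyond GC, indels, rearrangements, assembly
fragmentation/contamination, or paralogy beyond what gain/loss induces.
Passing the recovery tests therefore demonstrates correctness of the
implementations under the stated models, not robustness to assembly noise
or deep divergence.

## Orthology and pangenome

Pairwise protein comparison is optimal local alignment (Biopython
PairwiseAligner) under BLOSUM62 with affine gaps (open 11, extend 1; a
length-L gap costs 11 + L). Bit scores use fixed gapped-BLOSUM62
Karlin–Altschul constants (λ = 0.267, K = 0.041) and
E = m·n·2^(−bitscore); the E-value here is a filter, not a calibrated
statistic. `best_hits` prefilters candidate subjects by shared amino-acid
4-mers (≥ 3 shared) before exact rescoring — a seed-and-extend heuristic;
pairs it skips could not pass the 10⁻⁶ cut at these proteome sizes, and
`min_shared_kmers=0` disables it. BBH requires reciprocal best hits, E ≤
10⁻⁶ both ways, and min(query, subject coverage) ≥ 0.60 in both directions
(the strictest reading of "mutual coverage of 60 %"). Families are
connected components of the union BBH graph (single-linkage chaining
accepted); if a component holds several genes of one strain, the gene with
the highest summed bitscore to the component keeps the seat and the rest
become singletons. Categories: core = all strains, specific = one strain,
shared otherwise. The reported core fraction divides the core count by the
mean per-strain CDS count and rounds to integer percent.

Synteny conservation between two genomes is the fraction of adjacent
core-gene pairs (per contig) in one genome whose family images are adjacent
in either orientation in the other.

## ANI

Fragment-mapping ANI: non-overlapping 1,020-nt fragments per contig
(trailing remainder discarded, keeping per-fragment statistics identically
distributed); each fragment is seeded onto the subject by exact 16-mers
sampled every 64 bp on both orientations, the most-voted candidate window is
aligned with edlib in glocal mode, and the best local block within that
alignment is extracted from the CIGAR by a maximum-scoring-interval pass
(match +1, mismatch −1, gap −2 per column). Identity = matches / aligned
columns (gap columns included — the conservative denominator). Retention
requires identity ≥ 0.30 over ≥ 0.70 of the fragment length, so fragments
overhanging deletions or non-homologous sequence drop out. Directed ANI is
the mean retained identity × 100; the symmetric ANI averages both
directions and is reported by default (both directions are retained in the
result object). When nothing is retained the ANI is undefined (NaN), never
zero.

## Genomic islands

Windows of 5 kb every 500 bp are z-scored against the window population of
the same genome using a robust center and scale: at desk scale a 25-kb
island is over a tenth of the genome and would mask itself under moment
statistics by inflating the standard deviation. The scale is estimated in
two passes (MAD flags outlying windows, then the more efficient moment
statistics are taken over the clean windows) and floored by the scale
implied by the non-overlapping step-sized tiles, rescaled by
√(step/window): overlapping windows leave only ~genome/window independent
samples, so the window-level estimate alone wobbles by ~15 % and its
downward excursions produce spurious calls, while the tiles are numerous
and independent. Genomes with real long-range composition structure exceed
the floor and keep their window-level scale. Maximal runs of windows with
z ≤ −3, merged across gaps ≤ 2 steps, are kept if they span ≥ 8 kb (the
length test is repeated after boundary refinement). Boundaries are then refined from window to step resolution:
the candidate is extended by one window on each side and trimmed inward
tile by tile (tile = step) while both the immediate tile and a 2-kb
lookahead mean still look like background, using the midpoint between the
island's central-half GC and the genome center as the decision line. The
tile pins the boundary; the lookahead guards against single-tile noise. On
the planted default island this places boundaries within ~1 kb of truth and
the recomputed island GC within ~0.2 points of the planted value. On
i.i.d. null genomes of 100 kb the false-call rate at default thresholds is
about 0.1 % per genome (measured over 2,000 nulls) — the irreducible rate
of genuine ~−3σ GC excursions spanning 8 kb — so a batch of 100 nulls
almost always yields zero calls.

MGE context: genes overlapping the island or within 5 kb whose product
matches the keyword lexicon (integrase, transposase, insertion sequence,
phage, recombinase; bare "IS" only on word boundaries so "isomerase" never
matches). Flanking repeats: exact maximal direct repeats ≥ 15 bp with one
copy wholly inside each 2-kb margin; at GC 0.38 the chance collision rate
is ~0.01 per island, so any hit is informative. Because both copies must
lie wholly in the margins, repeat detection expects boundaries near truth;
with scan-derived boundaries (±1 kb) a planted repeat can fall just inside
the call and be missed — context evidence then rests on the markers, which
is why the HGT context signal accepts either.

## Gene trees and HGT verdicts

Multiple alignment is center-star (center = maximal summed pairwise global
score, "once a gap, always a gap" merging) — adequate for the well-conserved
families scanned here. Distances: p-distance over jointly ungapped sites,
Poisson correction −ln(1−p) for proteins, or Jukes–Cantor for nucleotides;
saturated pairs (argument ≤ 0) become +∞ and must be pruned before tree
building. Neighbor joining is implemented with deterministic tie-breaking
(lexicographic on the joined leaf sets) and non-negative branch lengths
(negative estimates clamped to zero, deficit moved to the sister branch);
on additive matrices it reproduces the generating topology and branch
lengths exactly. Nodal support is the percentage of 100 column-resampled
pseudo-replicates containing the same bipartition. Robinson–Foulds distance
counts symmetric-difference bipartitions and normalizes by 2(n−3).

A locus's HGT evidence combines three booleans: composition (island call
with |ΔGC| ≥ 2 points — well below the ~6-point effect modeled, well above
window noise), context (≥ 1 MGE marker or flanking repeat pair), and
phylogeny. The phylogenetic signal works on unrooted split semantics: among
the gene tree's internal edges with support ≥ 70 (the display threshold the
field's figures use), take the split side containing the focal taxon, minus
the focal; the smallest such set is the focal's supported sister set, and
the signal fires when it shares no taxon with the focal's species-tree
sister set. When no edge is supported the sister set falls back to all
other taxa, making the test conservatively negative. Verdict: supported
(≥ 2 signals), partial (1), none (0). The 70 threshold and the 2-point ΔGC
floor are configurable; they are reporting conventions, not estimated
quantities.

## Profile search

Profiles are per-column log-odds matrices in bits,
score(a) = log₂((countₐ + pc·bgₐ)/(n + pc)/bgₐ), built from seed alignments
after dropping columns with ≥ 50 % gaps; background is uniform (1/20) or
seed-derived; pseudocount weight 1 by default. Scanning slides the profile
ungapped along the protein; the default is glocal (terminal truncation
allowed, overhanging columns score 0) so that proteins shorter than the
profile get a well-behaved best score — forcing full-width placements makes
the decoy null's variance explode with length heterogeneity and destroys
the calibration. E-values come from a Gumbel fitted by moment matching
(β = s·√6/π, μ = mean − γβ) to the best scores of ≥ 100
composition-preserving per-protein shuffles drawn from the target proteome;
E(s) = N·(1 − exp(−exp(−(s−μ)/β))). This is a presence/absence detector
for conserved families, not a full profile HMM: no insert/delete states, no
forward-algorithm scores, and no parity with HMMER E-values is claimed.
Seed alignments for synthetic families are generated as the planted protein
plus mutated homologs; real families should use curated seed alignments.

## Trait concordance

Trait tables are strain × trait matrices over {+, −, NA}; rows with other
symbol sets (the 3-level alkaline-phosphatase regulation states
Constitutive / Induce / −) are carried but excluded from binary analyses.
The packaged fixtures transcribe the published auxotrophy, phosphorus-source
and phosphorus-strategy tables; footnote marks live in a note column and do
not affect symbols. The published table's printed auxotrophy total for
p1.1.43 is 7 while the running text and the column's "−" entries give 8;
the summarizer counts cells (8) and the printed total is preserved in the
fixture metadata. Pathway predictions are monotone set-cover rules: a trait
is predicted "+" iff any alternative requirement set of gene families is
fully present. Concordance compares observed and predicted cell by cell
over shared strain/trait names, excluding NA, and lists every inconsistency.

## Pipeline and reproducibility

`pipeline.run_all` chains simulate/ingest → pangenome → ANI → islands → HGT
→ repertoire → traits, writing TSV/BED/JSON reports with fixed names. All
randomness flows from one root seed through named substreams
(`numpy.random.SeedSequence.spawn`), so identical seed + configuration give
byte-identical reports; any stage failure aborts with the stage name.

## Problem sizes

The test suite and the acceptance script run at desk scale: ~200-kb
three-strain clades (~320 genes each) for pangenome/island/HGT checks,
~1-Mb clades for ANI calibration, 100 × 100-kb null genomes for island
specificity, 200-residue families over 8 taxa with 100 bootstrap replicates
for phylogenetics. These sizes keep every expected effect far larger than
its sampling error (e.g. ANI sampling error < 0.02 points at 1 Mb) while
the full suite completes in about a minute.

## Known limitations

* BBH orthology at these divergences is essentially exact; the package does
  not attempt Markov clustering or tree-aware orthology and will chain
  fast-evolving paralogs at larger divergences.
* The island scan is composition-only (GC); codon-usage or k-mer scores and
  CRISPR/prophage classification are out of scope.
* Center-star + NJ is adequate for the conserved families simulated here
  but is not a replacement for ML inference on hard alignments.
* E-value calibration is per-proteome and composition-matched but ungapped;
  scores are not comparable across profiles of different lengths.
* The fragment-ANI dialect (identity denominator includes gap columns;
  best-local-block trimming) can differ from other implementations by a few
  hundredths of a point; the calibration tolerance absorbs this.
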