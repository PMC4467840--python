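# Methods

## Coordinates and domain objects

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the I/O boundary only. "Antisense" means
opposite strand symbols with ≥ 1 bp of genomic overlap; unstranded features
are never antisense partners. A `TranscriptModel` is an ordered chain of
disjoint exons on one chromosome and strand; a `NatRecord` carries one
cis-NAT, its topology call, its OLP/NOLP decomposition and the per-stage
boolean flags. OLP ∪ NOLP always tiles the NAT's exonic footprint exactly
(asserted as an invariant).

## Topology classification

Five geometries of a NAT against its antisense gene(s), decided on
transcript spans (not exon chains) and assigned with precedence 5, 3, 4, 1, 2:

| Type | geometry |
|------|----------|
| 5 | the NAT opposes ≥ 2 distinct genes |
| 3 | NAT span ⊆ gene span |
| 4 | gene span ⊂ NAT span |
| 1 | partial overlap, the 5′ terminus of each transcript lies inside the other (head-to-head, divergent transcription) |
| 2 | partial overlap, the 3′ termini overlap (tail-to-tail, convergent) |

For two opposite-strand transcripts in partial overlap exactly one of the
Type-1/Type-2 conditions holds, so classification is total and unique. The
decomposition into OLP/NOLP subtracts protein-coding **exon chains** by
default (`mode="exon"`, so intronic stretches under the overlap count as
NOLP); `mode="transcript_span"` subtracts whole gene spans instead. Type-3
NATs are excluded from all conservation analyses — under span subtraction
they have no NOLP at all.

The non-redundant (NR) set is built greedily: records sorted by decreasing
total NOLP length (ties broken lexicographically by id for determinism); a
record is kept iff none of its NOLP intervals overlaps (≥ 1 bp, either
strand) a NOLP of an already-kept record. The output is overlap-free and
the procedure is idempotent. Cross-set validation of one NAT catalogue
against others uses ≥ 1 bp same-strand genomic overlap (the most permissive
rule; configurable).

## Scale likelihood-ratio test

The neutral model is a rooted tree with branch lengths in expected
substitutions/site plus a reversible rate matrix Q and equilibrium
frequencies π, normalised on construction so the mean equilibrium
substitution rate is 1 (−Σ πᵢqᵢᵢ = 1). Transition matrices P(t) = e^{Qt}
come from the π-symmetrised eigendecomposition (real spectrum, computed
once and cached). Column likelihoods use Felsenstein pruning vectorised
over pattern-compressed columns; gaps, Ns and species absent from the
alignment are missing data (partial-likelihood vector of ones), not a
fifth state.

Per NOLP interval, alignment columns are stitched from the MAF blocks
overlapping it (species missing from a block contribute missing data). One
scale ρ multiplies every branch; lnL(ρ) is maximised by bounded Brent
search on ρ ∈ [10⁻³, 10] with tolerance 10⁻⁶. D = 2(lnL(ρ̂) − lnL(1)) is
referred to the upper tail of χ² with 1 df (two-sided in ρ; the direction —
conserved ρ̂ < 1, accelerated ρ̂ > 1 — is reported separately), and a NAT is
called conserved when any of its NOLP intervals has p < α = 0.05 with
ρ̂ < 1; the count of individually significant intervals is also reported,
since multi-interval NOLPs can carry two conserved regions. Columns with
fewer than 2 non-missing species are skipped and loci with fewer than 10
usable columns are flagged untestable rather than scored. If the optimiser
cannot beat the null (|D| below tolerance), the locus is clamped to
ρ̂ = 1, D = 0. Holm–Bonferroni (step-down running maximum of
(m − j + 1)·p₍ⱼ₎, capped at 1) is applied across all interval tests of a
run; both raw and adjusted calls are kept.

Testing is per NOLP interval, not per NAT pooled and not sliding-window:
that is the unit the decomposition defines, and it is what lets one NAT
exhibit several independently conserved regions.

## Local alignment and sister-genome calls

Smith–Waterman with affine gaps (gap of length L costs open + L·extend) is
implemented with a row-vectorised DP; horizontal-gap scores within a row
are resolved by a prefix-max scan, which is exact because re-opening a gap
never beats extending one. Traceback ties prefer diagonal, then up, then
left. E-values use the Karlin–Altschul form E = K·m·n·e^{−λS} with
documented calibration defaults: nucleotide +2/−3, open 5 / extend 2,
K = 0.41, λ = 0.625 (ungapped BLASTN-like constants); protein BLOSUM62,
open 11 / extend 1, K = 0.041, λ = 0.267. These are configurable and
recorded in output metadata; gapped λ estimation is out of scope.

The transcript-to-genome mapper seeds with exact 11-mers on both strands,
clusters seeds by diagonal (band 40), extends the best-seeded clusters with
Smith–Waterman, and accepts a locus at identity ≥ 0.90 over ≥ 0.50 of the
query (declared defaults; the thresholds of the original mapping tools are
not published). Clusters with fewer than a fifth of the best cluster's
seeds are pruned, and extension stops once a hit explains ≥ 90% of the
query — a deliberate best-locus bias matching how the mapping is used here.

Orthologs are bi-directional best hits on protein scores; ties disqualify.
*Sequence conserved in the sister genome*: best nucleotide hit of the NOLP
(both orientations) within a symmetric 5-kb flank of the orthologous gene
has e < 10⁻¹⁰. *Expression conserved*: the NAT maps into the sister
genome, and some transcript-evidence interval there overlaps the mapped
locus antisense to the orthologous gene, has no ORF > 100 codons on its
sense strand (ORF = ATG to in-frame stop, length excluding the stop,
N-containing codons never start or stop), and has no sense-direction
protein hit at e ≤ 10⁻⁴. Failure reasons (no ortholog, unmapped, no
qualifying evidence) are recorded.

## Matched resampling null

Each observed NOLP is described by (length, side, distance): the side
(upstream/downstream, strand-aware) and distance from its gene-proximal
edge to the span boundary of its nearest gene. A replicate re-places every
NOLP at a uniformly chosen *different* gene at the same side and distance,
rejecting draws that overlap any annotated transcript or leave the
chromosome (≤ 1000 attempts, then a hard error naming the interval).
Matching is exact per NOLP rather than distribution-level (stricter; a
distribution-level reading of "same distribution of lengths and positions"
would also be defensible, and per-interval matching implies it). Replicate
seeds derive from the master seed by a counter. The observed statistic is
compared to the replicate mean and sd by a normal tail probability;
zero-variance nulls are flagged degenerate and resolved by direct
comparison. Because lengths are matched exactly, any per-bp statistic is
degenerate by construction — the intended use is count statistics (peaks,
conserved intervals, siRNA hits).

## Hypergeometric tests and siRNA handling

Association of two boolean flags over a NAT universe is tested exactly:
N = universe, K = Σa, n = Σb, k = Σ(a∧b); enrichment p = P(X ≥ k),
depletion p = P(X ≤ k), summed from log-binomial terms (log-space, exact to
floating point; verified against both literal sample enumeration for tiny N
and an independent library implementation). For peak enrichment the
universe is NAT-level (NATs with ≥ 1 peak among conserved NATs), a choice
recorded in the output because a peak-level universe is also arguable.

siRNA reads (18–30 nt, ACGT only; others skipped and counted) are collapsed
to non-redundant sequences, then matched exactly (configurable 0–3
mismatches) against the combined reference of protein-coding transcripts
and NAT regions. A read is *unique* iff it has exactly one
(reference, offset) forward-orientation match; unique NAT hits get a
NOLP/OLP compartment by match midpoint and are *trans*-acting iff the read
also matches in reverse orientation on a transcribed region of another
locus — a reverse match onto the NAT's own sense gene is the definition of
cis and never triggers the trans label.

## Synthetic worlds

The generator is a pure function of (config, seed); identical inputs give
byte-identical files. Defaults describe a small plant-like setting:

* 9-leaf tree of total depth ≈ 0.5 substitutions/site (a crucifer-family
  range), HKY (κ = 2) as the reversible model, background
  π = (0.32, 0.18, 0.18, 0.32);
* genes with implanted random CDSs (ATG + stop-free codons + TAA) at
  1.4–2.6 kb gaps; NATs realised per requested topology by direct geometry,
  so intended types are exact ground truth;
* conserved loci (default 30%) evolve at scale 0.3, the rest at 1.0; the
  whole-genome alignment is conditioned on the focal row equalling the
  genome sequence by evolving outward from the focal leaf — exact under
  reversibility when the anchor sequence is drawn from π, which the
  generated genome is;
* siRNA reads 21–24 nt drawn from OLP vs NOLP at 9:1 plus 10% background;
  peaks 60% in 300-bp promoter windows; transposons placed in NOLPs with
  conservation-dependent probability (0.05 vs 0.4) plus intergenic
  background;
* the sister genome evolves at 0.10 substitutions/site (a close-congener
  distance that keeps pairwise e-value calls well inside their operating
  range); CDS codons that would become stops are kept intact so orthologous
  proteins stay full-length; antisense transcript evidence is retained at
  NAT loci with probability q (default 0.3), optionally coupled to the
  conservation label through an odds ratio, with the two per-class
  probabilities solved so the overall retention stays at q.

What the generator does **not** emulate: indels in the alignment (columns
are substitution-only), rearrangements between focal and sister genomes
(they are colinear), intron-containing NATs by default, GC/repeat structure,
or expression-level noise. Passing tests therefore demonstrate correctness
of the algorithms under the stated model, not robustness to alignment error
or annotation noise in real data.

## Problem sizes and design choices in the checks

The calibration checks use 1000 neutral loci (type-I error within
[0.03, 0.07] at p < 0.05) and 200 loci per scale (median ρ̂ within 20% of
truth; ≥ 80% of scale-0.3 loci called conserved), each locus 9 taxa × 200
columns. Topology recovery uses a 100-NAT world covering all five types.
The end-to-end association check uses worlds with 30% conserved NOLPs and
30% expression retention: one 150-NAT world generated with a
conservation–expression odds ratio of 6 must be flagged (p < 0.05), and
100 independently generated 24-NAT worlds must yield approximately uniform
p-values — assessed on the mid-p transform, the standard uniformity check
for a discrete exact test, whose raw p-values are conservative by
construction. In these loops conservation flags always come from the real
scale-LRT path and expression flags from the real mapping/evidence path;
the sister-proteome homology exclusion is switched off there (it is
exercised by its own unit tests) to keep the loops lean.

## Numerical notes and limitations

* Zero-probability columns (e.g. differing bases on a zero-length tree)
  are guarded at log(1e-300) rather than −∞; eigendecomposition round-off
  makes "impossible" likelihoods astronomically small but finite.
* Fixed-precision model files are re-balanced on read by absorbing row-sum
  round-off into the rate-matrix diagonal; genuine violations still raise.
* The χ²₁ reference for D is asymptotic; at very short loci the test is
  conservative, which the calibration bounds absorb.
* `hypergeom_p` is exact but the mid-p uniformity of small-universe
  association tests is a property of the transform, not of the raw p.
* The mapper is exact-seed based: queries diverged far beyond ~15% identity
  or split by rearrangement will not map, and the best-locus bias makes it
  unsuitable for paralog discovery.
* BDBH on whole proteomes is quadratic in proteome size; it is meant for
  the reduced proteomes of these analyses, not genome-scale catalogues.
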