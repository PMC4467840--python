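"""Matched resampling null: random samples of near-gene, NOLP-like DNA.

Each replicate draws, for every observed NOLP, an interval of the same
length placed at the same (side, distance) relative to a uniformly chosen
*different* gene, rejected until it overlaps no gene transcript and stays on
the chromosome. The observed statistic is then compared to the replicate
distribution with normal statistics (z-score tail probability), exactly the
comparison the matched-sample design supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .intervals import GenomicInterval, TranscriptModel, overlap_bp

MAX_ATTEMPTS = 1000


@dataclass
class NullSampleSet:
    replicate_index: int
    intervals: list[GenomicInterval]
    seed: int


@dataclass
class _Anchor:
    """Observed NOLP described relative to its nearest gene."""

    length: int
    side: str       # 'upstream' | 'downstream' (strand-aware wrt the gene)
    distance: int   # gene-proximal NOLP edge to gene span boundary, >= 0
    nearest_gene: str


def _describe_nolp(nolp: GenomicInterval, genes: list[TranscriptModel]) -> _Anchor:
    best = None
    for g in genes:
        span = g.span
        if g.chrom != nolp.chrom:
            continue
        if span.start >= nolp.end:            # gene to the right
            dist, left_of_gene = span.start - nolp.end, True
        elif span.end <= nolp.start:          # gene to the left
            dist, left_of_gene = nolp.start - span.end, False
        else:                                 # overlapping the span (intronic NOLP)
            dist, left_of_gene = 0, nolp.start <= span.start
        if best is None or dist < best[0]:
            best = (dist, left_of_gene, g)
    if best is None:
        raise ValueError(f"no gene on {nolp.chrom} to anchor NOLP {nolp}")
    dist, left_of_gene, g = best
    if left_of_gene:
        side = "upstream" if g.strand == "+" else "downstream"
    else:
        side = "downstream" if g.strand == "+" else "upstream"
    return _Anchor(len(nolp), side, dist, g.id)


def _place(anchor: _Anchor, gene: TranscriptModel, chrom_len: int) -> GenomicInterval | None:
    span = gene.span
    left_of_gene = (anchor.side == "upstream") == (gene.strand == "+")
    if left_of_gene:
        end = span.start - anchor.distance
        start = end - anchor.length
    else:
        start = span.end + anchor.distance
        end = start + anchor.length
    if start < 0 or end > chrom_len or start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end)


def sample_matched_set(
    observed_nolps: Sequence[GenomicInterval],
    annotation: Sequence[TranscriptModel],
    genome_extent: dict[str, int],
    seed: int,
    replicate_index: int = 0,
) -> NullSampleSet:
    """One replicate of near-gene NOLP-like intervals matched per observed
    NOLP on (length, side, distance-to-nearest-gene).

    Raises if any NOLP cannot be placed within ``MAX_ATTEMPTS`` redraws.
    """
    genes = [t for t in annotation if t.biotype == "protein_coding"]
    if not genes:
        raise ValueError("annotation contains no protein-coding genes")
    rng = np.random.default_rng(seed)
    spans = [g.span for g in annotation]
    out: list[GenomicInterval] = []
    for nolp in observed_nolps:
        anchor = _describe_nolp(nolp, genes)
        placed = None
        for _ in range(MAX_ATTEMPTS):
            gene = genes[rng.integers(len(genes))]
            if gene.id == anchor.nearest_gene:
                continue
            cand = _place(anchor, gene, genome_extent[gene.chrom])
            if cand is None:
                continue
            if any(overlap_bp(cand, s) > 0 for s in spans):
                continue
            placed = cand
            break
        if placed is None:
            raise RuntimeError(
                f"could not place a matched interval for NOLP {nolp} "
                f"after {MAX_ATTEMPTS} attempts"
            )
        out.append(placed)
    return NullSampleSet(replicate_index, out, seed)


def null_distribution(
    statistic: Callable[[list[GenomicInterval]], float],
    annotation: Sequence[TranscriptModel],
    observed_nolps: Sequence[GenomicInterval],
    genome_extent: dict[str, int],
    n_replicates: int = 500,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Evaluate ``statistic`` on ``n_replicates`` matched null sets.

    Replicate seeds are derived from the master seed by a counter, so the
    whole distribution is reproducible from one integer. Returns
    ``(mean, sd, values)``.
    """
    values = np.empty(n_replicates)
    for r in range(n_replicates):
        rep = sample_matched_set(
            observed_nolps, annotation, genome_extent, seed=seed + r, replicate_index=r
        )
        values[r] = statistic(rep.intervals)
    return float(values.mean()), float(values.std(ddof=1)), values


def normal_empirical_p(
    observed: float, null_mean: float, null_sd: float, tail: str = "lower"
) -> tuple[float, bool]:
    """Normal-statistics tail probability of the observed value against the
    replicate distribution; returns ``(p, degenerate)`` where degenerate
    flags a zero-variance null."""
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if null_sd == 0:
        if tail == "lower":
            return (0.0 if observed < null_mean else 1.0), True
        return (0.0 if observed > null_mean else 1.0), True
    z = (observed - null_mean) / null_sd
    p = norm.sf(z) if tail == "upper" else norm.cdf(z)
    return float(p), False
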