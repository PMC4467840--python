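"""Topology classification of cis-NATs against antisense genes, OLP/NOLP
extraction, the non-redundant set, and cross-set validation.

A cis-NAT and its antisense gene can sit in five geometric configurations:

* Type 1 — partial overlap, divergent (head-to-head): the 5' end of each
  transcript lies inside the other, transcription proceeds apart.
* Type 2 — partial overlap, convergent (tail-to-tail): the 3' ends overlap.
* Type 3 — the NAT's span is fully contained in one antisense gene's span.
* Type 4 — an antisense gene's span is strictly contained in the NAT's span.
* Type 5 — the NAT overlaps two or more distinct antisense genes.

Assignment precedence is 5, 3, 4, 1, 2: a NAT with two antisense partners is
Type 5 even if it is also fully contained in one of them. Containment is
decided on transcript spans; OLP/NOLP decomposition is decided on exon chains
(or spans, selectable).
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import (
    GenomicInterval,
    NatRecord,
    TranscriptModel,
    interval_subtract,
    merge_intervals,
    overlap_bp,
    total_length,
)

NO_ANTISENSE_PARTNER = "no_antisense_partner"


@dataclass
class TopologyCall:
    nat_id: str
    type: int | None
    antisense_gene_ids: list[str]

    @property
    def classified(self) -> bool:
        return self.type is not None


def _antisense_partners(
    nat: TranscriptModel, genes: list[TranscriptModel]
) -> list[TranscriptModel]:
    """Genes with >=1 bp genomic span overlap on the opposite strand.

    Unstranded features never count as antisense partners.
    """
    if nat.strand not in "+-":
        return []
    want = "-" if nat.strand == "+" else "+"
    return [
        g
        for g in genes
        if g.strand == want and overlap_bp(nat.span, g.span) > 0
    ]


def classify_topology(
    nat: TranscriptModel, genes: list[TranscriptModel]
) -> TopologyCall:
    """Assign exactly one topology type using the precedence order 5,3,4,1,2.

    A NAT overlapping no gene on the opposite strand gets ``type=None``
    (``no_antisense_partner``), a distinct outcome rather than an error.
    """
    partners = _antisense_partners(nat, genes)
    if not partners:
        return TopologyCall(nat.id, None, [])
    ids = [g.id for g in partners]
    distinct_genes = {g.gene_id for g in partners}
    if len(distinct_genes) >= 2:
        return TopologyCall(nat.id, 5, ids)
    gene = partners[0]
    ns, gs = nat.span, gene.span
    if gs.start <= ns.start and ns.end <= gs.end:
        return TopologyCall(nat.id, 3, ids)
    if ns.start <= gs.start and gs.end <= ns.end:
        return TopologyCall(nat.id, 4, ids)
    # partial overlap: head-to-head (both 5' termini inside the other) vs
    # tail-to-tail (both 3' termini inside the other)
    def inside(pos: int, span: GenomicInterval) -> bool:
        return span.start <= pos < span.end

    if inside(nat.five_prime(), gs) and inside(gene.five_prime(), ns):
        return TopologyCall(nat.id, 1, ids)
    return TopologyCall(nat.id, 2, ids)


def extract_nolps(
    nat: TranscriptModel,
    genes: list[TranscriptModel],
    mode: str = "exon",
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split the NAT's exonic footprint into gene-overlapping parts (OLPs) and
    non-overlapping parts (NOLPs).

    ``mode='exon'`` subtracts protein-coding exon chains, so intronic stretches
    under the overlap count as NOLP; ``mode='transcript_span'`` subtracts whole
    gene spans. Returns ``(olp, nolps)``.
    """
    if mode not in ("exon", "transcript_span"):
        raise ValueError(f"unknown NOLP mode {mode!r}")
    coding = [g for g in genes if g.biotype == "protein_coding" and g.chrom == nat.chrom]
    if mode == "exon":
        obstacles = [e for g in coding for e in g.exons]
    else:
        obstacles = [g.span for g in coding]
    nolps: list[GenomicInterval] = []
    olp: list[GenomicInterval] = []
    for exon in nat.footprint():
        free = interval_subtract(exon, obstacles)
        nolps.extend(free)
        olp.extend(interval_subtract(exon, free))
    return merge_strand(olp, nat.strand), merge_strand(nolps, nat.strand)


def merge_strand(intervals, strand):
    """Merge adjacent/overlapping intervals, restamping the given strand."""
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, strand)
        for iv in merge_intervals(intervals)
    ] if intervals else []


def classify_all(
    nats: list[TranscriptModel],
    genes: list[TranscriptModel],
    dataset: str = "TAIR",
    mode: str = "exon",
) -> list[NatRecord]:
    """Classify every NAT and decompose it into OLP/NOLP; NATs with no
    antisense partner are dropped (they are not cis-NATs)."""
    coding = [g for g in genes if g.biotype == "protein_coding"]
    records = []
    for nat in nats:
        call = classify_topology(nat, coding)
        if not call.classified:
            continue
        olp, nolps = extract_nolps(nat, coding, mode=mode)
        records.append(
            NatRecord(
                transcript=nat,
                dataset=dataset,
                topology=call.type,
                antisense_gene_ids=call.antisense_gene_ids,
                olp=olp,
                nolps=nolps,
            )
        )
    return records


def build_nr_set(nolp_owners: list[NatRecord]) -> list[NatRecord]:
    """Greedy non-redundant list over NOLPs.

    Records are taken in decreasing order of total NOLP length (ties broken by
    record id for determinism); a record is kept iff none of its NOLP
    intervals overlaps (>=1 bp, either strand) a NOLP of any already-kept
    record. Records with no NOLPs are excluded up front.
    """
    candidates = [r for r in nolp_owners if r.nolps]
    candidates.sort(key=lambda r: (-r.nolp_length(), r.id))
    kept: list[NatRecord] = []
    kept_nolps: list[GenomicInterval] = []
    for rec in candidates:
        clash = any(
            overlap_bp(a, b) > 0 for a in rec.nolps for b in kept_nolps
        )
        if not clash:
            kept.append(rec)
            kept_nolps.extend(rec.nolps)
    return kept


def crossvalidate(
    nats_a: list[NatRecord], other_sets: list[NatRecord]
) -> list[NatRecord]:
    """Flag each record in ``nats_a`` as validated iff its genomic span
    overlaps (>=1 bp, same strand) any NAT of the other sets. Mutates and
    returns ``nats_a``."""
    for rec in nats_a:
        span = rec.transcript.span
        rec.validated_by_other_sets = any(
            o.transcript.strand == rec.transcript.strand
            and overlap_bp(span, o.transcript.span) > 0
            for o in other_sets
        )
    return nats_a
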