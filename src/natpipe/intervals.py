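"""Strand-aware genomic intervals and the interval algebra the pipeline is built on.

All internal coordinates are 0-based half-open ``[start, end)``; conversion to
and from 1-based inclusive conventions (GFF3) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on one sequence.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of ``a`` and ``b``; 0 if disjoint or on
    different sequences."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal disjoint intervals.

    Strand is dropped (result is unstranded); inputs may span several chroms.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def interval_subtract(
    a: GenomicInterval, bs: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal sub-intervals of ``a`` covered by none of ``bs``, sorted.

    Every ``b`` must be on ``a``'s chrom. Strand of the results follows ``a``.
    """
    for b in bs:
        if b.chrom != a.chrom:
            raise ValueError(f"chrom mismatch: {a.chrom} vs {b.chrom}")
    out: list[GenomicInterval] = []
    pos = a.start
    for b in merge_intervals(bs) if bs else []:
        if b.end <= pos or b.start >= a.end:
            continue
        if b.start > pos:
            out.append(GenomicInterval(a.chrom, pos, b.start, a.strand))
        pos = max(pos, b.end)
        if pos >= a.end:
            break
    if pos < a.end:
        out.append(GenomicInterval(a.chrom, pos, a.end, a.strand))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chrom and strand.

    ``biotype`` is one of ``protein_coding``, ``nat``, ``transposon``,
    ``pseudogene``, ``other``. ``span`` is the genomic extent from the first
    exon start to the last exon end.
    """

    id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]

    BIOTYPES = ("protein_coding", "nat", "transposon", "pseudogene", "other")

    def __post_init__(self) -> None:
        if self.biotype not in self.BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id}: exons on mixed chrom/strand")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def footprint(self) -> list[GenomicInterval]:
        """Exonic footprint (the exons themselves; already disjoint/sorted)."""
        return list(self.exons)

    def five_prime(self) -> int:
        """Genomic position of the 5' terminal base (0-based)."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    def three_prime(self) -> int:
        """Genomic position of the 3' terminal base (0-based)."""
        return self.span.end - 1 if self.strand == "+" else self.span.start


@dataclass
class NatRecord:
    """One cis-NAT with its topology call, OLP/NOLP decomposition and the
    per-stage flags the pipeline fills in."""

    transcript: TranscriptModel
    dataset: str = "TAIR"
    topology: int | None = None
    antisense_gene_ids: list[str] = field(default_factory=list)
    olp: list[GenomicInterval] = field(default_factory=list)
    nolps: list[GenomicInterval] = field(default_factory=list)
    conserved_pairwise: bool | None = None
    conserved_phylo: bool | None = None
    expression_conserved: bool | None = None
    validated_by_other_sets: bool | None = None

    DATASETS = ("TAIR", "Matsui2008", "Okamoto2010", "RNASeq", "RepTAS", "NR")

    @property
    def id(self) -> str:
        return self.transcript.id

    def nolp_length(self) -> int:
        return total_length(self.nolps)

    def check_partition(self) -> None:
        """Assert olp and nolps partition the transcript's exonic footprint."""
        parts = sorted(self.olp + self.nolps, key=lambda iv: iv.start)
        foot = self.transcript.footprint()
        if total_length(parts) != total_length(foot):
            raise AssertionError(f"{self.id}: OLP+NOLP length != footprint length")
        covered = merge_intervals(parts) if parts else []
        if covered != [GenomicInterval(i.chrom, i.start, i.end) for i in merge_intervals(foot)]:
            raise AssertionError(f"{self.id}: OLP+NOLP do not tile the footprint")


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (peaks, transposons, CNSs, transcript
    evidence) with optional per-interval ids."""

    kind: str
    intervals: list[GenomicInterval]
    ids: list[str] | None = None

    KINDS = ("chip_peak", "transposon", "cns", "transcript_evidence")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.ids is not None:
            if len(self.ids) != len(self.intervals):
                raise ValueError("ids/intervals length mismatch")
            if len(set(self.ids)) != len(self.ids):
                raise ValueError("feature ids must be unique")

    def __len__(self) -> int:
        return len(self.intervals)
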