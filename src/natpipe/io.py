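"""Readers and writers for the standard formats the pipeline touches.

Conventions: GFF3 is 1-based inclusive on disk, BED6 and MAF are 0-based
half-open; everything is converted to internal 0-based half-open coordinates
on read and back on write. FASTA/FASTQ go through Bio.SeqIO and MAF through
Bio.AlignIO.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, TranscriptModel

# feature-type -> biotype fallback when no biotype attribute is present
_TYPE_TO_BIOTYPE = {
    "mRNA": "protein_coding",
    "transcript": "other",
    "ncRNA": "other",
    "antisense_RNA": "nat",
    "antisense_transcript": "nat",
    "nat": "nat",
    "transposable_element": "transposon",
    "pseudogenic_transcript": "pseudogene",
}


class FormatError(ValueError):
    """Raised for malformed annotation/model files; message names the line."""


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, val = chunk.split("=", 1)
        attrs[key.strip()] = val.strip()
    return attrs


def read_annotation(path: str | Path, format: str = "gff3") -> list[TranscriptModel]:
    """Read transcript models from GFF3 (gene/transcript/exon) or BED6.

    BED rows become single-exon transcripts (the shape tiling-array NAT
    "regions" take); GFF3 transcripts with no exon children are treated the
    same way, using the transcript line's own extent.
    """
    path = Path(path)
    if format == "bed":
        return [
            TranscriptModel(id=name, gene_id=name, biotype="nat", exons=[iv])
            for iv, name in read_bed(path, with_names=True)
        ]
    if format != "gff3":
        raise ValueError(f"unknown annotation format {format!r}")

    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon without Parent attribute")
                exons_by_tx.setdefault(parent, []).append(iv)
            elif ftype == "gene":
                continue
            else:
                tid = attrs.get("ID")
                if tid is None:
                    raise FormatError(f"{path}:{lineno}: {ftype} without ID attribute")
                biotype = attrs.get("biotype", _TYPE_TO_BIOTYPE.get(ftype, "other"))
                tx_meta[tid] = {
                    "gene_id": attrs.get("Parent", tid),
                    "biotype": biotype,
                    "span": iv,
                }
                order.append(tid)

    transcripts = []
    for tid in order:
        meta = tx_meta[tid]
        exons = exons_by_tx.get(tid) or [meta["span"]]
        transcripts.append(
            TranscriptModel(id=tid, gene_id=meta["gene_id"], biotype=meta["biotype"], exons=exons)
        )
    # exon groups whose parent transcript line is absent
    for tid, exons in exons_by_tx.items():
        if tid not in tx_meta:
            transcripts.append(
                TranscriptModel(id=tid, gene_id=tid, biotype="other", exons=exons)
            )
    return transcripts


def write_annotation(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GFF3 (1-based inclusive), one transcript + exon
    lines per model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            span = tx.span
            ftype = {"protein_coding": "mRNA", "nat": "antisense_RNA"}.get(tx.biotype, "transcript")
            fh.write(
                f"{span.chrom}\tnatpipe\t{ftype}\t{span.start + 1}\t{span.end}\t.\t"
                f"{span.strand}\t.\tID={tx.id};Parent={tx.gene_id};biotype={tx.biotype}\n"
            )
            for i, ex in enumerate(tx.exons, 1):
                fh.write(
                    f"{ex.chrom}\tnatpipe\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={tx.id}.exon{i};Parent={tx.id}\n"
                )


def read_bed(path: str | Path, with_names: bool = False):
    """Read BED (3-6 columns, 0-based half-open) as GenomicIntervals."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
            iv = GenomicInterval(cols[0], start, end, strand)
            name = cols[3] if len(cols) >= 4 else f"feat{lineno}"
            out.append((iv, name) if with_names else iv)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"feat{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_reads(path: str | Path) -> dict[str, str]:
    """Read short reads from FASTA or FASTQ (sniffed from the first byte)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)}


# ---------------------------------------------------------------------------
# MAF alignment blocks


@dataclass
class AlignmentBlock:
    """One MAF block: per-species gapped rows over {A,C,G,T,N,-}, referenced
    to an interval on the focal genome (the first row)."""

    ref_interval: GenomicInterval
    rows: dict[str, str]
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = list(self.rows)
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        ref_sp = self.species[0]
        ungapped = len(self.rows[ref_sp]) - self.rows[ref_sp].count("-")
        if ungapped != len(self.ref_interval):
            raise ValueError(
                f"reference row has {ungapped} bases but ref interval spans "
                f"{len(self.ref_interval)}"
            )

    @property
    def ref_species(self) -> str:
        return self.species[0]

    def ref_columns(self) -> list[int]:
        """Alignment-column index of each reference base, in ref order."""
        return [i for i, c in enumerate(self.rows[self.ref_species]) if c != "-"]


def read_maf(path: str | Path, ref_species: str | None = None) -> list[AlignmentBlock]:
    """Read MAF blocks. Row source names are ``species.chrom``; the reference
    is the first row of each block (or ``ref_species`` if given)."""
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows: dict[str, str] = {}
        species: list[str] = []
        ref = None
        for rec in aln:
            sp, _, chrom = rec.id.partition(".")
            rows[sp] = str(rec.seq).upper()
            species.append(sp)
            if ref is None and (ref_species is None or sp == ref_species):
                start = rec.annotations["start"]
                size = rec.annotations["size"]
                strand = "+" if rec.annotations.get("strand", 1) == 1 else "-"
                ref = GenomicInterval(chrom or sp, start, start + size, strand)
                ref_name = sp
        if ref is None:
            raise FormatError(f"{path}: block missing reference species row")
        species.remove(ref_name)
        species.insert(0, ref_name)
        blocks.append(AlignmentBlock(ref_interval=ref, rows=rows, species=species))
    blocks.sort(key=lambda b: (b.ref_interval.chrom, b.ref_interval.start))
    return blocks


def write_maf(blocks: Sequence[AlignmentBlock], path: str | Path) -> None:
    alns = []
    for blk in blocks:
        aln = MultipleSeqAlignment([])
        for i, sp in enumerate(blk.species):
            row = blk.rows[sp]
            size = len(row) - row.count("-")
            if i == 0:
                src = f"{sp}.{blk.ref_interval.chrom}"
                start = blk.ref_interval.start
                srcsize = blk.ref_interval.end + 10_000
            else:
                src, start, srcsize = sp, 0, size
            rec = SeqRecord(Seq(row), id=src)
            rec.annotations.update(
                {"start": start, "size": size, "strand": 1, "srcSize": srcsize}
            )
            aln.append(rec)
        alns.append(aln)
    with open(path, "w") as fh:
        AlignIO.write(alns, fh, "maf")


def stitch_columns(
    blocks: Sequence[AlignmentBlock],
    query: GenomicInterval,
    species: Sequence[str],
) -> list[str]:
    """Alignment columns (one string per column, species order as given) for
    the reference positions inside ``query``.

    Blocks are stitched by reference coordinate; species absent from a block
    contribute ``-`` (missing data). Reference positions covered by no block
    are skipped.
    """
    columns: list[str] = []
    for blk in blocks:
        if blk.ref_interval.chrom != query.chrom:
            continue
        if blk.ref_interval.end <= query.start or blk.ref_interval.start >= query.end:
            continue
        ref_cols = blk.ref_columns()
        for offset, col_idx in enumerate(ref_cols):
            pos = blk.ref_interval.start + offset
            if query.start <= pos < query.end:
                columns.append(
                    "".join(blk.rows.get(sp, "-" * len(blk.rows[blk.ref_species]))[col_idx]
                            for sp in species)
                )
    return columns
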