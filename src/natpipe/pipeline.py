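"""End-to-end orchestration: one config in, the full set of stage outputs
and report tables out, reproducibly.

Stage order: topology classification -> NOLP conservation (scale LRT over
the species alignment, Holm-Bonferroni across all interval tests) ->
sister-genome sequence/expression conservation -> matched resampling null ->
siRNA mapping -> report tables. Every output TSV carries a metadata header
(version, config hash, seed) and reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .crossref import ReferenceSet, build_report_tables, map_sirnas
from .homology import (
    GenomeIndex,
    bdbh_orthologs,
    call_expression_conservation,
    pairwise_conservation_call,
    revcomp,
    seed_chain_extend_map,
)
from .intervals import FeatureTrack, GenomicInterval, NatRecord, TranscriptModel
from .io import read_annotation, read_bed, read_fasta, read_maf, read_reads
from .nullsampling import normal_empirical_p, null_distribution
from .phylo import call_conserved, holm_bonferroni, read_neutral_model, scale_lrt
from .io import stitch_columns
from .topology import build_nr_set, classify_all


@dataclass
class PipelineConfig:
    genes: str
    nats: str
    genome: str
    maf: str | None = None
    model: str | None = None
    sister_genome: str | None = None
    sister_evidence: str | None = None
    sister_proteome: str | None = None
    proteome: str | None = None
    sirnas: str | None = None
    peaks: str | None = None
    transposons: str | None = None
    outdir: str = "natpipe_out"
    dataset: str = "synthetic"
    nolp_mode: str = "exon"
    alpha: float = 0.05
    pairwise_evalue: float = 1e-10
    protein_evalue: float = 1e-4
    max_orf_codons: int = 100
    flank: int = 5000
    n_replicates: int = 500
    null_statistic: str = "chip_peaks"
    seed: int = 17

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def transcript_sequence(genome: dict[str, str], tx: TranscriptModel) -> str:
    seq = "".join(genome[e.chrom][e.start:e.end] for e in tx.exons)
    return revcomp(seq) if tx.strand == "-" else seq


def _local_regions(tx: TranscriptModel, intervals) -> list[tuple[int, int]]:
    """Map genomic intervals inside a (single-exon footprint) transcript to
    transcript-local coordinates on its sense strand."""
    span = tx.span
    out = []
    for iv in intervals:
        if tx.strand == "+":
            out.append((iv.start - span.start, iv.end - span.start))
        else:
            out.append((span.end - iv.end, span.end - iv.start))
    return sorted(out)


def _interval_seq(genome: dict[str, str], iv: GenomicInterval) -> str:
    seq = genome[iv.chrom][iv.start:iv.end]
    return revcomp(seq) if iv.strand == "-" else seq


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# natpipe {__version__}\n# config_hash {config.config_hash()}\n"
                 f"# seed {config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage the config's inputs support; returns written paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tables").mkdir(exist_ok=True)
    written: dict[str, Path] = {}

    # --- topology ---------------------------------------------------------
    try:
        genes = read_annotation(config.genes)
        nats = read_annotation(config.nats)
        genome = read_fasta(config.genome)
    except (OSError, ValueError) as exc:
        raise StageError("topology", str(exc)) from exc
    records = classify_all(nats, genes, dataset=config.dataset, mode=config.nolp_mode)
    topo_df = pd.DataFrame(
        {
            "nat_id": r.id,
            "dataset": r.dataset,
            "type": r.topology,
            "antisense_genes": ",".join(r.antisense_gene_ids),
            "nolp_intervals": ";".join(f"{iv.start}-{iv.end}" for iv in r.nolps),
            "olp_intervals": ";".join(f"{iv.start}-{iv.end}" for iv in r.olp),
        }
        for r in records
    )
    _write_tsv(topo_df, outdir / "topology.tsv", config)
    written["topology"] = outdir / "topology.tsv"

    # --- conservation (scale LRT) ----------------------------------------
    if config.maf and config.model:
        try:
            blocks = read_maf(config.maf)
            model = read_neutral_model(config.model)
        except (OSError, ValueError) as exc:
            raise StageError("conservation", str(exc)) from exc
        rows = []
        tested = []
        for rec in records:
            if rec.topology == 3:
                continue
            for iv in rec.nolps:
                cols = stitch_columns(blocks, iv, model.leaf_names)
                res = scale_lrt(cols, model)
                rows.append({"nat_id": rec.id, "start": iv.start, "end": iv.end,
                             "scale": res.scale, "lnL_null": res.lnL_null,
                             "lnL_alt": res.lnL_alt, "D": res.D, "p": res.p_value,
                             "direction": res.direction, "testable": res.testable})
                tested.append((rec, res))
        if tested:
            adj, _ = holm_bonferroni([r.p_value for _, r in tested], config.alpha)
            for (rec, res), a in zip(tested, adj):
                res.p_adjusted = float(a)
        for i, (_rec, res) in enumerate(tested):
            rows[i]["p_holm"] = res.p_adjusted
        by_rec: dict[str, list] = {}
        for rec, res in tested:
            by_rec.setdefault(rec.id, []).append(res)
        for rec in records:
            if rec.topology == 3:
                rec.conserved_phylo = None
            else:
                rec.conserved_phylo, _ = call_conserved(
                    by_rec.get(rec.id, []), alpha=config.alpha
                )
        cons_df = pd.DataFrame(rows)
        _write_tsv(cons_df, outdir / "conservation.tsv", config)
        written["conservation"] = outdir / "conservation.tsv"

    # --- sister genome: sequence + expression conservation ---------------
    if config.sister_genome and config.sister_evidence:
        try:
            sister = read_fasta(config.sister_genome)
            ev = read_bed(config.sister_evidence, with_names=True)
        except (OSError, ValueError) as exc:
            raise StageError("expression", str(exc)) from exc
        evidence = FeatureTrack(
            "transcript_evidence", [iv for iv, _ in ev], ids=[n for _, n in ev]
        )
        sister_index = GenomeIndex(sister)
        sister_prot = read_fasta(config.sister_proteome) if config.sister_proteome else {}
        focal_prot = read_fasta(config.proteome) if config.proteome else {}
        if focal_prot and sister_prot:
            orthologs = dict(bdbh_orthologs(focal_prot, sister_prot))
        else:
            orthologs = {}
        gene_by_id = {g.id: g for g in genes}
        ortho_span_cache: dict[str, GenomicInterval | None] = {}

        def ortholog_span(gene_id: str) -> GenomicInterval | None:
            if gene_id in ortho_span_cache:
                return ortho_span_cache[gene_id]
            span = None
            if (gene_id in orthologs or not orthologs) and gene_id in gene_by_id:
                g = gene_by_id[gene_id]
                hits = seed_chain_extend_map(transcript_sequence(genome, g), sister_index)
                if hits:
                    t = hits[0].target
                    strand = g.strand if hits[0].strand == "+" else (
                        "-" if g.strand == "+" else "+"
                    )
                    span = GenomicInterval(t.chrom, t.start, t.end, strand)
            ortho_span_cache[gene_id] = span
            return span

        expr_rows = []
        for rec in records:
            gene_id = rec.antisense_gene_ids[0] if rec.antisense_gene_ids else None
            gid = gene_by_id[gene_id].gene_id if gene_id in gene_by_id else gene_id
            ospan = ortholog_span(gene_id) if gene_id else None
            nat_seq = transcript_sequence(genome, rec.transcript)
            call = call_expression_conservation(
                nat_seq, sister_index, evidence, ospan, sister_prot,
                max_orf=config.max_orf_codons, protein_evalue=config.protein_evalue,
            )
            rec.expression_conserved = call.conserved
            # pairwise sequence conservation: best NOLP hit in the ortholog flank
            pairwise = False
            if ospan is not None and rec.nolps:
                chrom_len = len(sister[ospan.chrom])
                lo = max(0, ospan.start - config.flank)
                hi = min(chrom_len, ospan.end + config.flank)
                flank_seq = sister[ospan.chrom][lo:hi]
                pairwise = any(
                    pairwise_conservation_call(
                        _interval_seq(genome, iv), flank_seq,
                        evalue_cutoff=config.pairwise_evalue,
                    )
                    for iv in rec.nolps
                )
            rec.conserved_pairwise = pairwise
            expr_rows.append({"nat_id": rec.id, "expression_conserved": call.conserved,
                              "reason": call.reason, "conserved_pairwise": pairwise,
                              "ortholog_found": ospan is not None})
        _write_tsv(pd.DataFrame(expr_rows), outdir / "expression.tsv", config)
        written["expression"] = outdir / "expression.tsv"

    # --- feature tracks ---------------------------------------------------
    peaks = transposons = None
    if config.peaks:
        pk = read_bed(config.peaks, with_names=True)
        peaks = FeatureTrack("chip_peak", [iv for iv, _ in pk], ids=[n for _, n in pk])
    if config.transposons:
        te = read_bed(config.transposons)
        transposons = FeatureTrack("transposon", te)

    # --- matched resampling null ------------------------------------------
    if peaks is not None:
        from .crossref import count_feature_overlap

        observed_nolps = [iv for r in records for iv in r.nolps]
        if observed_nolps:
            genome_extent = {c: len(s) for c, s in genome.items()}
            stat = lambda ivs: count_feature_overlap(ivs, peaks, "features")
            observed = stat(observed_nolps)
            try:
                mean, sd, values = null_distribution(
                    stat, genes + nats, observed_nolps, genome_extent,
                    n_replicates=config.n_replicates, seed=config.seed,
                )
            except (RuntimeError, ValueError) as exc:
                raise StageError("null", str(exc)) from exc
            p_up, degen_u = normal_empirical_p(observed, mean, sd, "upper")
            p_lo, degen_l = normal_empirical_p(observed, mean, sd, "lower")
            null_df = pd.DataFrame([
                {"statistic": config.null_statistic, "observed": observed,
                 "null_mean": mean, "null_sd": sd,
                 "p_upper": p_up, "p_lower": p_lo,
                 "degenerate": degen_u or degen_l,
                 "n_replicates": config.n_replicates}
            ])
            _write_tsv(null_df, outdir / "null.tsv", config)
            written["null"] = outdir / "null.tsv"

    # --- siRNA mapping -----------------------------------------------------
    sirna_mappings = None
    if config.sirnas:
        reads = read_reads(config.sirnas)
        refset = build_reference_set(genome, genes, records)
        mappings, _skipped = map_sirnas(reads, refset)
        sirna_mappings = {config.dataset: mappings}
        sirna_df = pd.DataFrame(
            {
                "read_id": m.read_id, "copies": m.copies, "reference": m.reference,
                "offset": m.offset, "orientation": m.orientation, "unique": m.unique,
                "compartment": m.compartment, "acting": m.acting,
            }
            for m in mappings
        )
        _write_tsv(sirna_df, outdir / "sirna.tsv", config)
        written["sirna"] = outdir / "sirna.tsv"

    # --- NR set + report tables -------------------------------------------
    nr = build_nr_set([r for r in records if r.topology != 3])
    by_dataset = {config.dataset: records, "NR": nr}
    tables = build_report_tables(
        by_dataset,
        peaks=peaks,
        transposons=transposons,
        sirna_mappings=sirna_mappings,
    )
    for name, df in tables.items():
        path = outdir / "tables" / f"{name}.tsv"
        _write_tsv(df, path, config)
        written[f"table_{name}"] = path
    return written


def build_reference_set(
    genome: dict[str, str],
    genes: list[TranscriptModel],
    records: list[NatRecord],
) -> ReferenceSet:
    """Combined siRNA reference: protein-coding transcripts plus NAT regions,
    with NOLP/OLP labels in transcript-local coordinates and locus grouping
    tying each NAT to its antisense genes."""
    seqs: dict[str, str] = {}
    nat_regions: dict[str, dict[str, list[tuple[int, int]]]] = {}
    locus: dict[str, str] = {}
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        seqs[g.id] = transcript_sequence(genome, g)
    for rec in records:
        tx = rec.transcript
        seqs[tx.id] = transcript_sequence(genome, tx)
        nat_regions[tx.id] = {
            "nolp": _local_regions(tx, rec.nolps),
            "olp": _local_regions(tx, rec.olp),
        }
        locus[tx.id] = tx.id
        for gid in rec.antisense_gene_ids:
            locus[gid] = tx.id
    return ReferenceSet(seqs=seqs, nat_regions=nat_regions, locus=locus)


# ---------------------------------------------------------------------------
# In-memory analysis of synthetic worlds


def analyze_world(
    world,
    alpha: float = 0.05,
    with_expression: bool = True,
    use_sister_proteome: bool = True,
    seed: int | None = None,
) -> list[NatRecord]:
    """Run the classification, conservation-LRT and expression stages on an
    in-memory synthetic world, returning flagged records.

    The sister annotation (ortholog gene coordinates) is taken from the
    world's own gene table — the synthetic sister genome is colinear with the
    focal one, so the sister annotation an external pipeline run would read
    from disk is exactly this table.
    """
    from .synth import generate_sister, simulate_alignment

    config = world.config
    model = config.neutral_model()
    records = classify_all(world.nats, world.genes, dataset=config.dataset)
    blocks = simulate_alignment(world, seed=seed)
    tested = []
    for rec in records:
        if rec.topology == 3:
            continue
        results = []
        for iv in rec.nolps:
            cols = stitch_columns(blocks, iv, model.leaf_names)
            results.append(scale_lrt(cols, model))
        rec.conserved_phylo, _ = call_conserved(results, alpha=alpha)
        tested.append(rec)
    if with_expression:
        sister, (evidence_ivs, names), sister_prot = generate_sister(
            world, seed=None if seed is None else seed + 1
        )
        evidence = FeatureTrack("transcript_evidence", evidence_ivs,
                                ids=names or None)
        index = GenomeIndex(sister)
        prot = sister_prot if use_sister_proteome else {}
        gene_by_id = {g.id: g for g in world.genes}
        for rec in records:
            g = gene_by_id[rec.antisense_gene_ids[0]]
            ospan = GenomicInterval(
                "sister_" + g.chrom, g.span.start, g.span.end, g.strand
            )
            nat_seq = transcript_sequence(world.genome, rec.transcript)
            call = call_expression_conservation(nat_seq, index, evidence, ospan, prot)
            rec.expression_conserved = call.conserved
    return records
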