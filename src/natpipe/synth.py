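"""Synthetic world generator.

Builds, from one seed, a complete input set with the statistical structure
the analysis assumes: a genome with protein-coding genes whose CDS is
implanted in the sequence, cis-NATs realising each of the five topologies by
construction, a 9-taxon whole-genome alignment simulated under the neutral
model with per-locus branch-length scales (conserved NOLP loci at a reduced
scale), siRNA reads drawn preferentially from OLPs, promoter-enriched peak
tracks, transposons depleted in conserved NOLPs, and a diverged sister
genome that retains antisense transcript evidence at NAT loci with a
configurable probability — optionally coupled to the conservation label.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs. The truth table records each NAT's intended type,
scale, and sister-expression status, so every downstream flag can be checked
against ground truth without running the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TranscriptModel, interval_subtract
from .io import AlignmentBlock, write_annotation, write_bed, write_fasta, write_maf
from .phylo import (
    BASES,
    NeutralModel,
    codes_to_seq,
    parse_newick,
    simulate_columns,
)

# Nine-leaf tree with total root-to-tip depth around 0.5 substitutions/site,
# the sort of range a crucifer-family alignment spans.
DEFAULT_TREE = (
    "(((((focal:0.08,sister:0.08):0.06,sp3:0.14):0.05,(sp4:0.12,sp5:0.12):0.07)"
    ":0.05,(sp6:0.16,sp7:0.16):0.08):0.06,(sp8:0.22,sp9:0.22):0.08);"
)
DEFAULT_FREQS = (0.32, 0.18, 0.18, 0.32)


@dataclass
class SynthConfig:
    genome_length: int = 200_000
    chrom: str = "chr1"
    n_genes: int = 40
    gene_codons: tuple[int, int] = (120, 260)
    gene_gap: tuple[int, int] = (1400, 2600)
    n_nats: int = 30
    nat_length: tuple[int, int] = (400, 1200)
    topology_props: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2}
    )
    dataset: str = "synthetic"
    # conservation truth
    frac_conserved: float = 0.3
    conserved_scale: float = 0.3
    tree_newick: str = DEFAULT_TREE
    base_freqs: tuple[float, ...] = DEFAULT_FREQS
    kappa: float = 2.0
    maf_block: int = 5000
    # siRNA
    n_sirna_reads: int = 400
    olp_nolp_ratio: float = 9.0
    sirna_background_frac: float = 0.1
    sirna_length: tuple[int, int] = (21, 24)
    # peaks
    n_peaks: int = 120
    promoter_frac: float = 0.6
    promoter_window: int = 300
    peak_length: tuple[int, int] = (80, 150)
    # transposons
    te_length: tuple[int, int] = (100, 200)
    te_prob_conserved: float = 0.05
    te_prob_unconserved: float = 0.4
    n_background_te: int = 30
    # sister genome
    sister_divergence: float = 0.10
    expression_retention: float = 0.3
    expression_coupling: float = 1.0  # q_conserved / q_unconserved odds ratio
    seed: int = 0

    def neutral_model(self) -> NeutralModel:
        return NeutralModel.hky(
            parse_newick(self.tree_newick), np.array(self.base_freqs), self.kappa
        )

    def retention_probs(self) -> tuple[float, float]:
        """(q_conserved, q_unconserved) with overall retention equal to
        ``expression_retention`` given ``frac_conserved``."""
        f, q, rho = self.frac_conserved, self.expression_retention, self.expression_coupling
        q_un = q / (f * rho + (1 - f))
        return min(1.0, rho * q_un), min(1.0, q_un)


@dataclass
class SynthWorld:
    config: SynthConfig
    genome: dict[str, str]
    genes: list[TranscriptModel]
    nats: list[TranscriptModel]
    truth: pd.DataFrame
    cds_ranges: dict[str, GenomicInterval]
    proteome: dict[str, str]


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = None


def _codon_to_aa(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Seq import Seq

        _CODON_TABLE = {}
        for a in BASES:
            for b in BASES:
                for c in BASES:
                    _CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    return _CODON_TABLE[codon]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def generate_annotation(config: SynthConfig) -> SynthWorld:
    """Genome + genes + NATs realising the requested topology mix, with the
    per-NAT truth table. Raises if the features cannot be packed into the
    genome."""
    rng = np.random.default_rng(config.seed)
    model = config.neutral_model()
    chrom = config.chrom

    # genome background from equilibrium frequencies
    codes = rng.choice(4, size=config.genome_length, p=model.pi)
    genome = np.array(list(BASES))[codes]

    # NAT type plan
    types = sorted(config.topology_props)
    props = np.array([config.topology_props[t] for t in types], dtype=float)
    if props.sum() <= 0:
        raise ValueError("topology proportions must sum to a positive value")
    props = props / props.sum()
    counts = np.floor(props * config.n_nats).astype(int)
    for i in np.argsort(-(props * config.n_nats - counts)):
        if counts.sum() >= config.n_nats:
            break
        counts[i] += 1
    plan: list[int] = [t for t, c in zip(types, counts) for _ in range(c)]
    rng.shuffle(plan)
    genes_needed = sum(2 if t == 5 else 1 for t in plan)
    if genes_needed > config.n_genes:
        raise ValueError(
            f"{config.n_genes} genes cannot host {config.n_nats} NATs "
            f"({genes_needed} needed)"
        )

    # place genes left to right
    genes: list[TranscriptModel] = []
    cds_ranges: dict[str, GenomicInterval] = {}
    proteome: dict[str, str] = {}
    pos = int(rng.integers(*config.gene_gap))
    for gi in range(config.n_genes):
        n_codons = int(rng.integers(*config.gene_codons))
        cds = _random_cds(n_codons, rng)
        length = len(cds)
        if pos + length + config.gene_gap[1] > config.genome_length:
            raise ValueError("genome too short for the requested gene count")
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, pos, pos + length, strand)
        gid = f"g{gi + 1:03d}"
        genes.append(TranscriptModel(id=gid, gene_id=gid, biotype="protein_coding", exons=[iv]))
        genome[pos:pos + length] = list(cds if strand == "+" else _revcomp(cds))
        cds_ranges[gid] = iv
        proteome[gid] = "".join(
            _codon_to_aa(cds[i:i + 3]) for i in range(0, len(cds) - 3, 3)
        )
        pos += length + int(rng.integers(*config.gene_gap))

    # attach NATs to genes; Type 5 consumes a pair of same-strand neighbours
    nats: list[TranscriptModel] = []
    rows = []
    cursor = 0
    for ni, t in enumerate(plan):
        nid = f"nat{ni + 1:03d}"
        if t == 5:
            while cursor + 1 < len(genes) and genes[cursor].strand != genes[cursor + 1].strand:
                # force the pair onto one strand so the NAT opposes both
                g = genes[cursor + 1]
                flipped = GenomicInterval(chrom, g.span.start, g.span.end, genes[cursor].strand)
                genes[cursor + 1] = TranscriptModel(g.id, g.gene_id, g.biotype, [flipped])
                cds_ranges[g.id] = flipped
                s = "".join(genome[flipped.start:flipped.end])
                genome[flipped.start:flipped.end] = list(_revcomp(s))
                break
            g1, g2 = genes[cursor], genes[cursor + 1]
            strand = "-" if g1.strand == "+" else "+"
            o1 = int(rng.integers(80, 200))
            o2 = int(rng.integers(80, 200))
            iv = GenomicInterval(chrom, g1.span.end - o1, g2.span.start + o2, strand)
            gene_ids = [g1.id, g2.id]
            cursor += 2
        else:
            g = genes[cursor]
            gs, ge = g.span.start, g.span.end
            strand = "-" if g.strand == "+" else "+"
            Ln = int(rng.integers(*config.nat_length))
            if t == 3:
                glen = ge - gs
                a = int(rng.integers(20, max(21, glen // 4)))
                b = int(rng.integers(20, max(21, glen // 4)))
                iv = GenomicInterval(chrom, gs + a, max(gs + a + 60, ge - b), strand)
                iv = GenomicInterval(chrom, iv.start, min(iv.end, ge), strand)
            elif t == 4:
                a = int(rng.integers(150, 400))
                b = int(rng.integers(150, 400))
                iv = GenomicInterval(chrom, gs - a, ge + b, strand)
            else:
                o = int(rng.integers(100, 300))
                Ln = max(Ln, o + 150)
                if t == 1:
                    # head-to-head: overlap at the gene's 5' end
                    if g.strand == "-":
                        iv = GenomicInterval(chrom, ge - o, ge - o + Ln, strand)
                    else:
                        iv = GenomicInterval(chrom, gs + o - Ln, gs + o, strand)
                else:
                    # tail-to-tail: overlap at the gene's 3' end
                    if g.strand == "-":
                        iv = GenomicInterval(chrom, gs + o - Ln, gs + o, strand)
                    else:
                        iv = GenomicInterval(chrom, ge - o, ge - o + Ln, strand)
            gene_ids = [g.id]
            cursor += 1
        nats.append(TranscriptModel(id=nid, gene_id=nid, biotype="nat", exons=[iv]))
        conserved = bool(rng.random() < config.frac_conserved)
        rows.append(
            {
                "nat_id": nid,
                "dataset": config.dataset,
                "intended_type": t,
                "gene_ids": ",".join(gene_ids),
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "scale": config.conserved_scale if conserved else 1.0,
                "conserved": conserved,
            }
        )

    # sister-expression truth, optionally coupled to conservation
    q_c, q_u = config.retention_probs()
    for row in rows:
        q = q_c if row["conserved"] else q_u
        row["expressed_in_sister"] = bool(rng.random() < q)

    truth = pd.DataFrame(rows)
    world = SynthWorld(
        config=config,
        genome={chrom: "".join(genome)},
        genes=genes,
        nats=nats,
        truth=truth,
        cds_ranges=cds_ranges,
        proteome=proteome,
    )
    return world


def truth_nolps(world: SynthWorld) -> dict[str, list[GenomicInterval]]:
    """Ground-truth NOLP intervals per NAT (exonic footprint minus gene
    exons), straight from the generator's own geometry."""
    exons = [e for g in world.genes for e in g.exons]
    out = {}
    for nat in world.nats:
        nolps = []
        for ex in nat.exons:
            nolps.extend(interval_subtract(ex, [e for e in exons if e.chrom == ex.chrom]))
        out[nat.id] = nolps
    return out


def scale_map(world: SynthWorld) -> list[tuple[GenomicInterval, float]]:
    """Per-locus scale assignments: conserved NATs' NOLPs at the conserved
    scale, everything else neutral."""
    nolps = truth_nolps(world)
    out = []
    for row in world.truth.itertuples():
        if row.scale != 1.0:
            out.extend((iv, row.scale) for iv in nolps[row.nat_id])
    return out


def simulate_alignment(world: SynthWorld, seed: int | None = None) -> list[AlignmentBlock]:
    """Whole-genome 9-taxon alignment tiled into blocks, conditioned on the
    focal row equalling the genome sequence (exact under reversibility), with
    conserved loci evolved at their reduced scale."""
    config = world.config
    model = config.neutral_model()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    chrom = config.chrom
    genome = world.genome[chrom]
    L = len(genome)
    focal_codes = np.array([BASES.index(c) if c in BASES else 0 for c in genome], dtype=np.int8)

    scales = np.ones(L)
    for iv, s in scale_map(world):
        scales[iv.start:iv.end] = s
    others = [n for n in model.leaf_names if n != "focal"]
    rows_all = {sp: np.empty(L, dtype=np.int8) for sp in others}
    for s in np.unique(scales):
        mask = scales == s
        sim = simulate_columns(
            model, float(s), int(mask.sum()), rng,
            anchor_leaf="focal", anchor_states=focal_codes[mask],
        )
        for sp in others:
            rows_all[sp][mask] = sim[sp]

    blocks = []
    for start in range(0, L, config.maf_block):
        end = min(L, start + config.maf_block)
        rows = {"focal": genome[start:end]}
        for sp in others:
            rows[sp] = codes_to_seq(rows_all[sp][start:end])
        blocks.append(
            AlignmentBlock(
                ref_interval=GenomicInterval(chrom, start, end),
                rows=rows,
                species=["focal"] + others,
            )
        )
    return blocks


def generate_sirnas(world: SynthWorld, seed: int | None = None) -> dict[str, str]:
    """Short reads (21-24 nt) drawn from NAT OLPs vs NOLPs at the configured
    ratio, plus a background fraction from random genome positions. Reads are
    emitted in the NAT's sense orientation."""
    config = world.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genome = world.genome[config.chrom]
    nolps = truth_nolps(world)
    gene_exons = [e for g in world.genes for e in g.exons]
    reads = {}
    p_olp = config.olp_nolp_ratio / (config.olp_nolp_ratio + 1.0)
    for i in range(config.n_sirna_reads):
        rlen = int(rng.integers(config.sirna_length[0], config.sirna_length[1] + 1))
        if rng.random() < config.sirna_background_frac:
            pos = int(rng.integers(0, len(genome) - rlen))
            seq = genome[pos:pos + rlen]
            if rng.random() < 0.5:
                seq = _revcomp(seq)
        else:
            nat = world.nats[int(rng.integers(len(world.nats)))]
            span = nat.span
            from_olp = rng.random() < p_olp
            free = nolps[nat.id]
            if from_olp or not free:
                olp = []
                for ex in nat.exons:
                    covered = interval_subtract(ex, free) if free else [ex]
                    olp.extend(covered)
                pool = olp or [span]
            else:
                pool = free
            pool = [iv for iv in pool if len(iv) >= rlen] or [span]
            iv = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(iv.start, max(iv.start + 1, iv.end - rlen)))
            seq = genome[pos:pos + rlen]
            if nat.strand == "-":
                seq = _revcomp(seq)
        reads[f"read{i + 1:05d}"] = seq
    return reads


def generate_peaks(world: SynthWorld, seed: int | None = None):
    """Peak intervals enriched in promoter windows upstream of gene starts."""
    config = world.config
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    genome_len = len(world.genome[config.chrom])
    intervals = []
    for _ in range(config.n_peaks):
        width = int(rng.integers(*config.peak_length))
        if rng.random() < config.promoter_frac:
            g = world.genes[int(rng.integers(len(world.genes)))]
            tss = g.span.start if g.strand == "+" else g.span.end
            lo = tss - config.promoter_window if g.strand == "+" else tss
            hi = tss if g.strand == "+" else tss + config.promoter_window
            start = int(rng.integers(max(0, lo), max(1, hi - width)))
        else:
            start = int(rng.integers(0, genome_len - width))
        intervals.append(GenomicInterval(config.chrom, start, start + width))
    return intervals


def generate_transposons(world: SynthWorld, seed: int | None = None):
    """Transposon intervals placed inside NOLPs with a conservation-dependent
    probability, plus background copies in intergenic space."""
    config = world.config
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    nolps = truth_nolps(world)
    conserved = dict(zip(world.truth.nat_id, world.truth.conserved))
    intervals = []
    for nat in world.nats:
        p = config.te_prob_conserved if conserved[nat.id] else config.te_prob_unconserved
        for iv in nolps[nat.id]:
            if len(iv) < config.te_length[0] + 10 or rng.random() >= p:
                continue
            width = int(rng.integers(config.te_length[0], min(config.te_length[1], len(iv))))
            start = int(rng.integers(iv.start, iv.end - width))
            intervals.append(GenomicInterval(config.chrom, start, start + width))
    genome_len = len(world.genome[config.chrom])
    spans = [g.span for g in world.genes] + [n.span for n in world.nats]
    tries = 0
    placed = 0
    while placed < config.n_background_te and tries < 50 * config.n_background_te:
        tries += 1
        width = int(rng.integers(*config.te_length))
        start = int(rng.integers(0, genome_len - width))
        cand = GenomicInterval(config.chrom, start, start + width)
        if any(cand.overlaps(s) for s in spans):
            continue
        intervals.append(cand)
        placed += 1
    return intervals


def generate_sister(world: SynthWorld, seed: int | None = None):
    """Diverged sister genome plus antisense transcript-evidence intervals and
    the sister proteome.

    The sister sequence evolves from the focal genome at the configured
    divergence; codons of gene CDSs that would become stops are kept intact,
    so orthologous proteins stay full length. Evidence intervals sit at NAT
    loci (same coordinates — no rearrangement is simulated) and are retained
    with the per-NAT truth-table probability already drawn by
    ``generate_annotation``.
    """
    config = world.config
    model = config.neutral_model()
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    chrom = config.chrom
    genome = world.genome[chrom]
    P = model.transition_matrix(config.sister_divergence)
    codes = np.array([BASES.index(c) for c in genome], dtype=np.int8)
    cum = P.cumsum(axis=1)
    u = rng.random(len(codes))
    new_codes = (u[:, None] > cum[codes]).sum(axis=1).astype(np.int8)
    sister = np.array(list(BASES))[new_codes]

    # repair in-frame stops inside CDSs so sister proteins stay intact
    sister_proteome = {}
    for gid, iv in world.cds_ranges.items():
        s = "".join(sister[iv.start:iv.end])
        cds = s if iv.strand == "+" else _revcomp(s)
        orig = genome[iv.start:iv.end]
        orig_cds = orig if iv.strand == "+" else _revcomp(orig)
        fixed = []
        for i in range(0, len(cds) - 3, 3):
            codon = cds[i:i + 3]
            fixed.append(orig_cds[i:i + 3] if codon in _STOP_CODONS else codon)
        fixed_cds = "ATG" + "".join(fixed)[3:] + "TAA"
        sister_proteome[f"{gid}_sister"] = "".join(
            _codon_to_aa(fixed_cds[i:i + 3]) for i in range(0, len(fixed_cds) - 3, 3)
        )
        implant = fixed_cds if iv.strand == "+" else _revcomp(fixed_cds)
        sister[iv.start:iv.end] = list(implant)

    evidence = []
    names = []
    for row in world.truth.itertuples():
        if row.expressed_in_sister:
            evidence.append(
                GenomicInterval("sister_" + chrom, row.start, row.end, row.strand)
            )
            names.append(f"ev_{row.nat_id}")
    return {"sister_" + chrom: "".join(sister)}, (evidence, names), sister_proteome


def write_world(world: SynthWorld, outdir: str | Path) -> dict[str, Path]:
    """Write the whole world to disk: FASTA/GFF3/BED/MAF plus the truth TSV.
    Returns the path of every file written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "nats": outdir / "nats.gff3",
        "maf": outdir / "alignment.maf",
        "model": outdir / "neutral.mod",
        "truth": outdir / "truth.tsv",
        "sirnas": outdir / "sirnas.fa",
        "peaks": outdir / "peaks.bed",
        "transposons": outdir / "transposons.bed",
        "sister_genome": outdir / "sister.fa",
        "sister_evidence": outdir / "sister_evidence.bed",
        "sister_proteome": outdir / "sister_proteome.fa",
        "proteome": outdir / "proteome.fa",
    }
    write_fasta(world.genome, paths["genome"])
    write_annotation(world.genes, paths["genes"])
    write_annotation(world.nats, paths["nats"])
    write_maf(simulate_alignment(world), paths["maf"])
    from .phylo import write_neutral_model

    write_neutral_model(world.config.neutral_model(), paths["model"])
    world.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(generate_sirnas(world), paths["sirnas"])
    peaks = generate_peaks(world)
    write_bed(peaks, paths["peaks"])
    write_bed(generate_transposons(world), paths["transposons"])
    sister_genome, (evidence, names), sister_prot = generate_sister(world)
    write_fasta(sister_genome, paths["sister_genome"])
    write_bed(evidence, paths["sister_evidence"], names=names)
    write_fasta(sister_prot, paths["sister_proteome"])
    write_fasta(world.proteome, paths["proteome"])
    return paths
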