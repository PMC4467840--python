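"""Simplified local-alignment machinery and the sister-species conservation
calls built on it.

This module supplies the alignment-shaped steps of the pipeline as compact
in-package equivalents: affine-gap Smith-Waterman local alignment with
Karlin-Altschul e-values, a seed-and-extend transcript-to-genome mapper,
bi-directional best-hit (BDBH) ortholog pairing, an ORF scanner, and the
decision rules for "sequence conserved in the sister genome" (best local hit
below an e-value cutoff in the flank of the orthologous gene) and
"expression conserved" (antisense transcript evidence at the mapped locus
with no long ORF and no sense-direction protein homology).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .intervals import FeatureTrack, GenomicInterval

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


@dataclass
class ScoringScheme:
    """Substitution scores + affine gap penalties + Karlin-Altschul K, lambda.

    Gap cost for a length-L gap is ``gap_open + L * gap_extend`` (both
    penalties positive). Defaults are BLASTN-like ungapped constants for the
    +2/-3 nucleotide scheme; ``protein()`` gives a BLOSUM62 scheme.
    """

    alphabet: str = NT_ALPHABET
    matrix: np.ndarray | None = None
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    K: float = 0.41
    lam: float = 0.625

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")
        if self.matrix is None:
            n = len(self.alphabet)
            m = np.full((n + 1, n + 1), self.mismatch, dtype=float)
            np.fill_diagonal(m, self.match)
            m[n, :] = m[:, n] = self.mismatch  # unknown characters
            self.matrix = m
        self._index = {c: i for i, c in enumerate(self.alphabet)}

    @classmethod
    def protein(cls) -> "ScoringScheme":
        """BLOSUM62 with gapped-BLAST-style penalties (open 11, extend 1) and
        the published gapped constants K=0.041, lambda=0.267."""
        blosum = substitution_matrices.load("BLOSUM62")
        n = len(AA_ALPHABET)
        m = np.full((n + 1, n + 1), -4.0)
        for i, a in enumerate(AA_ALPHABET):
            for j, b in enumerate(AA_ALPHABET):
                try:
                    m[i, j] = blosum[a, b]
                except (KeyError, IndexError):
                    pass
        return cls(alphabet=AA_ALPHABET, matrix=m, gap_open=11.0, gap_extend=1.0,
                   K=0.041, lam=0.267)

    def encode(self, seq: str) -> np.ndarray:
        n = len(self.alphabet)
        return np.array([self._index.get(c, n) for c in seq.upper()], dtype=np.int64)


@dataclass
class LocalHit:
    query: GenomicInterval | None
    target: GenomicInterval | None
    score: float
    e_value: float
    identity: float
    strand: str = "+"
    aligned_query_length: int = 0


def e_value(score: float, m: int, n: int, scoring: ScoringScheme) -> float:
    """Karlin-Altschul expected hit count E = K * m * n * exp(-lambda * S)."""
    return scoring.K * m * n * np.exp(-scoring.lam * score)


def _sw_matrix(a_codes: np.ndarray, b_codes: np.ndarray, scoring: ScoringScheme):
    """Fill the Smith-Waterman H matrix (affine gaps), row-vectorised.

    Horizontal-gap scores within a row are resolved with a prefix-max scan:
    E[j] = max_{j'<j} (H[j'] - open - (j-j')*extend), which only needs H
    values not themselves derived from a horizontal gap (a longer gap is
    always scored at least as well by extension as by re-opening).
    """
    la, lb = len(a_codes), len(b_codes)
    go, ge = scoring.gap_open, scoring.gap_extend
    H = np.zeros((la + 1, lb + 1))
    F = np.full(lb + 1, -np.inf)
    sub = scoring.matrix
    j_idx = np.arange(lb + 1)
    for i in range(1, la + 1):
        srow = sub[a_codes[i - 1]][b_codes]
        diag = H[i - 1, :-1] + srow
        F = np.maximum(H[i - 1] - go - ge, F - ge)
        h0 = np.maximum(F[1:], diag)
        h0 = np.maximum(h0, 0.0)
        h0 = np.concatenate(([0.0], h0))
        T = h0 + j_idx * ge
        prefix = np.maximum.accumulate(T)
        E = np.concatenate(([-np.inf], prefix[:-1])) - go - j_idx * ge
        H[i] = np.maximum(h0, np.maximum(E, 0.0))
    return H


def smith_waterman(a: str, b: str, scoring: ScoringScheme | None = None) -> LocalHit:
    """Optimal affine-gap local alignment of ``a`` vs ``b``.

    Traceback ties prefer diagonal, then up (gap in ``b``), then left (gap in
    ``a``). A score of 0 yields an empty hit (identity 0, no intervals).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    ac, bc = scoring.encode(a), scoring.encode(b)
    H = _sw_matrix(ac, bc, scoring)
    score = float(H.max())
    hit = LocalHit(None, None, score, e_value(score, len(a), len(b), scoring), 0.0)
    if score <= 0:
        return hit
    i, j = np.unravel_index(np.argmax(H), H.shape)
    i, j = int(i), int(j)
    end_i, end_j = i, j
    matches = aligned = 0
    go, ge = scoring.gap_open, scoring.gap_extend
    while i > 0 and j > 0 and H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + scoring.matrix[ac[i - 1], bc[j - 1]]:
            matches += int(ac[i - 1] == bc[j - 1])
            aligned += 1
            i, j = i - 1, j - 1
            continue
        moved = False
        for k in range(1, i + 1):  # up: gap in b
            if H[i, j] == H[i - k, j] - go - k * ge:
                aligned += k
                i -= k
                moved = True
                break
        if moved:
            continue
        for k in range(1, j + 1):  # left: gap in a
            if H[i, j] == H[i, j - k] - go - k * ge:
                aligned += k
                j -= k
                moved = True
                break
        if not moved:
            break
    hit.query = GenomicInterval("query", i, end_i)
    hit.target = GenomicInterval("target", j, end_j)
    hit.identity = matches / aligned if aligned else 0.0
    hit.aligned_query_length = end_i - i
    return hit


# ---------------------------------------------------------------------------
# Seed-and-extend mapping


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class GenomeIndex:
    """Exact k-mer index over a set of named sequences."""

    def __init__(self, seqs: dict[str, str], k: int = 11):
        self.k = k
        self.seqs = seqs
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in seqs.items():
            seq = seq.upper()
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos:pos + k], []).append((name, pos))


def seed_chain_extend_map(
    query: str,
    genome: dict[str, str] | GenomeIndex,
    k: int = 11,
    min_identity: float = 0.90,
    min_coverage: float = 0.50,
    scoring: ScoringScheme | None = None,
    max_candidates: int = 4,
) -> list[LocalHit]:
    """Map a transcript onto a genome: exact k-mer seeds on both strands,
    diagonal clustering, gapped Smith-Waterman extension of the best chains.

    A mapping is accepted iff its identity is >= ``min_identity`` over at
    least ``min_coverage`` of the query length. Hits are returned best-first
    with ``target`` in genome coordinates and ``strand`` giving the query
    orientation.
    """
    query = query.upper()
    if len(query) < k:
        return []
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    scoring = scoring or ScoringScheme()
    candidates: list[tuple[int, str, str, int, int]] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        seeds: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for qpos in range(0, len(qseq) - index.k + 1):
            for name, rpos in index.kmers.get(qseq[qpos:qpos + index.k], ()):
                diag = rpos - qpos
                seeds.setdefault((name, diag // 40), []).append((rpos, qpos))
        for (name, _band), hits in seeds.items():
            rmin = min(r for r, _ in hits)
            rmax = max(r for r, _ in hits) + index.k
            candidates.append((len(hits), strand, name, rmin, rmax))
    candidates.sort(reverse=True)
    if candidates:
        # weak, isolated seed clusters cannot beat the best-seeded chain
        floor = max(2, candidates[0][0] // 5)
        candidates = [c for c in candidates if c[0] >= floor]
    results = []
    seen: set[tuple[str, str, int]] = set()
    for _count, strand, name, rmin, rmax in candidates[:max_candidates]:
        ref = index.seqs[name]
        lo = max(0, rmin - len(query))
        hi = min(len(ref), rmax + len(query))
        key = (strand, name, lo // 50)
        if key in seen:
            continue
        seen.add(key)
        qseq = query if strand == "+" else revcomp(query)
        hit = smith_waterman(qseq, ref[lo:hi], scoring)
        if hit.target is None:
            continue
        if hit.identity >= min_identity and hit.aligned_query_length >= min_coverage * len(query):
            hit.target = GenomicInterval(name, lo + hit.target.start, lo + hit.target.end, strand)
            hit.strand = strand
            hit.e_value = e_value(hit.score, len(query), sum(len(s) for s in index.seqs.values()),
                                  scoring)
            results.append(hit)
            if hit.aligned_query_length >= 0.9 * len(query):
                break  # best-seeded chain already explains the query
    results.sort(key=lambda h: -h.score)
    return results


def bdbh_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    scoring: ScoringScheme | None = None,
) -> list[tuple[str, str]]:
    """Bi-directional best hits between two proteomes.

    (a, b) is reported iff b is a's unique best-scoring protein in B and a is
    b's unique best in A; score ties disqualify a pair.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    scoring = scoring or ScoringScheme.protein()
    names_a, names_b = list(proteome_a), list(proteome_b)
    scores = np.zeros((len(names_a), len(names_b)))
    for i, na in enumerate(names_a):
        for j, nb in enumerate(names_b):
            scores[i, j] = smith_waterman(proteome_a[na], proteome_b[nb], scoring).score

    def unique_argmax(row: np.ndarray) -> int | None:
        best = row.max()
        if best <= 0:
            return None
        idx = np.flatnonzero(row == best)
        return int(idx[0]) if len(idx) == 1 else None

    pairs = []
    best_in_b = [unique_argmax(scores[i]) for i in range(len(names_a))]
    best_in_a = [unique_argmax(scores[:, j]) for j in range(len(names_b))]
    for i, j in enumerate(best_in_b):
        if j is not None and best_in_a[j] == i:
            pairs.append((names_a[i], names_b[j]))
    return pairs


# ---------------------------------------------------------------------------
# ORFs


@dataclass
class Orf:
    start: int        # 0-based offset of the ATG on the scanned strand
    frame: int        # 0-2
    strand: str       # '+' or '-'
    length: int       # codons, excluding the stop


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: str, strands: str = "both") -> list[Orf]:
    """ATG-to-in-frame-stop ORFs; length excludes the stop codon. Codons
    containing N never count as ATG or stop. One (maximal) ORF is reported
    per stop: the one opened by the earliest ATG since the previous stop."""
    seq = seq.upper()
    out = []
    strand_list = {"both": "+-", "sense": "+", "antisense": "-"}[strands]
    for strand in strand_list:
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            open_at = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos:pos + 3]
                if "N" in codon:
                    continue
                if codon in _STOPS:
                    if open_at is not None:
                        out.append(Orf(open_at, frame, strand, (pos - open_at) // 3))
                        open_at = None
                elif codon == "ATG" and open_at is None:
                    open_at = pos
    return out


def max_orf_codons(seq: str, strands: str = "both") -> int:
    orfs = find_orfs(seq, strands)
    return max((o.length for o in orfs), default=0)


# ---------------------------------------------------------------------------
# Sister-genome conservation calls


def pairwise_conservation_call(
    nolp_seq: str,
    sister_region_seq: str,
    scoring: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-10,
) -> bool:
    """Sequence conserved in the sister genome iff the best nucleotide local
    hit of the NOLP against the flank of the orthologous gene has
    e-value < cutoff (both orientations tried)."""
    if not nolp_seq or not sister_region_seq:
        return False
    scoring = scoring or ScoringScheme()
    best = max(
        smith_waterman(nolp_seq, sister_region_seq, scoring).score,
        smith_waterman(revcomp(nolp_seq), sister_region_seq, scoring).score,
    )
    return e_value(best, len(nolp_seq), len(sister_region_seq), scoring) < evalue_cutoff


def protein_homology_coverage(
    nolp_seq: str,
    proteome: dict[str, str],
    scoring: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-4,
    strands: str = "both",
) -> int:
    """Nucleotide bp of the NOLP covered by protein-level local hits
    (six-frame translation by default, best hit per frame x protein,
    e <= cutoff); ``strands='sense'`` restricts to the three forward frames."""
    if not proteome or len(nolp_seq) < 3:
        return 0
    scoring = scoring or ScoringScheme.protein()
    covered: list[GenomicInterval] = []
    L = len(nolp_seq)
    for strand in {"both": "+-", "sense": "+", "antisense": "-"}[strands]:
        s = nolp_seq if strand == "+" else revcomp(nolp_seq)
        for frame in range(3):
            prot = str(Seq(s[frame:frame + 3 * ((len(s) - frame) // 3)]).translate())
            if len(prot) < 5:
                continue
            for pname, pseq in proteome.items():
                if not pseq:
                    continue
                hit = smith_waterman(prot, pseq, scoring)
                if hit.query is None:
                    continue
                if e_value(hit.score, len(prot), len(pseq), scoring) <= evalue_cutoff:
                    nt_start = frame + 3 * hit.query.start
                    nt_end = frame + 3 * hit.query.end
                    if strand == "-":
                        nt_start, nt_end = L - nt_end, L - nt_start
                    covered.append(GenomicInterval("nolp", nt_start, nt_end))
    if not covered:
        return 0
    from .intervals import merge_intervals, total_length

    return total_length(merge_intervals(covered))


@dataclass
class ExpressionCall:
    conserved: bool
    reason: str
    mapped_locus: GenomicInterval | None = None


def call_expression_conservation(
    nat_seq: str,
    sister_genome: dict[str, str] | GenomeIndex,
    sister_evidence: FeatureTrack,
    ortholog_span: GenomicInterval | None,
    proteome: dict[str, str],
    max_orf: int = 100,
    protein_evalue: float = 1e-4,
    mapper_kwargs: dict | None = None,
) -> ExpressionCall:
    """Expression conserved iff the NAT maps into the sister genome and some
    transcript-evidence interval there (i) overlaps the mapped locus antisense
    to the orthologous gene, (ii) has no ORF > ``max_orf`` codons on its sense
    strand, and (iii) has no sense-direction protein homology at
    e <= ``protein_evalue``."""
    if ortholog_span is None:
        return ExpressionCall(False, "no_ortholog")
    index = (sister_genome if isinstance(sister_genome, GenomeIndex)
             else GenomeIndex(sister_genome))
    hits = seed_chain_extend_map(nat_seq, index, **(mapper_kwargs or {}))
    if not hits:
        return ExpressionCall(False, "unmapped")
    locus = hits[0].target
    antisense = "-" if ortholog_span.strand == "+" else "+"
    from .intervals import overlap_bp

    for iv in sister_evidence.intervals:
        if iv.strand != antisense or overlap_bp(iv, locus) == 0:
            continue
        if overlap_bp(iv, ortholog_span) == 0:
            continue
        ev_seq = index.seqs[iv.chrom][iv.start:iv.end]
        if iv.strand == "-":
            ev_seq = revcomp(ev_seq)
        if max_orf_codons(ev_seq, strands="sense") > max_orf:
            continue
        if proteome and protein_homology_coverage(
            ev_seq, proteome, evalue_cutoff=protein_evalue, strands="sense"
        ) > 0:
            continue
        return ExpressionCall(True, "ok", locus)
    return ExpressionCall(False, "no_antisense_evidence", locus)
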