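"""Local alignment, e-values, mapping, orthologs, ORFs, sister-genome calls."""

import numpy as np
import pytest

from natpipe.homology import (
    GenomeIndex,
    ScoringScheme,
    bdbh_orthologs,
    call_expression_conservation,
    e_value,
    find_orfs,
    max_orf_codons,
    pairwise_conservation_call,
    protein_homology_coverage,
    revcomp,
    seed_chain_extend_map,
    smith_waterman,
)
from natpipe.intervals import FeatureTrack, GenomicInterval

from conftest import random_dna

SIMPLE = ScoringScheme(match=1, mismatch=-1, gap_open=0.5, gap_extend=0.5)


def sw_oracle(a, b, scoring):
    """Independent cell-by-cell affine-gap DP (three explicit matrices)."""
    la, lb = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    go, ge = scoring.gap_open, scoring.gap_extend
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - go - ge, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go - ge, F[i - 1][j] - ge)
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identical_sequences(self):
        hit = smith_waterman("ACGT", "ACGT", SIMPLE)
        assert hit.score == 4 and hit.identity == 1.0

    def test_no_positive_alignment(self):
        assert smith_waterman("AAAA", "TTTT", SIMPLE).score == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = random_dna(rng, int(rng.integers(1, 21)))
            b = random_dna(rng, int(rng.integers(1, 21)))
            assert smith_waterman(a, b).score == sw_oracle(a, b, ScoringScheme())

    def test_score_symmetry_and_extension_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = random_dna(rng, int(rng.integers(5, 30)))
            b = random_dna(rng, int(rng.integers(5, 30)))
            s_ab = smith_waterman(a, b).score
            assert s_ab == smith_waterman(b, a).score
            # appending sequence can only add alignment opportunities
            assert smith_waterman(a + "ACGT", b).score >= s_ab
            assert smith_waterman(a, b + "ACGT").score >= s_ab


class TestEValue:
    def test_reference_value(self):
        s = ScoringScheme(K=0.1, lam=1.0)
        assert e_value(30, 100, 100, s) == pytest.approx(9.36e-11, rel=1e-2)

    def test_monotone_in_score(self):
        s = ScoringScheme()
        evs = [e_value(x, 100, 100, s) for x in range(10, 100, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_linear_in_target_length(self):
        s = ScoringScheme()
        assert e_value(30, 100, 200, s) == pytest.approx(2 * e_value(30, 100, 100, s))

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(K=-1.0)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=0)


class TestOrfs:
    def test_minimal_orf(self):
        (orf,) = find_orfs("ATGAAATAA", strands="sense")
        assert orf.length == 2 and orf.start == 0 and orf.frame == 0

    def test_no_atg_no_orf(self):
        assert find_orfs("CCCCCCTAACCC", strands="sense") == []

    def test_101_codon_orf(self):
        seq = "ATG" + "GCA" * 100 + "TAA"
        assert len(seq) == 306
        assert max_orf_codons(seq, strands="sense") == 101

    def test_n_codons_never_start_or_stop(self):
        assert find_orfs("ATNAAATAA", strands="sense") == []
        seq = "ATG" + "AAA" + "TNA" + "AAA" + "TAA"
        (orf,) = find_orfs(seq, strands="sense")
        assert orf.length == 4  # the N-containing codon is not a stop

    def test_reverse_strand_orfs_found(self):
        fwd = "ATGAAATAA"
        assert max_orf_codons(revcomp(fwd), strands="both") == 2
        assert max_orf_codons(revcomp(fwd), strands="sense") == 0


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(10)
    return {"chrA": random_dna(rng, 100_000)}


class TestMapper:
    def test_verbatim_query_recovers_source(self, genome):
        q = genome["chrA"][40_000:40_500]
        (hit,) = seed_chain_extend_map(q, genome)[:1]
        assert hit.target.start == 40_000 and hit.target.end == 40_500
        assert hit.identity == 1.0 and hit.strand == "+"

    def test_reverse_complement_maps_minus(self, genome):
        q = revcomp(genome["chrA"][40_000:40_500])
        (hit,) = seed_chain_extend_map(q, genome)[:1]
        assert hit.target.start == 40_000 and hit.target.end == 40_500
        assert hit.strand == "-"

    def test_mutated_query_recovers_implant(self, genome):
        rng = np.random.default_rng(11)
        q = list(genome["chrA"][70_000:70_600])
        for i in rng.choice(600, size=30, replace=False):
            q[i] = rng.choice([c for c in "ACGT" if c != q[i]])
        hits = seed_chain_extend_map("".join(q), genome)
        assert hits
        assert abs(hits[0].target.start - 70_000) <= 5
        assert abs(hits[0].target.end - 70_600) <= 5
        assert hits[0].identity >= 0.9

    def test_no_seeds_returns_empty(self, genome):
        assert seed_chain_extend_map("ACGTACGTAC", genome, k=11) == []

    def test_random_draws_always_return_source(self, genome):
        index = GenomeIndex(genome)
        rng = np.random.default_rng(12)
        for _ in range(100):
            start = int(rng.integers(0, 99_000))
            length = int(rng.integers(100, 900))
            q = genome["chrA"][start:start + length]
            hits = seed_chain_extend_map(q, index)
            assert hits, f"no hit for draw at {start}"
            assert hits[0].target.start == start
            assert hits[0].target.end == start + length


class TestBdbh:
    def test_identical_proteomes_identity_map(self):
        rng = np.random.default_rng(13)
        prots = {f"p{i}": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 60))
                 for i in range(6)}
        pairs = bdbh_orthologs(prots, {k + "_b": v for k, v in prots.items()})
        assert dict(pairs) == {k: k + "_b" for k in prots}

    def test_tie_excluded(self):
        a = {"a1": "MKLVVAAA"}
        b = {"b1": "MKLVVAAA", "b2": "MKLVVAAA"}
        assert bdbh_orthologs(a, b) == []

    def test_symmetry(self):
        rng = np.random.default_rng(14)
        pa = {f"a{i}": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 50))
              for i in range(4)}
        pb = {f"b{i}": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 50))
              for i in range(4)}
        fwd = set(bdbh_orthologs(pa, pb))
        rev = {(x, y) for y, x in bdbh_orthologs(pb, pa)}
        assert fwd == rev

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            bdbh_orthologs({}, {"b": "MKL"})


class TestPairwiseConservation:
    def test_implanted_sequence_is_conserved(self):
        rng = np.random.default_rng(15)
        nolp = random_dna(rng, 120)
        flank = random_dna(rng, 2000) + nolp + random_dna(rng, 2000)
        assert pairwise_conservation_call(nolp, flank)

    def test_reverse_orientation_also_detected(self):
        rng = np.random.default_rng(16)
        nolp = random_dna(rng, 120)
        flank = random_dna(rng, 1000) + revcomp(nolp) + random_dna(rng, 1000)
        assert pairwise_conservation_call(nolp, flank)

    def test_unrelated_sequences_not_conserved(self):
        rng = np.random.default_rng(17)
        assert not pairwise_conservation_call(random_dna(rng, 200), random_dna(rng, 200))

    def test_empty_flank_false(self):
        assert not pairwise_conservation_call("ACGTACGT", "")


class TestProteinHomology:
    def test_implanted_protein_segment_covered(self):
        rng = np.random.default_rng(18)
        prot = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 60))
        codon = {  # one codon per residue is enough for an exact back-translation
            "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
            "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
            "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
            "Y": "TAT", "V": "GTT",
        }
        nolp = random_dna(rng, 99) + "".join(codon[a] for a in prot) + random_dna(rng, 99)
        covered = protein_homology_coverage(nolp, {"p": prot})
        assert covered >= 180

    def test_random_sequence_uncovered(self):
        rng = np.random.default_rng(19)
        prots = {"p": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 80))}
        assert protein_homology_coverage(random_dna(rng, 300), prots) == 0

    def test_empty_proteome(self):
        assert protein_homology_coverage("ACGTACGTACGT", {}) == 0


class TestExpressionConservation:
    def _setup(self, seed=20, evidence_orf=None):
        rng = np.random.default_rng(seed)
        genome = random_dna(rng, 6000)
        nat = genome[2000:2600]
        ev_seq = evidence_orf
        if ev_seq is not None:
            genome = genome[:2000] + ev_seq + genome[2000 + len(ev_seq):]
            nat = genome[2000:2000 + len(ev_seq)]
        sister = {"s": genome}
        ospan = GenomicInterval("s", 1500, 3000, "-")
        evidence = FeatureTrack(
            "transcript_evidence",
            [GenomicInterval("s", 2000, 2000 + len(nat), "+")],
        )
        return nat, sister, evidence, ospan

    def test_implanted_antisense_evidence_is_conserved(self):
        nat, sister, evidence, ospan = self._setup()
        call = call_expression_conservation(nat, sister, evidence, ospan, {})
        assert call.conserved and call.reason == "ok"

    def test_long_orf_evidence_rejected(self):
        orf = "ATG" + "GCA" * 149 + "TAA"
        nat, sister, evidence, ospan = self._setup(evidence_orf=orf)
        call = call_expression_conservation(nat, sister, evidence, ospan, {})
        assert not call.conserved and call.reason == "no_antisense_evidence"

    def test_no_ortholog_false(self):
        nat, sister, evidence, _ = self._setup()
        call = call_expression_conservation(nat, sister, evidence, None, {})
        assert not call.conserved and call.reason == "no_ortholog"

    def test_no_overlapping_evidence_false(self):
        nat, sister, _, ospan = self._setup()
        empty = FeatureTrack("transcript_evidence", [GenomicInterval("s", 4000, 4200, "+")])
        call = call_expression_conservation(nat, sister, empty, ospan, {})
        assert not call.conserved

    def test_sense_strand_evidence_not_antisense(self):
        nat, sister, _, ospan = self._setup()
        sense = FeatureTrack("transcript_evidence", [GenomicInterval("s", 2000, 2600, "-")])
        call = call_expression_conservation(nat, sister, sense, ospan, {})
        assert not call.conserved
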