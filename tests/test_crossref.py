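"""Hypergeometric tests, siRNA mapping/classification, feature overlap,
report tables."""

import itertools
import math

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import hypergeom as scipy_hypergeom, kstest

from natpipe.crossref import (
    ContingencyCounts,
    ReferenceSet,
    association_test,
    classify_sirna,
    count_feature_overlap,
    hypergeom_logpmf,
    hypergeom_p,
    map_sirnas,
    topology_table,
)
from natpipe.homology import revcomp
from natpipe.intervals import FeatureTrack, GenomicInterval

from conftest import random_dna


class TestHypergeom:
    def test_counts_invariants(self):
        with pytest.raises(ValueError):
            ContingencyCounts(10, 11, 5, 0)
        with pytest.raises(ValueError):
            ContingencyCounts(10, 5, 5, 6)

    def test_single_term_closed_form(self):
        assert hypergeom_p(ContingencyCounts(10, 5, 5, 5)) == pytest.approx(1 / 252)

    def test_matsui_style_counts(self):
        p = hypergeom_p(ContingencyCounts(3172, 1014, 1023, 350), "enrichment")
        assert round(p, 2) == 0.03

    def test_matches_scipy_cross_check(self):
        c = ContingencyCounts(1538, 314, 437, 168)
        assert hypergeom_p(c, "enrichment") == pytest.approx(
            float(scipy_hypergeom.sf(c.k - 1, c.N, c.K, c.n)), rel=1e-9
        )
        assert hypergeom_p(c, "depletion") == pytest.approx(
            float(scipy_hypergeom.cdf(c.k, c.N, c.K, c.n)), rel=1e-9
        )

    def test_tiny_populations_match_literal_sample_enumeration(self):
        """For N <= 7, enumerate every C(N, n) sample explicitly."""
        for N in range(1, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    pop = [1] * K + [0] * (N - K)
                    samples = list(itertools.combinations(range(N), n))
                    ks = [sum(pop[i] for i in s) for s in samples]
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        c = ContingencyCounts(N, K, n, k)
                        enr = sum(1 for x in ks if x >= k) / len(samples)
                        dep = sum(1 for x in ks if x <= k) / len(samples)
                        assert hypergeom_p(c, "enrichment") == pytest.approx(enr, abs=1e-12)
                        assert hypergeom_p(c, "depletion") == pytest.approx(dep, abs=1e-12)

    def test_complement_identity(self):
        """enrichment + depletion = 1 + P(X = k) for all valid counts."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(1, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            c = ContingencyCounts(N, K, n, k)
            pmf = math.exp(hypergeom_logpmf(c, np.array([k]))[0])
            total = hypergeom_p(c, "enrichment") + hypergeom_p(c, "depletion")
            assert total == pytest.approx(1 + pmf, abs=1e-9)


class TestAssociation:
    def test_counts_and_symmetry(self):
        a = [True, True, False, False, True]
        b = [True, False, True, False, True]
        c, p_enr, p_dep = association_test(a, b)
        assert (c.N, c.K, c.n, c.k) == (5, 3, 3, 2)
        c2, p_enr2, p_dep2 = association_test(b, a)
        assert (c2.K, c2.n) == (c.n, c.K)
        assert p_enr == pytest.approx(p_enr2) and p_dep == pytest.approx(p_dep2)

    def test_identical_flags_single_term(self):
        a = [True, True, False, False]
        c, p_enr, _ = association_test(a, a)
        assert c.k == c.K == c.n == 2
        assert p_enr == pytest.approx(1 / 6)  # C(2,2)C(2,0)/C(4,2)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            association_test({"x": True}, {"y": True})
        with pytest.raises(ValueError, match="universes"):
            association_test([True], [True, False])

    def test_independent_flags_give_uniformish_p(self):
        """Calibration of the exact enrichment test under independence,
        checked on the mid-p transform (the standard uniformity check for a
        discrete test statistic)."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            a = rng.random(2000) < 0.3
            b = rng.random(2000) < 0.3
            c, p_enr, p_dep = association_test(list(a), list(b))
            pmf = p_enr + p_dep - 1.0
            ps.append(p_enr - 0.5 * pmf)
        assert kstest(ps, "uniform").pvalue > 0.01


def _refset():
    rng = np.random.default_rng(2)
    gene = random_dna(rng, 400)
    nat = random_dna(rng, 300)
    distal = random_dna(rng, 400)
    return gene, nat, distal, ReferenceSet(
        seqs={"gene1": gene, "nat1": nat, "mrna9": distal},
        nat_regions={"nat1": {"nolp": [(0, 150)], "olp": [(150, 300)]}},
        locus={"nat1": "L1", "gene1": "L1", "mrna9": "L9"},
    )


class TestSirnaMapping:
    def test_unique_forward_nolp_read(self):
        _, nat, _, refs = _refset()
        reads = {"r1": nat[10:31]}
        (m,), skipped = map_sirnas(reads, refs)
        assert skipped == 0
        assert m.unique and m.orientation == "forward"
        assert m.compartment == "NOLP" and m.acting == "cis"

    def test_olp_compartment(self):
        _, nat, _, refs = _refset()
        (m,), _ = map_sirnas({"r": nat[200:222]}, refs)
        assert m.compartment == "OLP"

    def test_two_loci_not_unique(self):
        gene, nat, _, refs = _refset()
        refs.seqs["gene1"] = gene[:100] + nat[10:40] + gene[130:]
        (m,), _ = map_sirnas({"r": nat[10:31]}, refs)
        assert not m.unique and m.compartment is None

    def test_reverse_on_distal_transcript_is_trans(self):
        gene, nat, distal, refs = _refset()
        refs.seqs["mrna9"] = distal[:100] + revcomp(nat[10:31]) + distal[121:]
        (m,), _ = map_sirnas({"r": nat[10:31]}, refs)
        assert m.unique and m.acting == "trans"

    def test_own_locus_reverse_match_stays_cis(self):
        gene, nat, _, refs = _refset()
        refs.seqs["gene1"] = gene[:100] + revcomp(nat[10:31]) + gene[121:]
        (m,), _ = map_sirnas({"r": nat[10:31]}, refs)
        assert m.unique and m.acting == "cis"
        assert classify_sirna(m, ["gene1"], refs) == "cis"
        assert classify_sirna(m, ["mrna9"], refs) == "trans"

    def test_bad_reads_skipped_and_collapsed(self):
        _, nat, _, refs = _refset()
        reads = {"short": "ACGT", "nchar": "N" * 21, "a": nat[10:31], "b": nat[10:31]}
        mappings, skipped = map_sirnas(reads, refs)
        assert skipped == 2
        assert len(mappings) == 1 and mappings[0].copies == 2

    def test_matches_bruteforce_offset_scan(self):
        """Mapping equals an independent sliding-window scan of every offset
        and orientation over a 100-kb reference."""
        rng = np.random.default_rng(3)
        ref = random_dna(rng, 100_000)
        refs = ReferenceSet(seqs={"chr": ref})
        arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        reads = {}
        for i in range(30):  # planted reads
            s = int(rng.integers(0, 99_000))
            L = int(rng.integers(18, 31))
            reads[f"p{i}"] = ref[s:s + L]
        for i in range(20):  # random reads
            reads[f"q{i}"] = random_dna(rng, int(rng.integers(18, 31)))
        mappings, _ = map_sirnas(reads, refs)
        by_seq = {m.seq: m for m in mappings}
        for seq, m in by_seq.items():
            win = sliding_window_view(arr, len(seq))
            fwd = np.flatnonzero(
                (win == np.frombuffer(seq.encode(), dtype=np.uint8)).all(axis=1)
            )
            assert m.unique == (len(fwd) == 1)
            if m.orientation == "forward":
                assert m.offset == int(fwd[0])


class TestFeatureOverlap:
    NOLPS = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]

    def test_peak_spanning_two_nolps_counts_once(self):
        track = FeatureTrack("chip_peak", [GenomicInterval("c", 50, 250)])
        assert count_feature_overlap(self.NOLPS, track, "features") == 1

    def test_disjoint_track_zero(self):
        track = FeatureTrack("chip_peak", [GenomicInterval("c", 400, 500)])
        assert count_feature_overlap(self.NOLPS, track, "features") == 0
        assert count_feature_overlap(self.NOLPS, track, "bp") == 0

    def test_track_equal_to_nolps_covers_all_bp(self):
        track = FeatureTrack("transposon", list(self.NOLPS))
        assert count_feature_overlap(self.NOLPS, track, "bp") == 200

    def test_overlapping_track_intervals_not_double_counted(self):
        track = FeatureTrack(
            "transposon",
            [GenomicInterval("c", 0, 60), GenomicInterval("c", 40, 100)],
        )
        assert count_feature_overlap(self.NOLPS, track, "bp") == 100


class TestReportTables:
    def test_topology_table_rows_sum_to_total(self, demo_records):
        df = topology_table(demo_records)
        per_type = df[df.type != "total"]["n"].sum()
        assert per_type == df[df.type == "total"]["n"].iloc[0] == len(demo_records)

    def test_sirna_partition_between_compartments(self, demo_world, demo_records):
        from natpipe.pipeline import build_reference_set
        from natpipe.synth import generate_sirnas

        refs = build_reference_set(demo_world.genome, demo_world.genes, demo_records)
        mappings, _ = map_sirnas(generate_sirnas(demo_world), refs)
        uniq_nat = [m for m in mappings if m.unique and m.compartment is not None]
        n_nolp = sum(1 for m in uniq_nat if m.compartment == "NOLP")
        n_olp = sum(1 for m in uniq_nat if m.compartment == "OLP")
        n_other = sum(1 for m in uniq_nat if m.compartment == "other")
        assert n_nolp + n_olp + n_other == len(uniq_nat)
        # NAT-located unique reads fall in exactly one of NOLP/OLP
        for m in uniq_nat:
            assert m.compartment in ("NOLP", "OLP", "other")

    def test_order_invariance_of_counts(self):
        _, nat, _, refs = _refset()
        reads = {"a": nat[10:31], "b": nat[40:61], "c": nat[200:221]}
        fwd, _ = map_sirnas(reads, refs)
        rev, _ = map_sirnas(dict(reversed(list(reads.items()))), refs)
        assert {(m.seq, m.compartment) for m in fwd} == {
            (m.seq, m.compartment) for m in rev
        }
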