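"""Synthetic world generator: determinism, geometry, simulation fidelity."""

import filecmp

import numpy as np
import pytest

from natpipe.phylo import NeutralModel, parse_newick, simulate_columns
from natpipe.synth import (
    SynthConfig,
    generate_annotation,
    generate_peaks,
    generate_sirnas,
    generate_sister,
    simulate_alignment,
    truth_nolps,
    write_world,
)
from natpipe.topology import classify_all


class TestDeterminism:
    def test_same_seed_byte_identical_worlds(self, tmp_path):
        cfg = SynthConfig(seed=21, genome_length=60_000, n_genes=12, n_nats=8,
                          n_sirna_reads=60, n_peaks=30, maf_block=3000)
        d1, d2 = tmp_path / "w1", tmp_path / "w2"
        p1 = write_world(generate_annotation(cfg), d1)
        p2 = write_world(generate_annotation(cfg), d2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_differs(self):
        a = generate_annotation(SynthConfig(seed=1, genome_length=60_000,
                                            n_genes=12, n_nats=8))
        b = generate_annotation(SynthConfig(seed=2, genome_length=60_000,
                                            n_genes=12, n_nats=8))
        assert a.genome != b.genome


class TestAnnotation:
    def test_zero_nats_valid_world(self):
        world = generate_annotation(
            SynthConfig(seed=3, genome_length=60_000, n_genes=10, n_nats=0)
        )
        assert world.nats == [] and len(world.genes) == 10
        assert len(world.genome[world.config.chrom]) == 60_000

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            generate_annotation(SynthConfig(seed=4, genome_length=10_000, n_genes=40))

    def test_more_nats_than_genes_raises(self):
        with pytest.raises(ValueError, match="cannot host"):
            generate_annotation(SynthConfig(seed=5, n_genes=5, n_nats=30))

    def test_truth_types_recovered_by_classifier(self, demo_world):
        records = classify_all(demo_world.nats, demo_world.genes)
        truth = dict(zip(demo_world.truth.nat_id, demo_world.truth.intended_type))
        assert all(truth[r.id] == r.topology for r in records)
        assert len(records) == len(demo_world.nats)

    def test_retention_probability_mixture(self):
        cfg = SynthConfig(frac_conserved=0.3, expression_retention=0.3,
                          expression_coupling=4.0)
        q_c, q_u = cfg.retention_probs()
        assert q_c == pytest.approx(4 * q_u)
        assert 0.3 * q_c + 0.7 * q_u == pytest.approx(0.3)


class TestAlignmentSimulation:
    def test_scale_zero_copies_anchor(self, nine_taxon_model):
        rng = np.random.default_rng(6)
        anchor = rng.integers(0, 4, size=100).astype(np.int8)
        sim = simulate_columns(nine_taxon_model, 1e-9, 100, rng,
                               anchor_leaf="focal", anchor_states=anchor)
        for sp, states in sim.items():
            np.testing.assert_array_equal(states, anchor)

    def test_two_leaf_divergence_matches_closed_form(self):
        model = NeutralModel.hky(parse_newick("(A:0.15,B:0.1);"),
                                 np.array([0.3, 0.2, 0.2, 0.3]), 2.0)
        rng = np.random.default_rng(7)
        sim = simulate_columns(model, 1.0, 10_000, rng)
        observed = float((sim["A"] != sim["B"]).mean())
        P = model.transition_matrix(0.25)
        expected = float(1.0 - np.sum(model.pi * np.diag(P)))
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(observed - expected) < 3 * se

    def test_base_composition_reaches_equilibrium(self, nine_taxon_model):
        rng = np.random.default_rng(8)
        sim = simulate_columns(nine_taxon_model, 1.0, 30_000, rng)
        states = np.concatenate(list(sim.values()))
        freqs = np.bincount(states, minlength=4) / len(states)
        np.testing.assert_allclose(freqs, nine_taxon_model.pi, atol=0.01)

    def test_focal_row_equals_genome(self, demo_world):
        blocks = simulate_alignment(demo_world)
        chrom = demo_world.config.chrom
        rebuilt = "".join(b.rows["focal"] for b in blocks)
        assert rebuilt == demo_world.genome[chrom]


class TestTracks:
    def test_sirna_compartment_ratio(self):
        """Without fully-nested NATs, unique mapped reads split OLP:NOLP at
        the configured 9:1 ratio (binomial 99% CI)."""
        from natpipe.crossref import map_sirnas
        from natpipe.pipeline import build_reference_set

        cfg = SynthConfig(seed=9, n_nats=24, n_sirna_reads=1200,
                          sirna_background_frac=0.0,
                          topology_props={1: 0.25, 2: 0.25, 4: 0.25, 5: 0.25})
        world = generate_annotation(cfg)
        records = classify_all(world.nats, world.genes)
        refs = build_reference_set(world.genome, world.genes, records)
        mappings, _ = map_sirnas(generate_sirnas(world), refs)
        uniq = [m for m in mappings if m.unique and m.compartment in ("NOLP", "OLP")]
        # weight by read copies: the binomial CI describes the raw draws,
        # before identical sequences are collapsed
        n_olp = sum(m.copies for m in uniq if m.compartment == "OLP")
        n = sum(m.copies for m in uniq)
        p_hat = n_olp / n
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(p_hat - 0.9) < 2.58 * se

    def test_q_zero_no_evidence(self):
        cfg = SynthConfig(seed=10, n_nats=10, expression_retention=0.0)
        world = generate_annotation(cfg)
        assert not world.truth.expressed_in_sister.any()
        _, (evidence, names), _ = generate_sister(world)
        assert evidence == [] and names == []

    def test_peaks_enriched_in_promoters(self):
        cfg = SynthConfig(seed=12, n_peaks=400, promoter_frac=0.8)
        world = generate_annotation(cfg)
        peaks = generate_peaks(world)
        win = cfg.promoter_window + max(cfg.peak_length)
        prom = 0
        for p in peaks:
            for g in world.genes:
                tss = g.span.start if g.strand == "+" else g.span.end
                if abs((p.start + p.end) // 2 - tss) <= win:
                    prom += 1
                    break
        # promoters cover ~6% of this genome, yet most peaks sit there
        assert prom / len(peaks) > 0.5

    def test_transposons_depleted_in_conserved_nolps(self):
        from natpipe.crossref import count_feature_overlap
        from natpipe.intervals import FeatureTrack
        from natpipe.synth import generate_transposons

        cfg = SynthConfig(seed=13, n_nats=60, n_genes=80, genome_length=500_000,
                          frac_conserved=0.5, n_background_te=0,
                          te_prob_conserved=0.05, te_prob_unconserved=0.8)
        world = generate_annotation(cfg)
        track = FeatureTrack("transposon", generate_transposons(world))
        nolps = truth_nolps(world)
        conserved = dict(zip(world.truth.nat_id, world.truth.conserved))
        cons_nolps = [iv for nid, ivs in nolps.items() if conserved[nid] for iv in ivs]
        unc_nolps = [iv for nid, ivs in nolps.items() if not conserved[nid] for iv in ivs]
        bp_c = count_feature_overlap(cons_nolps, track, "bp")
        bp_u = count_feature_overlap(unc_nolps, track, "bp")
        frac_c = bp_c / max(1, sum(len(i) for i in cons_nolps))
        frac_u = bp_u / max(1, sum(len(i) for i in unc_nolps))
        assert frac_c < frac_u


class TestSister:
    def test_divergence_near_configured_level(self, demo_world):
        sister, _, _ = generate_sister(demo_world)
        chrom = demo_world.config.chrom
        focal = demo_world.genome[chrom]
        s = sister["sister_" + chrom]
        diffs = sum(a != b for a, b in zip(focal, s)) / len(focal)
        model = demo_world.config.neutral_model()
        P = model.transition_matrix(demo_world.config.sister_divergence)
        expected = float(1.0 - np.sum(model.pi * np.diag(P)))
        # CDS stop-repair keeps a few extra sites identical
        assert 0.5 * expected < diffs < 1.2 * expected

    def test_sister_proteins_alignable_to_focal(self, demo_world):
        _, _, sprot = generate_sister(demo_world)
        assert set(sprot) == {g + "_sister" for g in demo_world.proteome}
        for gid, prot in demo_world.proteome.items():
            assert "*" not in sprot[gid + "_sister"]
            assert len(sprot[gid + "_sister"]) == len(prot)
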