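"""Generators: Balding-Nichols frequencies, Wright-Fisher sweeps, annotations."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from sweepset import (
    SimulationConfig,
    ValidationError,
    generate_annotation_bundle,
    simulate_divergence_freqs,
    simulate_polygenic_study,
    simulate_sweep_panel,
)
from sweepset.synthetic import SweepLostError


class TestDivergenceFreqs:
    def test_zero_F_reproduces_ancestral_frequency(self):
        cfg = SimulationConfig(n_snps=200, divergence_F=(0.0, 0.0), rng_seed=1)
        freqs = simulate_divergence_freqs(cfg)
        np.testing.assert_array_equal(freqs["p_POP1"], freqs["p_anc"])
        np.testing.assert_array_equal(freqs["p_POP2"], freqs["p_anc"])

    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(n_snps=300, rng_seed=9)
        a = simulate_divergence_freqs(cfg)
        b = simulate_divergence_freqs(cfg)
        assert a.equals(b)

    def test_degenerate_F_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(divergence_F=(1.0, 0.05))

    def test_second_moment_matches_balding_nichols(self):
        # E[(p1-p2)^2] = (F1+F2) * E[p(1-p)]; under Uniform(0.05, 0.95),
        # E[p(1-p)] = 0.25 - 0.81/12 = 0.1825
        f = 0.05
        cfg = SimulationConfig(n_snps=20_000, divergence_F=(f, f), rng_seed=3)
        freqs = simulate_divergence_freqs(cfg)
        diff2 = (freqs["p_POP1"] - freqs["p_POP2"]) ** 2
        expected = 2 * f * 0.1825
        mc_se = diff2.std() / np.sqrt(len(diff2))
        assert abs(diff2.mean() - expected) < 4 * mc_se

    def test_monomorphic_flagging(self):
        cfg = SimulationConfig(
            n_snps=2000, n_diploids=5, divergence_F=(0.4, 0.4), rng_seed=2
        )
        freqs = simulate_divergence_freqs(cfg)
        for pop in ("POP1", "POP2"):
            counts = freqs[f"count_{pop}"]
            poly = freqs[f"poly_{pop}"]
            assert ((counts > 0) & (counts < 10)).equals(poly)
            assert (~poly).sum() > 0  # strong drift + small sample fixes some


SMALL_WF = SimulationConfig(
    n_snps=80,
    n_diploids=30,
    recomb_rate=50.0,
    n_generations=40,
    rng_seed=0,
)


class TestSweepPanel:
    def test_same_seed_identical_matrix(self):
        cfg = replace(SMALL_WF, rng_seed=4)
        a, _ = simulate_sweep_panel(cfg)
        b, _ = simulate_sweep_panel(cfg)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_neutral_site_is_martingale(self):
        # with s = 0 the derived frequency is a martingale: the replicate
        # mean of the final frequency matches the initial frequency
        finals, inits = [], []
        for seed in range(60):
            cfg = replace(
                SMALL_WF, rng_seed=seed, sweep_site=40, sweep_init_freq=0.3,
                sweep_origin="multiple",
            )
            _, rec = simulate_sweep_panel(cfg)
            finals.append(rec.final_freq)
            inits.append(rec.initial_freq)
        finals = np.asarray(finals)
        mc_se = finals.std() / np.sqrt(finals.size)
        assert abs(finals.mean() - np.mean(inits)) < 4 * max(mc_se, 1e-3)

    def test_hard_sweep_reaches_fixation(self):
        cfg = replace(
            SMALL_WF, rng_seed=8, sweep_site=40,
            selection_coefficient=0.2, sweep_mode="hard", n_generations=400,
        )
        panel, rec = simulate_sweep_panel(cfg)
        assert rec.final_freq == 1.0
        assert panel.for_population("POP1").matrix[:, 40].min() == 1

    def test_incomplete_sweep_stops_at_target(self):
        cfg = replace(
            SMALL_WF, rng_seed=8, sweep_site=40,
            selection_coefficient=0.2, sweep_mode="incomplete",
            sweep_target_freq=0.6, n_generations=400,
        )
        _, rec = simulate_sweep_panel(cfg)
        assert 0.6 <= rec.final_freq < 1.0
        assert rec.n_generations_run < 400

    def test_lost_allele_exhausts_retries(self):
        cfg = replace(
            SMALL_WF, rng_seed=1, sweep_site=40,
            selection_coefficient=1e-6, sweep_mode="hard",
            sweep_init_freq=0.0, n_generations=3, max_sweep_retries=3,
        )
        with pytest.raises(SweepLostError):
            simulate_sweep_panel(cfg)

    def test_polarity_and_population_structure(self):
        panel, _ = simulate_sweep_panel(replace(SMALL_WF, rng_seed=2))
        assert set(np.unique(panel.matrix)) <= {0, 1}
        assert panel.populations == ["POP1", "POP2"]
        assert panel.for_population("POP1").n_haplotypes == 60
        assert np.all(np.diff(panel.pos) > 0)


class TestAnnotationBundle:
    @pytest.fixture(scope="class")
    def sweep_panel(self):
        cfg = replace(
            SMALL_WF, n_snps=200, rng_seed=6, sweep_site=100,
            selection_coefficient=0.2, sweep_mode="hard", n_generations=400,
        )
        panel, rec = simulate_sweep_panel(cfg)
        return cfg, panel, rec

    def test_planted_set_covers_sweep_gene(self, sweep_panel):
        cfg, panel, rec = sweep_panel
        bundle = generate_annotation_bundle(cfg, panel, rec)
        assert bundle.planted_set == "planted"
        flank = 25_000
        in_window = [
            g.gene_id
            for g in bundle.genes
            if g.union_interval[0] <= rec.position + flank
            and g.union_interval[1] >= rec.position - flank
        ]
        assert in_window  # the sweep window always overlaps tiling genes
        assert set(in_window) <= bundle.gene_sets["planted"]

    def test_full_overlap_pair_identical(self, sweep_panel):
        cfg, panel, rec = sweep_panel
        bundle = generate_annotation_bundle(
            cfg, panel, rec, overlap_pairs=[1.0]
        )
        assert bundle.gene_sets["ovlA0"] == bundle.gene_sets["ovlB0"]

    def test_requested_jaccard_realized_within_rounding(self, sweep_panel):
        cfg, panel, rec = sweep_panel
        k, target = 20, 0.5
        bundle = generate_annotation_bundle(
            cfg, panel, rec, n_genes=100, set_size=k, overlap_pairs=[target]
        )
        a, b = bundle.gene_sets["ovlA0"], bundle.gene_sets["ovlB0"]
        realized = len(a & b) / len(a | b)
        shared = round(2 * k * target / (1 + target))
        assert realized == pytest.approx(shared / (2 * k - shared))
        assert abs(realized - target) < 0.05

    def test_union_interval_spans_isoforms(self, sweep_panel):
        cfg, panel, rec = sweep_panel
        bundle = generate_annotation_bundle(cfg, panel, rec)
        for g in bundle.genes:
            start, end = g.union_interval
            assert start == min(s for s, _ in g.isoforms)
            assert end == max(e for _, e in g.isoforms)
            assert 1 <= len(g.isoforms) <= 3

    def test_oversized_set_request_rejected(self, sweep_panel):
        cfg, panel, rec = sweep_panel
        with pytest.raises(ValidationError):
            generate_annotation_bundle(cfg, panel, rec, n_genes=10, set_size=11)


class TestPolygenicStudy:
    def test_chromosomes_sweeps_and_planted_set(self):
        cfg = replace(
            SMALL_WF, n_snps=150, rng_seed=3, sweep_site=75,
            selection_coefficient=0.3, sweep_mode="incomplete",
            sweep_target_freq=0.8, n_generations=300,
        )
        panel, bundle, records = simulate_polygenic_study(
            cfg, n_chromosomes=2, n_genes_per_chrom=20, n_sets=8, set_size=10,
        )
        assert list(dict.fromkeys(panel.chrom)) == ["1", "2"]
        assert len(records) == 2
        planted = bundle.gene_sets[bundle.planted_set]
        for rec in records:
            covering = {
                g.gene_id
                for g in bundle.genes
                if g.chrom == rec.chrom
                and g.union_interval[0] <= rec.position <= g.union_interval[1]
            }
            assert covering <= planted

    def test_deterministic(self):
        cfg = replace(SMALL_WF, n_snps=100, rng_seed=5)
        pa, ba, _ = simulate_polygenic_study(
            cfg, n_chromosomes=2, n_genes_per_chrom=15, n_sets=5, set_size=8
        )
        pb, bb, _ = simulate_polygenic_study(
            cfg, n_chromosomes=2, n_genes_per_chrom=15, n_sets=5, set_size=8
        )
        np.testing.assert_array_equal(pa.matrix, pb.matrix)
        assert ba.gene_sets == bb.gene_sets
        assert ba.disease_genes == bb.disease_genes
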