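"""Cross-population composite-likelihood scan: model, filter, and scan."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import truncnorm

from sweepset import (
    SimulationConfig,
    ValidationError,
    XpclrModelConfig,
    estimate_drift,
    polymorphic_filter,
    simulate_divergence_freqs,
    simulate_sweep_panel,
    sweep_density,
    window_composite_loglik,
    xpclr_scan,
)
from sweepset.xpclr import _window_logliks

# density of the sweep mixture at p1=0.9 for (p2, omega, c) = (0.5, 0.05, 0.5),
# frozen from an independent oracle: central finite difference of the mixture
# CDF assembled from scipy.stats.truncnorm.cdf
ORACLE_DENSITY_09 = 0.09749858


def freq_table(snps, freqs):
    return pd.DataFrame({"snp": snps, "freq": freqs})


class TestPolymorphicFilter:
    def test_fixed_in_reference_dropped(self):
        obj = freq_table(["a", "b"], [0.5, 0.5])
        ref = freq_table(["a", "b"], [1.0, 0.5])
        assert list(polymorphic_filter(obj, ref)) == ["b"]

    def test_all_polymorphic_identity(self):
        obj = freq_table(list("abc"), [0.2, 0.5, 0.9])
        ref = freq_table(list("abc"), [0.3, 0.6, 0.8])
        assert list(polymorphic_filter(obj, ref)) == list("abc")

    def test_toy_five_snps_three_retained(self):
        obj = freq_table(list("abcde"), [0.0, 0.5, 0.4, 0.7, 0.2])
        ref = freq_table(list("abcde"), [0.5, 0.3, 0.2, 0.8, 1.0])
        assert list(polymorphic_filter(obj, ref)) == list("bcd")

    def test_nothing_retained_is_error(self):
        obj = freq_table(["a"], [1.0])
        ref = freq_table(["a"], [0.5])
        with pytest.raises(ValidationError):
            polymorphic_filter(obj, ref)


class TestEstimateDrift:
    def test_hand_arithmetic(self):
        obj = freq_table(["a", "b"], [0.6, 0.4])
        ref = freq_table(["a", "b"], [0.5, 0.5])
        retained = pd.Index(["a", "b"], name="snp")
        # (0.01/0.25 + 0.01/0.25) / 2 = 0.04
        assert estimate_drift(obj, ref, retained) == pytest.approx(0.04)

    def test_zero_differentiation_floored(self):
        obj = freq_table(["a", "b"], [0.4, 0.6])
        ref = freq_table(["a", "b"], [0.4, 0.6])
        retained = pd.Index(["a", "b"], name="snp")
        assert estimate_drift(obj, ref, retained) == 1e-4

    def test_balding_nichols_matches_analytic_expectation(self):
        # closed-form E[(p1-p2)^2 / (p2(1-p2))] under the Balding-Nichols
        # model via Beta moments, integrated over the Uniform(0.05, 0.95)
        # ancestral prior by quadrature. F = 0.02 keeps the Beta shape
        # parameters > 1 over the whole prior support, so the inverse
        # moments exist (at larger F the expectation diverges near the
        # prior's lower edge).
        f1 = f2 = 0.02
        cfg = SimulationConfig(
            n_snps=40_000, divergence_F=(f1, f2), rng_seed=11
        )
        freqs = simulate_divergence_freqs(cfg)
        p1, p2 = freqs["p_POP1"].to_numpy(), freqs["p_POP2"].to_numpy()
        ratio = (p1 - p2) ** 2 / (p2 * (1 - p2))
        est = ratio.mean()
        mc_se = ratio.std() / np.sqrt(ratio.size)

        def integrand(p):
            a = p * (1 - f2) / f2
            b = (1 - p) * (1 - f2) / f2
            inv_v = (a + b - 1) * (a + b - 2) / ((a - 1) * (b - 1))
            inv_1mp = (a + b - 1) / (b - 1)
            p_over = a / (b - 1)
            m2_p1 = p**2 + f1 * p * (1 - p)
            # E[(p1-p2)^2/(p2(1-p2)) | p] with p1, p2 independent given p
            return (
                m2_p1 * inv_v - 2 * p * inv_1mp + p_over
            ) / (0.95 - 0.05)

        expected, _ = quad(integrand, 0.05, 0.95, limit=200)
        assert abs(est - expected) < 4 * mc_se


class TestSweepDensity:
    def test_frozen_quadrature_oracle_point(self):
        dens = float(sweep_density(0.9, 0.5, 0.05, 0.5))
        assert dens == pytest.approx(ORACLE_DENSITY_09, abs=5e-8)

    def test_cdf_difference_oracle(self):
        # independent oracle: finite difference of the mixture CDF built
        # from scipy's truncated-normal CDF
        p2, omega, c = 0.3, 0.2, 0.4
        sd = np.sqrt(omega * p2 * (1 - p2))
        a, b = (0 - p2) / sd, (1 - p2) / sd

        def cdf(x):
            return p2 * truncnorm.cdf(
                (x - (1 - c)) / c, a, b, loc=p2, scale=sd
            ) + (1 - p2) * truncnorm.cdf(x / c, a, b, loc=p2, scale=sd)

        for p1 in (0.05, 0.25, 0.7, 0.9):
            h = 1e-6
            oracle = (cdf(p1 + h) - cdf(p1 - h)) / (2 * h)
            assert float(sweep_density(p1, p2, omega, c)) == pytest.approx(
                oracle, abs=1e-5
            )

    @pytest.mark.parametrize("p2", [0.2, 0.5, 0.7])
    @pytest.mark.parametrize("omega", [0.05, 0.2])
    @pytest.mark.parametrize("c", [0.2, 0.5, 1.0])
    def test_integrates_to_one(self, p2, omega, c):
        val, _ = quad(
            lambda x: float(sweep_density(x, p2, omega, c)), 0, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_c_equal_one_recovers_neutral(self):
        p1 = np.linspace(0.01, 0.99, 23)
        neutral = sweep_density(p1, 0.4, 0.1, 1.0)
        sd = np.sqrt(0.1 * 0.4 * 0.6)
        a, b = (0 - 0.4) / sd, (1 - 0.4) / sd
        expected = truncnorm.pdf(p1, a, b, loc=0.4, scale=sd)
        np.testing.assert_allclose(neutral, expected, rtol=1e-9)


class TestWindowLoglik:
    def test_q_zero_collapses_to_neutral(self, rng):
        n = 12
        p1 = rng.uniform(0.1, 0.9, n)
        p2 = rng.uniform(0.1, 0.9, n)
        r = rng.uniform(0, 0.05, n)
        w = rng.uniform(0.2, 1.0, n)
        ll_q0 = window_composite_loglik(p1, p2, r, w, 0.1, 0.0)
        neutral = sum(
            w[k] * np.log(float(sweep_density(p1[k], p2[k], 0.1, 1.0)))
            for k in range(n)
        )
        assert ll_q0 == pytest.approx(neutral, rel=1e-12)

    def test_vectorized_path_matches_scalar(self, rng):
        n = 10
        p1 = rng.uniform(0.05, 0.95, n)
        p2 = rng.uniform(0.05, 0.95, n)
        r = rng.uniform(0, 0.05, n)
        w = rng.uniform(0.2, 1.0, n)
        q_grid = np.array([0.0, 1e-3, 1e-2, 1e-1])
        vec = _window_logliks(p1, p2, r, w, 0.15, q_grid, -20.0)
        scalar = [
            window_composite_loglik(p1, p2, r, w, 0.15, q) for q in q_grid
        ]
        np.testing.assert_allclose(vec, scalar, rtol=1e-9)

    def test_negative_q_rejected(self):
        with pytest.raises(ValidationError):
            window_composite_loglik(
                np.array([0.5]), np.array([0.5]), np.array([0.0]),
                np.array([1.0]), 0.1, -1.0,
            )


@pytest.fixture(scope="module")
def small_scan():
    cfg = SimulationConfig(
        n_snps=400, n_diploids=60, recomb_rate=10.0,
        founder_switch_rate=300.0, n_generations=60, rng_seed=5,
    )
    panel, _ = simulate_sweep_panel(cfg)
    ft1 = panel.frequency_table("POP1")
    ft2 = panel.frequency_table("POP2")
    return panel, ft1, ft2


class TestXpclrScan:
    def test_scores_nonnegative_and_normalized(self, small_scan):
        panel, ft1, ft2 = small_scan
        grid, snps = xpclr_scan(ft1, ft2, panel.for_population("POP2"))
        assert (grid["score"].dropna() >= -1e-9).all()
        assert snps["score_norm"].mean() == pytest.approx(0.0, abs=1e-9)
        assert snps["score_norm"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_q_grid_only_zero_gives_zero_scores(self, small_scan):
        panel, ft1, ft2 = small_scan
        cfg = XpclrModelConfig(q_grid=np.array([0.0]))
        grid, _ = xpclr_scan(ft1, ft2, panel.for_population("POP2"), cfg)
        assert np.allclose(grid["score"].dropna(), 0.0)

    def test_input_row_order_irrelevant(self, small_scan):
        panel, ft1, ft2 = small_scan
        grid_a, snps_a = xpclr_scan(ft1, ft2, panel.for_population("POP2"))
        perm = np.random.default_rng(3).permutation(len(ft1))
        grid_b, snps_b = xpclr_scan(
            ft1.iloc[perm].reset_index(drop=True),
            ft2.iloc[perm].reset_index(drop=True),
            panel.for_population("POP2"),
        )
        pd.testing.assert_frame_equal(grid_a, grid_b)
        merged = snps_a.merge(snps_b, on="snp", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["score_norm_a"], merged["score_norm_b"], atol=1e-9
        )
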