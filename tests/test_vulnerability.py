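"""Vulnerability response functions, their inverses, and Bayesian curve fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soxplus import (
    VulnCurveObs,
    VulnParams,
    compare_formulations,
    fit_vuln_curve,
    knorm_eval,
    merge_posteriors,
    plc_knorm_convert,
    psi_at_knorm,
)

WB = VulnParams("WB", -3.01, 2.85)
SE = VulnParams("SE", -2.6, 2.85)
SOXF = VulnParams("SOXf", -2.6, 2.85)


class TestKnormEval:
    @pytest.mark.parametrize(
        "psi, params, expected, tol",
        [
            (0.0, WB, 1.0, 1e-12),                    # no loss at zero tension
            (-3.01, WB, np.exp(-1.0), 1e-9),          # reference-potential definition
            (-2.6, SOXF, 0.5, 1e-12),                 # psi50 definition
            (-2.647, WB, 0.500, 5e-4),                # bisection on the closed form
        ],
    )
    def test_reference_values(self, psi, params, expected, tol):
        assert knorm_eval(psi, params) == pytest.approx(expected, abs=tol)

    def test_positive_psi_rejected(self):
        with pytest.raises(ValueError):
            knorm_eval(0.5, WB)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            VulnParams("WB", -np.inf, 2.85)

    @pytest.mark.parametrize("params", [WB, SE, SOXF], ids=lambda p: p.formulation)
    def test_bounded_monotone_vanishing(self, params):
        """k_norm lies in [0,1], decreases with tension, and vanishes at extreme
        tension (the power-law tail of the sigmoidal form decays slowest)."""
        psi = -np.linspace(0.0, 50.0, 600)
        k = knorm_eval(psi, params)
        assert np.all((k >= 0.0) & (k <= 1.0))
        assert np.all(np.diff(k) <= 1e-12)  # psi decreasing along the grid
        assert k[-1] < 1e-3

    def test_wb_exact_unity_at_zero(self):
        assert knorm_eval(0.0, WB) == 1.0


class TestPsiAtKnorm:
    @pytest.mark.parametrize(
        "target, params, expected",
        [
            (0.5, SOXF, -2.6),
            (np.exp(-1.0), WB, -3.01),
            (0.5, WB, -3.01 * np.log(2.0) ** (1.0 / 2.85)),
        ],
    )
    def test_closed_forms(self, target, params, expected):
        assert psi_at_knorm(target, params) == pytest.approx(expected, abs=1e-9)

    def test_wb_psi50_near_reported_value(self):
        # half-loss potential from the combined-posterior medians lands near -2.6 MPa
        assert psi_at_knorm(0.5, WB) == pytest.approx(-2.65, abs=0.05)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, target):
        with pytest.raises(ValueError):
            psi_at_knorm(target, WB)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        target=st.floats(0.01, 0.99),
        form=st.sampled_from(["WB", "SE", "SOXf"]),
        p=st.floats(-3.4, -1.6),
        a=st.floats(1.2, 7.5),
    )
    def test_exact_inverse_roundtrip(self, target, form, p, a):
        """psi_at_knorm inverts knorm_eval to 1e-8 MPa over the parameter box."""
        params = VulnParams(form, p, a)
        psi = psi_at_knorm(target, params)
        if psi <= 0:  # SE inverse can cross zero for near-unity targets
            back = psi_at_knorm(float(knorm_eval(psi, params)), params)
            assert back == pytest.approx(psi, abs=1e-8)


class TestPlcConversion:
    def test_round_trip_involution(self):
        plc = np.linspace(0.0, 100.0, 11)
        back = plc_knorm_convert(plc_knorm_convert(plc, "to_knorm"), "to_plc")
        np.testing.assert_allclose(back, plc, atol=1e-12)

    @pytest.mark.parametrize("k, plc", [(1.0, 0.0), (0.5, 50.0), (0.63, 37.0)])
    def test_values(self, k, plc):
        assert plc_knorm_convert(k, "to_plc") == pytest.approx(plc)
        assert plc_knorm_convert(plc, "to_knorm") == pytest.approx(k)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            plc_knorm_convert(101.0, "to_knorm")
        with pytest.raises(ValueError):
            plc_knorm_convert(1.2, "to_plc")


def _synthetic_curve(rng, psi_ref=-3.0, a=2.8, sigma=3.0, sample_id="S"):
    psi = -np.arange(0.5, 5.0, 0.5)
    params = VulnParams("WB", psi_ref, a)
    plc = 100.0 * (1.0 - knorm_eval(psi, params))
    plc = np.clip(plc + rng.normal(0.0, sigma, psi.size), 0.0, 100.0)
    return VulnCurveObs(psi, plc, sample_id=sample_id)


class TestFitVulnCurve:
    def test_posterior_covers_truth_and_converges(self, rng):
        obs = _synthetic_curve(rng)
        post = fit_vuln_curve(obs, "WB", n_iterations=8000, n_burn=4000, seed=5)
        s = post.summary()
        assert s["psi_ref"]["q2.5"] <= -3.0 <= s["psi_ref"]["q97.5"]
        assert s["a_coef"]["q2.5"] <= 2.8 <= s["a_coef"]["q97.5"]
        assert np.all(post.diagnostics["gelman_rubin"] < 1.05)

    def test_degenerate_curve_rejected(self):
        obs = VulnCurveObs(-np.array([0.5, 1.0, 1.5, 2.0]), np.zeros(4))
        with pytest.raises(ValueError, match="degenerate"):
            fit_vuln_curve(obs)

    def test_seed_reproducibility(self, rng):
        obs = _synthetic_curve(rng)
        a = fit_vuln_curve(obs, "WB", n_iterations=2000, n_burn=1000, seed=3)
        b = fit_vuln_curve(obs, "WB", n_iterations=2000, n_burn=1000, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_credible_interval_coverage_over_replicates(self):
        """Over 20 seeded synthetic curves, >= 90% of 95% CIs contain the truth."""
        rng = np.random.default_rng(777)
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            obs = _synthetic_curve(rng, sample_id=f"S{i}")
            post = fit_vuln_curve(obs, "WB", n_iterations=6000, n_burn=3000, seed=100 + i)
            q = np.percentile(post.samples, [2.5, 97.5], axis=0)
            hits += int(q[0, 0] <= -3.0 <= q[1, 0]) + int(q[0, 1] <= 2.8 <= q[1, 1])
        assert hits / (2 * n_rep) >= 0.9


class TestMergePosteriors:
    def test_combined_size_and_medians(self, rng):
        posts = [
            fit_vuln_curve(_synthetic_curve(rng, sample_id=f"S{i}"), "WB",
                           n_iterations=3000, n_burn=1500, seed=i)
            for i in range(5)
        ]
        merged = merge_posteriors(posts, n_per_curve=1000, seed=0)
        assert merged.samples.shape == (5000, 2)
        med = np.median(merged.samples, axis=0)
        individual = np.array([np.median(p.samples, axis=0) for p in posts])
        assert np.all(med >= individual.min(axis=0) - 1e-9)
        assert np.all(med <= individual.max(axis=0) + 1e-9)

    def test_point_mass_identity(self):
        from soxplus import VulnPosterior

        point = np.tile([-3.0, 2.8], (50, 1))
        posts = [VulnPosterior("WB", point.copy()) for _ in range(5)]
        merged = merge_posteriors(posts, seed=1)
        assert np.all(merged.samples == [-3.0, 2.8])

    def test_mixed_formulations_rejected(self, rng):
        from soxplus import VulnPosterior

        a = VulnPosterior("WB", np.tile([-3.0, 2.8], (10, 1)))
        b = VulnPosterior("SE", np.tile([-2.6, 2.8], (10, 1)))
        with pytest.raises(ValueError, match="mixed"):
            merge_posteriors([a, b])


class TestCompareFormulations:
    def test_wb_ranked_first_on_wb_generated_curves(self):
        rng = np.random.default_rng(42)
        curves = [_synthetic_curve(rng, sigma=1.0, sample_id=f"S{i}") for i in range(3)]
        ranking = compare_formulations(curves, n_iterations=5000, n_burn=2500, seed=2)
        assert ranking[0]["formulation"] == "WB"
        assert ranking[0]["rmse"] <= ranking[-1]["rmse"]
        assert 0.9 <= ranking[0]["pseudo_r2"] <= 1.0

    def test_merged_wb_psi50_recovers_generation(self):
        """Merged WB fit of curves generated near psi50 -2.6 lands in [-2.7, -2.5]."""
        rng = np.random.default_rng(9)
        # psi_ref chosen so the WB half-loss point sits at -2.6 MPa
        psi_ref = -2.6 / np.log(2.0) ** (1.0 / 2.8)
        curves = [
            _synthetic_curve(rng, psi_ref=psi_ref, a=2.8, sigma=2.0, sample_id=f"S{i}")
            for i in range(5)
        ]
        posts = [
            fit_vuln_curve(c, "WB", n_iterations=5000, n_burn=2500, seed=20 + i)
            for i, c in enumerate(curves)
        ]
        merged = merge_posteriors(posts, seed=3)
        psi50 = psi_at_knorm(0.5, merged.median_params)
        assert -2.7 <= psi50 <= -2.5
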