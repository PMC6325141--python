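import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import crickspace as cs
from crickspace.fitness import (
    FitnessSpec,
    cm_from_constants,
    cm_per_mrna,
    curvature_from_rates,
    is_selectable,
    mean_fitness,
    noise_load,
    optimal_rates,
    predict_k,
    q_max,
    transcription_cost,
)


def random_spec(rng, alpha_m=5.1):
    return FitnessSpec(
        f_max=0.1,
        p_star=10 ** rng.uniform(2, 5),
        curvature=-(10 ** rng.uniform(-9, -6)),
        c_m=10 ** rng.uniform(-10, -8),
        l_m=1300.0,
        alpha_m=alpha_m,
    )


class TestCosts:
    def test_zero_transcription_costs_nothing(self):
        assert transcription_cost(0.0, 1300.0, 1e-9) == 0.0

    def test_typical_yeast_gene(self):
        # c_m = 1e-9 /nt, 1300 nt transcribed 30 times per hour
        assert transcription_cost(30.0, 1300.0, 1e-9) == pytest.approx(3.9e-5)
        assert transcription_cost(30.0, 1300.0, 1e-9) == pytest.approx(4e-5, rel=0.05)

    def test_linearity(self):
        base = transcription_cost(3.0, 100.0, 1e-9)
        assert transcription_cost(6.0, 100.0, 1e-9) == pytest.approx(2 * base)
        assert transcription_cost(3.0, 200.0, 1e-9) == pytest.approx(2 * base)
        assert transcription_cost(3.0, 100.0, 2e-9) == pytest.approx(2 * base)

    def test_cm_from_yeast_constants(self, yeast):
        c_m = cm_from_constants(yeast.mu, yeast.total_transcription, yeast.l_m)
        assert c_m == pytest.approx(0.42 / (1300.0 * 3.06e5), rel=1e-9)
        # the organism-level estimate matches the experimental 1.2e-9 /nt
        # within the stated measurement uncertainty of +-1e-9
        assert abs(c_m - 1.2e-9) < 1e-9

    def test_cm_linearity_in_mu(self):
        assert cm_from_constants(0.8, 1e5, 1e3) == pytest.approx(
            2 * cm_from_constants(0.4, 1e5, 1e3)
        )

    def test_cm_per_mrna_e_coli(self, ecoli):
        assert cm_per_mrna(ecoli.mu, ecoli.N_m) == pytest.approx(1.93 / 1380.0)
        assert cm_per_mrna(ecoli.mu, ecoli.N_m) == pytest.approx(1.4e-3, rel=0.05)


class TestNoiseLoad:
    def test_flat_fitness_no_load(self):
        assert noise_load(0.0, 123.0) == 0.0

    def test_linearity_in_variance(self):
        assert noise_load(-2e-8, 2e6) == pytest.approx(2 * noise_load(-2e-8, 1e6))

    def test_positive_curvature_rejected(self):
        with pytest.raises(cs.InvalidParameterError):
            noise_load(1e-8, 1.0)

    def test_monte_carlo_oracle(self, rng):
        """Averaging a quadratic fitness peak over Gaussian fluctuations loses
        exactly the analytic noise load."""
        f_max, curv, p_star, sigma = 0.05, -1e-7, 1e4, 2e3
        draws = p_star + sigma * rng.standard_normal(100_000)
        f = f_max + 0.5 * curv * (draws - p_star) ** 2
        expected_load = noise_load(curv, sigma**2)
        mc_load = f_max - f.mean()
        se = f.std(ddof=1) / np.sqrt(draws.size)
        assert abs(mc_load - expected_load) < 3 * se


class TestOptimum:
    def test_equal_cost_and_sensitivity_gives_unit_ratio(self, yeast):
        C = 1e-9 * 1300.0 * yeast.alpha_m
        # curvature chosen so Q = |f''| p*/2 equals C
        spec = FitnessSpec(f_max=0.1, p_star=1e4, curvature=-2 * C / 1e4,
                          c_m=1e-9, l_m=1300.0, alpha_m=yeast.alpha_m)
        assert optimal_rates(spec, yeast).ratio == pytest.approx(1.0, rel=1e-12)

    def test_matches_numerical_maximizer(self, yeast, rng):
        """Closed-form optimum against a bounded golden-section maximizer of
        the mean fitness, 20 random parameter sets."""
        for _ in range(20):
            spec = random_spec(rng, alpha_m=yeast.alpha_m)
            opt = optimal_rates(spec, yeast)
            res = minimize_scalar(
                lambda b: -mean_fitness(spec, yeast, b),
                bounds=(opt.beta_m * 1e-3, opt.beta_m * 1e3),
                method="bounded",
                options={"xatol": opt.beta_m * 1e-10},
            )
            assert res.x == pytest.approx(opt.beta_m, rel=1e-6)

    def test_perturbation_decreases_fitness(self, yeast, rng):
        spec = random_spec(rng, alpha_m=yeast.alpha_m)
        opt = optimal_rates(spec, yeast)
        best = mean_fitness(spec, yeast, opt.beta_m)
        assert mean_fitness(spec, yeast, 0.9 * opt.beta_m) < best
        assert mean_fitness(spec, yeast, 1.1 * opt.beta_m) < best

    def test_flat_peak_rejected(self, yeast):
        spec = FitnessSpec(f_max=0.1, p_star=1e4, curvature=0.0, c_m=1e-9,
                          l_m=1300.0, alpha_m=yeast.alpha_m)
        with pytest.raises(cs.InvalidParameterError, match="economy"):
            optimal_rates(spec, yeast)


class TestCurvature:
    def test_round_trip(self, yeast, rng):
        spec = random_spec(rng, alpha_m=yeast.alpha_m)
        opt = optimal_rates(spec, yeast)
        recovered = curvature_from_rates(opt.ratio, spec.C, spec.p_star)
        assert recovered == pytest.approx(spec.curvature, rel=1e-12)

    def test_monotone_in_ratio(self):
        a = curvature_from_rates(1.0, 1e-5, 1e4)
        b = curvature_from_rates(10.0, 1e-5, 1e4)
        assert abs(b) < abs(a)

    def test_boundary_gene_matches_q_max(self, yeast):
        k = predict_k(yeast).k_pred
        c_m = cm_from_constants(yeast.mu, yeast.total_transcription, yeast.l_m)
        C = c_m * yeast.l_m * yeast.alpha_m
        p_star = 1e4
        curv = curvature_from_rates(k, C, p_star)
        Q = 0.5 * abs(curv) * p_star
        assert Q == pytest.approx(q_max(yeast), rel=1e-9)


class TestBoundaryPrediction:
    def test_sqrt_rho_scaling_of_q_max(self, yeast):
        assert q_max(yeast, rho=0.25) == pytest.approx(q_max(yeast, rho=1.0) / 2.0, rel=1e-12)

    def test_identity_cost_over_q_max(self, yeast):
        c_m = cm_from_constants(yeast.mu, yeast.total_transcription, yeast.l_m)
        C = c_m * yeast.l_m * yeast.alpha_m
        assert C / q_max(yeast) == pytest.approx(predict_k(yeast).k_pred, rel=1e-9)

    def test_closed_form_independent_of_l_m_and_mu(self, yeast):
        """The two algebraic routes to k agree exactly, and the dependence on
        mRNA length and growth rate cancels."""
        for l_m, mu in [(500.0, 0.2), (1300.0, 0.42), (5000.0, 1.5)]:
            c_m = cm_from_constants(mu, yeast.total_transcription, l_m)
            k_route = yeast.beta_p_max * yeast.cv0 * np.sqrt(
                c_m * l_m / (yeast.alpha_p * mu)
            )
            assert k_route == pytest.approx(predict_k(yeast).k_pred, rel=1e-12)

    def test_quadrupled_output_halves_k(self, yeast):
        doubled = cs.CellularConstants(
            organism_label="scaled", N_m=4 * yeast.N_m, N_p=yeast.N_p, mu=yeast.mu,
            alpha_m=yeast.alpha_m, alpha_deg=yeast.alpha_deg, alpha_p=yeast.alpha_p,
            cv0=yeast.cv0, l_m=yeast.l_m, beta_p_max=yeast.beta_p_max,
        )
        assert predict_k(doubled).k_pred == pytest.approx(predict_k(yeast).k_pred / 2.0)

    def test_nonessential_boundary_is_higher(self, yeast):
        assert predict_k(yeast, rho=0.01).k_pred > predict_k(yeast, rho=1.0).k_pred

    def test_selectability_brute_force(self, yeast, rng):
        """is_selectable agrees with the direct inequality f_max > Q p* cv^2."""
        for _ in range(50):
            spec = random_spec(rng)
            cv2 = 10 ** rng.uniform(-3, 0)
            direct = spec.f_max > spec.Q * spec.p_star * cv2
            assert is_selectable(spec.f_max, spec.curvature, spec.p_star, cv2) == direct
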