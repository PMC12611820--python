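"""Exact transformations, flow fields, and their closed-form checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entroflow import (
    BoundaryMassWarning,
    DensityGrid,
    FlowIntegrationError,
    FlowParams,
    InvalidDensityError,
    entropic_flow_field,
    entropy,
    expectation,
    expectation_flow_field,
    exponential_tilt,
    generator_consistency_check,
    integrate_mixed_flow,
    orthogonality_covariance,
    power_law_transform,
)

from conftest import gaussian_pdf, mixture_pdf


class TestDensityGrid:
    @pytest.mark.parametrize(
        "support, mass, fragment",
        [
            (np.linspace(0, 1, 8), np.ones(8), "at least 16"),
            (np.linspace(0, 1, 32)[::-1], np.ones(32), "increasing"),
            (np.r_[np.linspace(0, 1, 31), 1.5], np.ones(32) / 1.5, "constant"),
            (np.linspace(0, 1, 32), np.r_[np.ones(31), np.nan], "finite"),
            (np.linspace(0, 1, 32), 3.0 * np.ones(32), "integrate to 1"),
        ],
    )
    def test_invariant_violations_are_named(self, support, mass, fragment):
        with pytest.raises(InvalidDensityError, match=fragment):
            DensityGrid(support, mass)

    def test_from_values_renormalizes_and_floors(self):
        x = np.linspace(-1, 1, 64)
        g = DensityGrid.from_values(x, np.r_[np.zeros(32), np.ones(32)])
        assert np.trapezoid(g.mass, x) == pytest.approx(1.0, abs=1e-12)
        assert np.all(g.mass > 0)

    def test_csv_round_trip(self, std_normal_grid, tmp_path):
        path = tmp_path / "density.csv"
        std_normal_grid.to_csv(path)
        back = DensityGrid.from_csv(path)
        np.testing.assert_allclose(back.support, std_normal_grid.support, rtol=0, atol=0)
        np.testing.assert_allclose(back.mass, std_normal_grid.mass, rtol=0, atol=0)


class TestEntropyExpectation:
    def test_uniform_entropy_is_log_range(self):
        x = np.linspace(0.0, 1.0, 512)
        g = DensityGrid.from_values(x, np.ones_like(x))
        assert entropy(g) == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_entropy_closed_form(self, std_normal_grid):
        expected = 0.5 * np.log(2 * np.pi * np.e)
        assert entropy(std_normal_grid) == pytest.approx(expected, abs=1e-4)

    def test_mixture_entropy_matches_fine_quadrature_oracle(self):
        # oracle: same integrand evaluated analytically at 10x resolution
        means, sds, ws = [-2.0, 2.0], [1.0, 1.0], [0.5, 0.5]
        x = np.linspace(-10, 10, 2048)
        g = DensityGrid.from_values(x, mixture_pdf(x, means, sds, ws))
        xf = np.linspace(-10, 10, 20480)
        qf = mixture_pdf(xf, means, sds, ws)
        oracle = -np.trapezoid(qf * np.log(qf), xf)
        assert entropy(g) == pytest.approx(oracle, abs=1e-6)

    def test_expectation_symmetry_and_location(self):
        assert expectation(DensityGrid.gaussian(0, 1, 2048)) == pytest.approx(0.0, abs=1e-10)
        assert expectation(DensityGrid.gaussian(1.5, 1, 2048)) == pytest.approx(1.5, abs=1e-4)

    def test_expectation_translation_equivariance(self):
        x = np.linspace(-8, 8, 1024)
        q = mixture_pdf(x, [-1.0, 2.0], [0.7, 1.1], [0.4, 0.6])
        g = DensityGrid.from_values(x, q)
        shifted = DensityGrid.from_values(x + 3.25, q)
        assert expectation(shifted) == pytest.approx(expectation(g) + 3.25, abs=1e-8)


class TestFlowFields:
    def test_uniform_entropic_field_vanishes(self):
        x = np.linspace(0, 2, 256)
        g = DensityGrid.from_values(x, np.ones_like(x))
        assert np.max(np.abs(entropic_flow_field(g))) < 1e-12

    def test_gaussian_entropic_field_closed_form(self, std_normal_grid):
        # log N(0,1) minus its own q-mean: -x^2/2 + 1/2
        x = std_normal_grid.support
        expected = -0.5 * x**2 + 0.5
        np.testing.assert_allclose(
            entropic_flow_field(std_normal_grid), expected, atol=1e-3
        )

    def test_expectation_field_is_centered_coordinates(self):
        g = DensityGrid.gaussian(2.0, 0.5, 1024)
        np.testing.assert_allclose(
            expectation_flow_field(g), g.support - 2.0, atol=1e-4
        )

    @pytest.mark.parametrize("which", ["entropic", "expectation"])
    def test_projection_zero_mean_under_q(self, which, std_normal_grid, skewed_grid):
        field = entropic_flow_field if which == "entropic" else expectation_flow_field
        for g in (std_normal_grid, skewed_grid):
            v = field(g)
            assert abs(np.trapezoid(v * g.mass, g.support)) < 1e-8


class TestPowerLaw:
    def test_identity_at_lambda_one(self, std_normal_grid):
        out = power_law_transform(std_normal_grid, 1.0)
        np.testing.assert_allclose(out.mass, std_normal_grid.mass, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 1.5, 2.0, 4.0])
    def test_gaussian_closed_form(self, lam):
        sigma = 1.3
        g = DensityGrid.gaussian(0.0, sigma, n=2048, span_sd=8.0)
        out = power_law_transform(g, lam)
        expected = gaussian_pdf(out.support, 0.0, sigma / np.sqrt(lam))
        assert np.max(np.abs(out.mass - expected)) < 1e-6

    def test_entropy_decreases_with_lambda(self):
        sigma = 1.0
        g = DensityGrid.gaussian(0.0, sigma, n=2048)
        ents = [entropy(power_law_transform(g, lam)) for lam in (1.0, 1.5, 2.0, 4.0)]
        assert np.all(np.diff(ents) < 0)
        for lam, e in zip((1.0, 1.5, 2.0, 4.0), ents):
            assert e == pytest.approx(0.5 * np.log(2 * np.pi * np.e * sigma**2 / lam), abs=1e-4)

    @pytest.mark.parametrize("lam", [0.0, -1.0, np.inf, np.nan])
    def test_invalid_exponent_rejected(self, std_normal_grid, lam):
        with pytest.raises(ValueError):
            power_law_transform(std_normal_grid, lam)


class TestExponentialTilt:
    def test_identity_at_lambda_zero(self, std_normal_grid):
        out = exponential_tilt(std_normal_grid, 0.0)
        np.testing.assert_allclose(out.mass, std_normal_grid.mass, atol=1e-12)

    @pytest.mark.parametrize("lam", [-0.5, 0.5, 1.0])
    def test_gaussian_mean_shift_closed_form(self, lam):
        mu, sigma = 0.3, 0.9
        g = DensityGrid.gaussian(mu, sigma, n=2048, span_sd=8.0)
        out = exponential_tilt(g, lam)
        expected = gaussian_pdf(out.support, mu + lam * sigma**2, sigma)
        assert np.max(np.abs(out.mass - expected)) < 1e-6

    def test_expectation_nondecreasing_in_lambda(self, std_normal_grid, skewed_grid):
        for g in (std_normal_grid, skewed_grid):
            means = [expectation(exponential_tilt(g, lam)) for lam in (-1.0, 0.0, 1.0)]
            assert means[0] < means[1] < means[2]

    def test_boundary_truncation_warns(self):
        narrow = DensityGrid.gaussian(0.0, 1.0, n=64, span_sd=2.5)
        with pytest.warns(BoundaryMassWarning):
            exponential_tilt(narrow, 4.0)


class TestMixedFlow:
    def test_zero_coefficients_are_identity(self, std_normal_grid):
        traj = integrate_mixed_flow(std_normal_grid, FlowParams(0, 0), 1.0, 10)
        np.testing.assert_allclose(traj.final.mass, std_normal_grid.mass, atol=1e-12)
        assert traj.initial is std_normal_grid
        assert traj.lambdas[0] == 0.0 and traj.lambdas[-1] == 1.0

    def test_pure_expectation_flow_reproduces_tilt_exactly(self, std_normal_grid):
        # Euler steps on log q compose tilts exactly; agreement is at
        # machine precision rather than merely O(dlam)
        beta, lam = 0.5, 1.0
        ref = exponential_tilt(std_normal_grid, beta * lam)
        for n_steps in (10, 40):
            traj = integrate_mixed_flow(std_normal_grid, FlowParams(0, beta), lam, n_steps)
            assert np.max(np.abs(traj.final.mass - ref.mass)) < 1e-10

    def test_pure_entropic_flow_converges_first_order_to_power_law(self, std_normal_grid):
        alpha, lam = 0.3, 1.0
        ref = power_law_transform(std_normal_grid, np.exp(alpha * lam))
        errs = []
        for n_steps in (50, 100, 200):
            traj = integrate_mixed_flow(std_normal_grid, FlowParams(alpha, 0), lam, n_steps)
            errs.append(np.max(np.abs(traj.final.mass - ref.mass)))
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for r in ratios:
            assert 1.5 < r < 2.6  # error halves when the step halves

    def test_every_trajectory_element_is_normalized(self, skewed_grid):
        traj = integrate_mixed_flow(skewed_grid, FlowParams(0.05, 0.4), 1.0, 25)
        for d in traj.densities:
            assert np.trapezoid(d.mass, d.support) == pytest.approx(1.0, abs=1e-8)

    def test_nonfinite_intermediate_aborts_with_step_index(self, std_normal_grid):
        with pytest.raises(FlowIntegrationError, match="step 1"):
            integrate_mixed_flow(std_normal_grid, FlowParams(1e308, 0), 1.0, 4)

    def test_invalid_step_count_rejected(self, std_normal_grid):
        with pytest.raises(ValueError):
            integrate_mixed_flow(std_normal_grid, FlowParams(0, 0), 1.0, 0)


class TestOrthogonality:
    def test_zero_for_densities_symmetric_about_mean(self):
        for g in (
            DensityGrid.gaussian(0.0, 1.0, 2048),
            DensityGrid.gaussian(2.0, 0.7, 2048),
        ):
            assert abs(orthogonality_covariance(g)) < 1e-8
        # symmetric bimodal mixture, centered at 1
        x = np.linspace(-9, 11, 4096)
        g = DensityGrid.from_values(x, mixture_pdf(x, [-1.0, 3.0], [0.8, 0.8], [0.5, 0.5]))
        assert abs(orthogonality_covariance(g)) < 1e-8

    def test_skewed_density_matches_fine_quadrature_oracle(self):
        # strongly skewed smooth mixture (exponential-like right tail)
        means, sds, ws = [-1.0, 2.0], [0.6, 1.8], [0.6, 0.4]
        x = np.linspace(-10, 16, 4096)
        g = DensityGrid.from_values(x, mixture_pdf(x, means, sds, ws))
        xf = np.linspace(-10, 16, 40960)
        qf = mixture_pdf(xf, means, sds, ws)
        qf = qf / np.trapezoid(qf, xf)
        lg = np.log(np.maximum(qf, 1e-300))
        mlg = np.trapezoid(qf * lg, xf)
        mx = np.trapezoid(xf * qf, xf)
        oracle = np.trapezoid((lg - mlg) * (xf - mx) * qf, xf)
        val = orthogonality_covariance(g)
        assert abs(oracle) > 0.1  # genuinely nonzero for a skewed law
        assert val == pytest.approx(oracle, abs=1e-6)


class TestGeneratorConsistency:
    def test_zero_eps_is_exact(self, std_normal_grid):
        assert generator_consistency_check(std_normal_grid, 0.0) == 0.0

    def test_second_order_in_eps_gaussian(self, std_normal_grid):
        d1 = generator_consistency_check(std_normal_grid, 0.01)
        d2 = generator_consistency_check(std_normal_grid, 0.005)
        assert d1 <= 1e-3
        assert d1 / d2 == pytest.approx(4.0, rel=0.3)

    def test_second_order_in_eps_bimodal(self):
        x = np.linspace(-10, 10, 2048)
        g = DensityGrid.from_values(x, mixture_pdf(x, [-2, 2], [1, 1], [0.5, 0.5]))
        d1 = generator_consistency_check(g, 0.02)
        d2 = generator_consistency_check(g, 0.01)
        assert d1 / d2 == pytest.approx(4.0, rel=0.3)

    def test_eps_out_of_range_rejected(self, std_normal_grid):
        with pytest.raises(ValueError):
            generator_consistency_check(std_normal_grid, 0.5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    mean=st.floats(-2, 2),
    sd=st.floats(0.3, 3),
    lam_pow=st.floats(0.5, 3),
    lam_tilt=st.floats(-0.8, 0.8),
)
def test_transforms_preserve_normalization_and_projection(mean, sd, lam_pow, lam_tilt):
    """Mass conservation and zero-mean fields hold across random Gaussians."""
    g = DensityGrid.gaussian(mean, sd, n=512, span_sd=8.0)
    for out in (power_law_transform(g, lam_pow), exponential_tilt(g, lam_tilt)):
        assert np.trapezoid(out.mass, out.support) == pytest.approx(1.0, abs=1e-8)
        v = entropic_flow_field(out)
        assert abs(np.trapezoid(v * out.mass, out.support)) < 1e-8
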