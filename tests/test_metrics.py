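import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoscale import (
    MetricProfile,
    ModelParams,
    ProfileSet,
    SpatialGrid,
    classify_scaling,
    expander_summaries,
    invert_profile,
    precision_profile,
    robustness_profile,
    scaling_profile,
    useful_patterning_region,
)
from morphoscale.metrics import MonotonicityError

from conftest import exponential_profile


class TestInvertProfile:
    def test_self_inversion_of_exponential(self):
        r = np.linspace(0, 1, 1001)
        M = np.exp(-r / 0.2)
        c = float(np.exp(-0.3 / 0.2))
        rho, clamped = invert_profile(r, M, c)
        assert rho == pytest.approx(0.3, abs=1e-6)
        assert not clamped

    def test_concentration_above_max_clamps_to_source(self):
        r = np.linspace(0, 1, 11)
        M = np.exp(-r)
        rho, clamped = invert_profile(r, M, 2.0 * M.max())
        assert rho == 0.0 and clamped

    def test_concentration_below_min_clamps_to_far_edge(self):
        r = np.linspace(0, 1, 11)
        M = np.exp(-r)
        rho, clamped = invert_profile(r, M, 0.5 * M.min())
        assert rho == 1.0 and clamped

    def test_log_linear_interpolation_on_coarse_table(self):
        r = np.array([0.0, 0.5, 1.0])
        M = np.array([1.0, np.exp(-1), np.exp(-2)])
        rho, clamped = invert_profile(r, M, np.exp(-0.5))
        assert rho == pytest.approx(0.25, abs=1e-12)
        assert not clamped

    def test_non_monotone_profile_names_violation(self):
        r = np.linspace(0, 1, 5)
        M = np.array([1.0, 0.5, 0.7, 0.3, 0.1])
        with pytest.raises(MonotonicityError, match="0.25"):
            invert_profile(r, M, 0.4)

    def test_plateau_returns_smallest_position(self):
        r = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        M = np.array([1.0, 0.5, 0.5, 0.5, 0.1])
        rho, _ = invert_profile(r, M, 0.5)
        assert rho == 0.25


class TestScalingProfile:
    def test_self_similar_pair_scales_perfectly(self):
        """A profile re-expressed on the same relative grid (shape and
        amplitude preserved) gives S = 1 everywhere."""
        g1 = SpatialGrid(50.0, 501)
        g2 = SpatialGrid(100.0, 501)
        M1 = np.exp(-g1.r / 0.2)
        ps1 = ProfileSet(g1, M1, np.ones(501), converged=True, residual=0.0)
        ps2 = ProfileSet(g2, M1.copy(), np.ones(501), converged=True,
                         residual=0.0)
        S = scaling_profile(ps1, ps2)
        np.testing.assert_allclose(S.values, 1.0, atol=1e-9)

    def test_fixed_exponential_gives_linear_decay_of_scaling(self, exp_pair):
        ps1, ps2 = exp_pair
        S = scaling_profile(ps1, ps2)
        np.testing.assert_allclose(S.values, 1.0 - S.r_values / 2, atol=1e-6)

    def test_amplitude_shift_of_scaled_profile(self):
        """Perfectly scaled shape but 1.5x amplitude at the larger length:
        every threshold moves by (lambda/L2) ln 1.5 toward the far edge."""
        lam_rel = 0.2
        g1 = SpatialGrid(50.0, 2001)
        g2 = SpatialGrid(100.0, 2001)
        ps1 = ProfileSet(g1, np.exp(-g1.r / lam_rel), np.ones(2001),
                         converged=True, residual=0.0)
        ps2 = ProfileSet(g2, 1.5 * np.exp(-g2.r / lam_rel), np.ones(2001),
                         converged=True, residual=0.0)
        S = scaling_profile(ps1, ps2)
        interior = (S.r_values > 0.15) & (S.r_values < 0.85)
        np.testing.assert_allclose(
            S.values[interior], 1.0 - lam_rel * np.log(1.5), atol=1e-6)

    def test_requires_larger_second_length(self, exp_pair):
        ps1, ps2 = exp_pair
        with pytest.raises(ValueError, match="larger"):
            scaling_profile(ps2, ps1)


class TestRobustnessProfile:
    def test_identical_profiles_are_fully_robust(self, exp_pair):
        ps1, _ = exp_pair
        R = robustness_profile(ps1, ps1, ps1)
        np.testing.assert_allclose(R.values, 1.0)

    def test_amplitude_fold_change_closed_form(self, exp_pair):
        ps1, _ = exp_pair
        plus = ProfileSet(ps1.grid, 1.5 * ps1.M, ps1.E, converged=True,
                          residual=0.0)
        minus = ProfileSet(ps1.grid, ps1.M / 1.5, ps1.E, converged=True,
                           residual=0.0)
        R = robustness_profile(ps1, plus, minus)
        interior = (R.r_values > 0.1) & (R.r_values < 0.9)
        np.testing.assert_allclose(
            R.values[interior], 1.0 - 0.2 * np.log(1.5), atol=1e-3)

    def test_clamp_arithmetic_at_far_position(self):
        """If the up-perturbed profile sits everywhere below the base
        concentration at r = 0.9 the inversion clamps to rho = 0, and with
        an unperturbed minus profile R(0.9) = 1 - 0.45 = 0.55."""
        g = SpatialGrid(50.0, 1001)
        M = np.exp(-g.r / 0.2)
        base = ProfileSet(g, M, np.ones(1001), converged=True, residual=0.0)
        # "plus" amplitude so large that M_base(0.9) exceeds nothing in it:
        # shift the whole profile up by a huge factor -> M(r=0.9, base)
        # is below plus everywhere -> rho_+ clamps to 1? use tiny instead:
        plus = ProfileSet(g, 1e6 * M, np.ones(1001), converged=True,
                          residual=0.0)
        R = robustness_profile(base, plus, base)
        i = np.argmin(np.abs(R.r_values - 0.9))
        # rho_+ clamps to 1 (concentration below plus minimum)
        assert R.values[i] == pytest.approx(1.0 - 0.5 * 0.1, abs=1e-9)
        assert R.clamped[i]
        tiny = ProfileSet(g, 1e-6 * M, np.ones(1001), converged=True,
                          residual=0.0)
        R2 = robustness_profile(base, tiny, base)
        j = np.argmin(np.abs(R2.r_values - 0.9))
        # rho_+ clamps to 0 (concentration above tiny profile's maximum)
        assert R2.values[j] == pytest.approx(1.0 - 0.45, abs=1e-9)
        assert R2.clamped[j]


class TestPrecisionProfile:
    def exp_r_profile(self, amplitude=1.0, Nx=2001):
        g = SpatialGrid(1.0, Nx)
        M = amplitude * np.exp(-g.positions / 0.2)
        return ProfileSet(g, M, np.zeros(Nx), converged=True, residual=0.0)

    def test_closed_form_sigma(self):
        P = precision_profile(self.exp_r_profile(), d=1.0)
        i = np.argmin(np.abs(P.r_values - 0.2))
        assert P.sigma[i] == pytest.approx(0.2 * np.exp(0.2 / 0.4), rel=1e-3)
        assert P.values[i] == pytest.approx(1 - 0.2 * np.exp(0.2 / 0.4),
                                            rel=1e-3)

    def test_quadrupled_amplitude_halves_sigma(self):
        P1 = precision_profile(self.exp_r_profile(1.0), d=1.0)
        P4 = precision_profile(self.exp_r_profile(4.0), d=1.0)
        ok = ~P1.clamped
        np.testing.assert_allclose(P4.sigma[ok], P1.sigma[ok] / 2, rtol=1e-9)

    def test_plateau_is_divergent_with_zero_precision(self):
        g = SpatialGrid(1.0, 101)
        ps = ProfileSet(g, np.ones(101), np.zeros(101), converged=True,
                        residual=0.0)
        P = precision_profile(ps, d=1.0)
        assert np.all(P.values == 0.0)
        assert np.all(P.clamped)
        assert np.all(np.isnan(P.sigma))


class TestMetricInvariance:
    @settings(max_examples=20, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_scaling_and_robustness_invariant_under_unit_rescaling(self, c):
        """Multiplying all concentrations by one factor changes neither
        S nor R (they compare positions, not magnitudes)."""
        g1 = SpatialGrid(50.0, 301)
        g2 = SpatialGrid(100.0, 301)
        M1 = np.exp(-g1.positions / 10.0)
        M2 = np.exp(-g2.positions / 10.0)
        a1 = ProfileSet(g1, M1, np.ones(301), converged=True, residual=0.0)
        a2 = ProfileSet(g2, M2, np.ones(301), converged=True, residual=0.0)
        b1 = ProfileSet(g1, c * M1, np.ones(301), converged=True, residual=0.0)
        b2 = ProfileSet(g2, c * M2, np.ones(301), converged=True, residual=0.0)
        np.testing.assert_allclose(scaling_profile(a1, a2).values,
                                   scaling_profile(b1, b2).values, atol=1e-9)


class TestExpanderSummaries:
    def params(self, **kw):
        base = dict(DM=1.0, DE=1.0, k=1.0, mu=1.0, nuM=1.0, nuE=1.0,
                    xi=0.5, zeta=0.5, m=0.5, h=2.0, beta=0.1, L=50.0)
        base.update(kw)
        return ModelParams(**base)

    def converged(self, g, M, E):
        return ProfileSet(g, M, E, converged=True, residual=0.0)

    def test_uniform_expander_has_zero_dynamic_range(self):
        g = SpatialGrid(50.0, 501)
        ps = self.converged(g, np.exp(-g.r / 0.2), np.ones(501))
        s = expander_summaries(ps, self.params())
        assert s.f_E == 0.0
        assert s.lambda_E is None  # never falls to half the edge value

    def test_linear_expander_dynamic_range(self):
        """E rising linearly with E(wM) = E(L)/2 gives f_E = 1/2."""
        g = SpatialGrid(50.0, 501)
        wM = 5.0
        E = (g.positions + 40.0) / 90.0  # E(5)=0.5, E(50)=1.0
        ps = self.converged(g, np.exp(-g.r / 0.2), E)
        s = expander_summaries(ps, self.params())
        assert s.f_E == pytest.approx(0.5, abs=1e-9)
        # half-decay position is x = wM -> lambda_E = L - wM
        assert s.lambda_E == pytest.approx(g.L - wM, rel=1e-3)

    def test_morphogen_at_hill_threshold_gives_half_tissue_source(self):
        g = SpatialGrid(50.0, 501)
        p = self.params()
        ps = self.converged(g, np.full(501, p.m), np.ones(501))
        s = expander_summaries(ps, p)
        assert s.w_E == pytest.approx(g.L / 2, rel=1e-9)

    def test_mu_bar_of_uniform_expander(self):
        g = SpatialGrid(50.0, 501)
        p = self.params()
        ps = self.converged(g, np.exp(-g.r / 0.2), np.full(501, p.zeta))
        s = expander_summaries(ps, p)
        assert s.mu_bar == pytest.approx(p.mu / 2 * g.L, rel=1e-9)

    def test_zero_edge_expander_is_undefined(self):
        g = SpatialGrid(50.0, 501)
        ps = self.converged(g, np.exp(-g.r / 0.2), np.zeros(501))
        s = expander_summaries(ps, self.params())
        assert s.f_E is None


class TestClassification:
    def metric(self, values, r=None):
        r = np.linspace(0, 1, len(values)) if r is None else r
        return MetricProfile(r, np.asarray(values, float),
                             np.zeros(len(values), bool))

    def test_perfect_scaling_is_global(self):
        S = self.metric(np.ones(101))
        assert classify_scaling(S, 0.98).kind == "global"

    def test_triangular_profile_is_local_at_peak(self):
        r = np.linspace(0, 1, 101)
        S = self.metric(1.0 - np.abs(r - 0.3), r)
        cls = classify_scaling(S, 0.98)
        assert cls.kind == "local"
        assert cls.local_position == pytest.approx(0.3, abs=1e-9)

    def test_uniformly_poor_scaling_is_none(self):
        S = self.metric(np.full(101, 0.5))
        assert classify_scaling(S, 0.98).kind == "none"

    def test_empty_target_region_rejected(self):
        S = self.metric(np.ones(101))
        with pytest.raises(ValueError, match="empty"):
            classify_scaling(S, 0.98, target_region=(2.0, 3.0))


class TestUsefulPatterningRegion:
    def metric(self, values, r):
        return MetricProfile(r, np.asarray(values, float),
                             np.zeros(len(r), bool))

    def test_all_high_gives_whole_region(self):
        r = np.linspace(0, 1, 101)
        one = self.metric(np.ones(101), r)
        ivs = useful_patterning_region(one, one, one, 0.95)
        assert ivs == [(0.0, 1.0)]

    def test_zero_precision_gives_no_region(self):
        r = np.linspace(0, 1, 101)
        one = self.metric(np.ones(101), r)
        zero = self.metric(np.zeros(101), r)
        assert useful_patterning_region(one, one, zero, 0.95) == []

    def test_interpolated_crossing_of_limiting_metric(self):
        """S = R = 1 and P falling linearly through the threshold: the
        interval ends at the interpolated crossing position."""
        r = np.linspace(0, 1, 101)
        one = self.metric(np.ones(101), r)
        P = self.metric(1.0 - 0.125 * r, r)  # crosses 0.95 at r = 0.4
        ivs = useful_patterning_region(one, one, P, 0.95)
        assert len(ivs) == 1
        assert ivs[0][0] == 0.0
        assert ivs[0][1] == pytest.approx(0.4, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        a = self.metric(np.ones(11), np.linspace(0, 1, 11))
        b = self.metric(np.ones(21), np.linspace(0, 1, 21))
        with pytest.raises(ValueError, match="r-grid"):
            useful_patterning_region(a, a, b, 0.95)
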