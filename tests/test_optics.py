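"""Absorption-model inversion, limits, dynamics, and the power-law fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coraloptics.optics import (
    AbsorptionParams,
    LOWER_BOUND,
    feedback_rate,
    fit_inverse_power_law,
    forward_reflectance,
    infer_absorption,
    per_pigment_dynamics,
)


class TestInferAbsorption:
    def test_flat_unit_skeleton(self):
        res = infer_absorption(0.25, 1.0)
        assert res.i_a1 == pytest.approx(0.5, abs=1e-12)
        assert res.i_a2 == pytest.approx(0.25, abs=1e-12)
        assert res.i_a == pytest.approx(0.75, abs=1e-12)  # = 1 - R'

    def test_general_parameters(self):
        # oracle: forward substitution gives R_1 = 0.5, a_2 = 0.2689292 and
        # reproduces R_H = 0.300000 exactly
        res = infer_absorption(0.30, 0.60, AbsorptionParams(1.5, 1.2, 0.8))
        assert res.i_a1 == pytest.approx(0.1792861, abs=5e-7)
        assert res.i_a2 == pytest.approx(0.1760141, abs=5e-7)
        assert res.i_a == pytest.approx(0.3553002, abs=5e-7)
        assert res.r_1 == pytest.approx(0.5)
        assert res.a_2 == pytest.approx(0.2689292, abs=5e-7)

    def test_holobiont_as_bright_as_skeleton(self):
        res = infer_absorption(0.6, 0.6)
        assert res.i_a1 == 0.0
        assert res.i_a2 == 0.0
        assert res.i_a == 0.0

    def test_printed_extremes(self):
        res = infer_absorption(0.26, 0.71)
        assert res.i_a1 == pytest.approx(0.39486, abs=5e-6)
        assert res.i_a2 == pytest.approx(0.16965, abs=5e-6)

    def test_over_bright_flagged_not_erroring(self):
        res = infer_absorption(0.75, 0.6)
        assert res.i_a1 == 0.0
        assert "over-bright" in res.flags

    @pytest.mark.parametrize("r_h,r_s", [(0.3, 0.0), (0.3, -0.1), (-0.1, 0.5)])
    def test_domain_errors(self, r_h, r_s):
        with pytest.raises(ValueError):
            infer_absorption(r_h, r_s)


class TestForwardReflectance:
    def test_flat_midpoint(self):
        assert forward_reflectance(0.5, 1.0) == pytest.approx(0.25)

    def test_no_absorption_returns_r1(self):
        p = AbsorptionParams(1.5, 1.2, 0.8)
        assert forward_reflectance(0.0, 0.6, p) == pytest.approx(0.5)

    def test_round_trip_oracle_value(self):
        p = AbsorptionParams(1.5, 1.2, 0.8)
        assert forward_reflectance(0.17929, 0.6, p) == pytest.approx(0.30000, abs=5e-6)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            forward_reflectance(0.8, 0.6, AbsorptionParams(1.5))


params_strategy = st.builds(
    AbsorptionParams,
    alpha=st.floats(1.0, 2.5),
    beta=st.floats(1.0, 2.0),
    gamma=st.floats(0.5, 1.0),
)


class TestModelIdentities:
    @given(
        i_a1=st.floats(0.0, 1.0),
        r_s=st.floats(0.05, 1.0),
        params=params_strategy,
    )
    @settings(max_examples=300, deadline=None)
    def test_forward_inverse_round_trip(self, i_a1, r_s, params):
        i_a1 = min(i_a1, 1.0 / params.alpha)
        r_h = forward_reflectance(i_a1, r_s, params)
        res = infer_absorption(r_h, r_s, params)
        assert res.i_a1 == pytest.approx(i_a1, abs=1e-10)

    @given(
        r_prime=st.floats(0.0, 1.0),
        r_s=st.floats(0.05, 1.0),
        params=params_strategy,
    )
    @settings(max_examples=300, deadline=None)
    def test_total_decomposition_identity(self, r_prime, r_s, params):
        """The two expressions for the skeleton-dependent fraction agree:
        the balance total minus I_a1 equals the closed-form I_a2."""
        res = infer_absorption(r_prime * r_s / params.beta, r_s, params)
        balance_i_a2 = (
            (1 - res.i_a1) * res.r_1 * res.a_2
            + (1 - res.i_a1) * params.gamma * (r_s - res.r_1)
        )
        assert balance_i_a2 == pytest.approx(res.i_a2, abs=1e-12)
        assert res.i_a == pytest.approx(res.i_a1 + res.i_a2, abs=1e-12)

    @given(r_prime=st.floats(0.0, 1.0), r_s=st.floats(0.05, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_flat_skeleton_closed_form(self, r_prime, r_s):
        res = infer_absorption(r_prime * r_s, r_s)
        assert res.i_a1 == pytest.approx(1.0 - np.sqrt(r_prime), abs=1e-12)

    @given(r_h=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_no_reentry_limit(self, r_h):
        res = infer_absorption(r_h, 1.0)
        assert res.i_a == pytest.approx(1.0 - r_h, abs=1e-12)

    def test_lower_bound_minimizes_i_a2(self):
        """Unit coefficients give the smallest skeleton-dependent
        absorption over the admissible coefficient grid."""
        violations = []
        pairs = [(0.02, 0.24), (0.05, 0.40), (0.10, 0.50), (0.26, 0.71), (0.20, 0.60)]
        for r_h, r_s in pairs:
            lb = infer_absorption(r_h, r_s).i_a2
            for a in np.linspace(1, 2.5, 7):
                for b in np.linspace(1, 2, 5):
                    for g in np.linspace(0.5, 1, 5):
                        try:
                            res = infer_absorption(r_h, r_s, AbsorptionParams(a, b, g))
                        except ValueError:
                            continue
                        if res.i_a2 < lb - 1e-12:
                            violations.append((r_h, r_s, a, b, g, res.i_a2, lb))
        assert not violations, f"lower-bound violations: {violations[:5]}"


class TestPerPigmentDynamics:
    def test_two_point_rate(self):
        res = per_pigment_dynamics([0.1, 0.2], [10, 5], [0, 2])
        assert np.allclose(res.ratio, [0.01, 0.04])
        assert res.rate == pytest.approx(0.015)

    def test_endpoint_mode_matches_two_points(self):
        res = per_pigment_dynamics([0.1, 0.2], [10, 5], [0, 2], method="endpoint")
        assert res.rate == pytest.approx(0.015)

    def test_constant_series(self):
        res = per_pigment_dynamics([0.1, 0.1, 0.1], [5, 5, 5], [0, 2, 4])
        assert res.rate == pytest.approx(0.0)

    def test_zero_pigment_errors(self):
        with pytest.raises(ValueError):
            per_pigment_dynamics([0.1, 0.2], [10, 0], [0, 2])


class TestFeedbackRate:
    def test_two_point_slope(self):
        assert feedback_rate([0.01, 0.05], [0.01, 0.03], [10, 5]) == pytest.approx(0.004)

    def test_identical_series(self):
        assert feedback_rate([0.01, 0.05], [0.01, 0.05], [10, 5]) == 0.0

    def test_constant_rho_errors(self):
        with pytest.raises(ValueError):
            feedback_rate([0.01, 0.05], [0.01, 0.03], [5, 5])


class TestInversePowerLaw:
    def test_noiseless_recovery(self):
        mu = np.array([1.5, 2, 3, 4.5, 6])
        fit = fit_inverse_power_law(mu, 2.0 * mu**-1.5)
        assert fit.a == pytest.approx(2.0, rel=1e-9)
        assert fit.b == pytest.approx(1.5, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_y_degenerate(self):
        fit = fit_inverse_power_law([1, 2, 3], [2.0, 2.0, 2.0])
        assert fit.b == 0.0
        assert fit.r2 == 0.0
        assert "degenerate-constant-y" in fit.flags

    def test_non_positive_y_errors(self):
        with pytest.raises(ValueError):
            fit_inverse_power_law([1, 2, 3], [1.0, -0.5, 2.0])

    def test_exponent_unbiased_under_lognormal_noise(self):
        rng = np.random.default_rng(42)
        mu = np.linspace(1.5, 6.0, 10)
        bs = []
        for _ in range(500):
            y = 2.0 * mu**-1.5 * np.exp(rng.normal(0, 0.3, len(mu)))
            bs.append(fit_inverse_power_law(mu, y).b)
        assert np.mean(bs) == pytest.approx(1.5, abs=0.1)
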