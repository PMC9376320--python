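"""Rohrer model: forward/inverse consistency, fitting, symmetry analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pneumotach as pt
from pneumotach.rohrer import FlowDirection, RohrerCoefficients

IN, EX = FlowDirection.INHALATION, FlowDirection.EXHALATION


def coeffs(k1, k2, d=FlowDirection.MEAN):
    return RohrerCoefficients(k1, k2, d)


class TestCoefficientInvariants:
    @pytest.mark.parametrize("k1,k2", [(-0.1, 1.0), (0.1, -1.0), (0.0, 0.0)])
    def test_unphysical_coefficients_rejected(self, k1, k2):
        with pytest.raises(pt.CoefficientError):
            RohrerCoefficients(k1, k2)

    def test_spec_requires_matching_directions(self):
        with pytest.raises(pt.InputError):
            pt.PneumotachSpec("x", coeffs(0.1, 0.1, EX), coeffs(0.1, 0.1, EX))

    def test_packaged_device_table(self, devices, p3):
        assert len(devices) == 5
        assert p3.exhalation.k1 == pytest.approx(0.133)
        assert p3.exhalation.k2 == pytest.approx(0.585)
        assert p3.channel_count == 19


class TestForwardModel:
    def test_zero_flow_zero_pressure(self, p2):
        assert pt.pressure_from_flow(0.0, p2.inhalation, p2.exhalation) == 0.0

    @pytest.mark.parametrize(
        "device,expected",
        [("pneumotach-3", 0.718), ("pneumotach-2", 1.388)],
    )
    def test_exhalation_pressure_at_one_lps(self, devices, device, expected):
        # exhalation flow is negative in the package's sign convention
        spec = devices[device]
        p = pt.pressure_from_flow(-1.0, spec.inhalation, spec.exhalation)
        assert abs(p) == pytest.approx(expected, abs=1e-12)
        assert p < 0

    def test_directional_dispatch_is_continuous_at_zero(self, p1):
        eps = 1e-9
        hi = pt.pressure_from_flow(eps, p1.inhalation, p1.exhalation)
        lo = pt.pressure_from_flow(-eps, p1.inhalation, p1.exhalation)
        assert abs(hi) < 1e-8 and abs(lo) < 1e-8


class TestInverseModel:
    def test_zero_pressure_zero_flow(self, p2):
        assert pt.flow_from_pressure(0.0, p2.inhalation) == 0.0

    def test_inverts_forward_example(self, p2):
        v = pt.flow_from_pressure(-1.388, p2.inhalation, p2.exhalation)
        assert v == pytest.approx(-1.0, rel=1e-12)

    def test_linear_limit(self):
        assert pt.flow_from_pressure(0.5, coeffs(0.5, 0.0)) == pytest.approx(1.0)

    def test_pure_quadratic_limit(self):
        assert pt.flow_from_pressure(0.9, coeffs(0.0, 0.1)) == pytest.approx(3.0)

    @given(
        k1=st.floats(0.0, 10.0),
        k2=st.floats(0.0, 10.0),
        v=st.floats(-5.0, 5.0),
    )
    def test_round_trip(self, k1, k2, v):
        if k1 + k2 < 1e-6:
            return
        c_in = coeffs(k1, k2, IN)
        c_ex = coeffs(k1 * 1.1 + 0.01, k2 * 0.9 + 0.01, EX)
        p = pt.pressure_from_flow(v, c_in, c_ex)
        v_back = pt.flow_from_pressure(p, c_in, c_ex)
        assert v_back == pytest.approx(v, rel=1e-12, abs=1e-12)

    @given(
        k1=st.floats(0.01, 5.0),
        k2=st.floats(0.01, 5.0),
        p=st.floats(0.001, 10.0),
        dp=st.floats(0.001, 1.0),
    )
    def test_monotone_in_pressure_and_coefficients(self, k1, k2, p, dp):
        c = coeffs(k1, k2)
        assert pt.flow_from_pressure(p + dp, c) > pt.flow_from_pressure(p, c)
        assert pt.flow_from_pressure(p, coeffs(k1 + dp, k2)) < pt.flow_from_pressure(p, c)
        assert pt.flow_from_pressure(p, coeffs(k1, k2 + dp)) < pt.flow_from_pressure(p, c)

    def test_continuity_as_k2_vanishes(self):
        c = coeffs(0.5, 1e-12)
        for p in (0.01, 0.5, 2.0):
            assert pt.flow_from_pressure(p, c) == pytest.approx(p / 0.5, rel=1e-6)


class TestResistance:
    def test_zero_flow_resistance_is_k1(self, p2):
        assert pt.resistance_at_flow(0.0, p2.exhalation) == pytest.approx(0.273)

    def test_low_resistance_device_stays_under_one(self, p3):
        # drilled resistor suitable for spontaneous breathing: R <= 1 at 1 L/s
        r = pt.resistance_at_flow(1.0, p3.exhalation)
        assert r == pytest.approx(0.718) and r <= 1.0

    def test_negative_flow_rejected(self, p2):
        with pytest.raises(pt.DomainError):
            pt.resistance_at_flow(-0.1, p2.inhalation)


class TestFitRohrer:
    def test_exact_recovery_from_noise_free_samples(self):
        true = coeffs(0.2, 1.0)
        flows = [0.1, 0.5, 1.0]
        samples = [(v, pt.pressure_from_flow(v, true)) for v in flows]
        fit = pt.fit_rohrer(samples)
        assert fit.coefficients.k1 == pytest.approx(0.2, abs=1e-10)
        assert fit.coefficients.k2 == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_self_consistency_on_device_coefficients(self, p2):
        flows = np.linspace(0.1, 1.2, 10)
        samples = [(v, pt.pressure_from_flow(v, p2.exhalation)) for v in flows]
        fit = pt.fit_rohrer(samples, EX)
        assert fit.coefficients.k1 == pytest.approx(0.273, rel=1e-6)
        assert fit.coefficients.k2 == pytest.approx(1.115, rel=1e-6)

    def test_zero_flow_samples_excluded(self):
        true = coeffs(0.3, 0.8)
        samples = [(0.0, 0.0)] + [(v, pt.pressure_from_flow(v, true)) for v in (0.2, 0.6, 1.0)]
        fit = pt.fit_rohrer(samples)
        assert fit.n_used == 3
        assert fit.coefficients.k2 == pytest.approx(0.8, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(pt.SingularDesignError):
            pt.fit_rohrer([(0.3, 0.1), (0.3, 0.11), (0.3, 0.09)])

    def test_too_few_samples_rejected(self):
        with pytest.raises(pt.InputError):
            pt.fit_rohrer([(0.1, 0.05), (0.5, 0.3)])

    def test_negative_intercept_clipped_with_warning(self):
        # resistance line with negative intercept: R = -0.05 + 1.0 v
        samples = [(v, v * (-0.05 + 1.0 * v)) for v in (0.2, 0.5, 0.8, 1.1)]
        with pytest.warns(UserWarning, match="clipping"):
            fit = pt.fit_rohrer(samples)
        assert fit.coefficients.k1 == 0.0
        assert fit.clipped


class TestSymmetryError:
    def test_symmetric_device_has_zero_error(self):
        spec = pt.PneumotachSpec(
            "sym", coeffs(0.2, 1.0, IN), coeffs(0.2, 1.0, EX)
        )
        rep = pt.symmetry_error(spec, 1.0)
        assert rep.worst == pytest.approx(0.0, abs=1e-15)

    def test_most_resistive_device_error_at_one_lps_near_1p3_pct(self, p1):
        # pointwise flow error at 1 L/s when the directional pairs are
        # replaced by their element-wise mean
        rep = pt.symmetry_error(p1, 1.0, n_grid=2, flow_floor=0.9999)
        assert 0.012 < rep.worst < 0.015
        assert rep.max_error_inhalation > rep.max_error_exhalation

    def test_relative_error_diverges_toward_zero_flow(self, p1):
        # with asymmetric K1 the relative metric blows up as v -> 0, which is
        # why the grid excludes a low-flow floor; worst sits at the floor
        low = pt.symmetry_error(p1, 1.0, flow_floor=0.01)
        default = pt.symmetry_error(p1, 1.0)
        assert low.worst > default.worst
        assert default.argmax_flow_inhalation == pytest.approx(default.flow_floor)

    def test_invalid_range_rejected(self, p1):
        with pytest.raises(pt.InputError):
            pt.symmetry_error(p1, -1.0)
        with pytest.raises(pt.InputError):
            pt.symmetry_error(p1, 0.01, flow_floor=0.05)
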