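"""Two-maneuver calibration: oracles, solver guarantees, reproducibility."""

import json
from importlib import resources

import numpy as np
import pytest

import pneumotach as pt


def constant_pressure_oracle(p1, t1, v1, p2, t2, v2):
    """Closed-form (K1, K2) for two constant-pressure maneuvers.

    Constant pressure P_i held for T_i with volume V_i implies constant
    flow u_i = V_i / T_i, so P_i = K1 u_i + K2 u_i^2 — a linear 2x2 system.
    """
    u1, u2 = v1 / t1, v2 / t2
    A = np.array([[u1, u1**2], [u2, u2**2]])
    return np.linalg.solve(A, [p1, p2])


def grid_search_oracle(records, volumes, k1_hi, k2_hi, n=401):
    """Brute-force minimizer of the max relative volume residual."""
    k1g = np.linspace(0, k1_hi, n)
    k2g = np.linspace(0, k2_hi, n)
    K1, K2 = np.meshgrid(k1g, k2g, indexing="ij")
    worst = np.zeros_like(K1)
    for (t, y), v in zip(records, volumes):
        # constant-pressure record: volume = T * invert(P)
        T = t[-1] - t[0]
        P = y[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            flows = np.where(
                K2 > 0,
                2.0 * P / (K1 + np.sqrt(K1**2 + 4.0 * K2 * P)),
                np.where(K1 > 0, P / np.where(K1 > 0, K1, 1.0), np.inf),
            )
        worst = np.maximum(worst, np.abs(T * flows - v) / v)
    i, j = np.unravel_index(np.argmin(worst), worst.shape)
    return k1g[i], k2g[j], (k1g[1] - k1g[0], k2g[1] - k2g[0])


class TestManeuverVolume:
    def test_constant_pressure_closed_form(self):
        # P = 0.08 with K1=0.2, K2=1.0 inverts to exactly 0.2 L/s
        t = np.linspace(0, 5, 1001)
        p = pt.PressureSignal(t=t, y=np.full(t.size, 0.08))
        v = pt.maneuver_volume(p, pt.RohrerCoefficients(0.2, 1.0))
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_zero_pressure_gives_zero_volume(self):
        t = np.linspace(0, 5, 100)
        p = pt.PressureSignal(t=t, y=np.zeros(100))
        assert pt.maneuver_volume(p, pt.RohrerCoefficients(0.2, 1.0)) == 0.0

    def test_trapezoid_convergence_order(self, p2):
        # halving dt reduces the discretization error ~4x on a smooth record
        errs = []
        for rate in (200.0, 400.0):
            flow = pt.generate_bag_maneuver(
                "fast", profile="half_sine", lead=0, trail=0, sample_rate=rate
            )
            p = pt.sense(flow, pt.SensorModel(spec=p2, noise_sd=0, offset=0, sample_rate=rate))
            errs.append(abs(pt.maneuver_volume(p, p2.inhalation) - 1.0))
        assert 3.0 < errs[0] / errs[1] < 5.0

    def test_strictly_decreasing_in_each_coefficient(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 4, 401)
        y = np.abs(rng.normal(0.3, 0.2, t.size))
        p = pt.PressureSignal(t=t, y=y)
        for k1, k2 in [(0.1, 0.5), (0.5, 1.5), (1.0, 0.2)]:
            base = pt.maneuver_volume(p, pt.RohrerCoefficients(k1, k2))
            assert pt.maneuver_volume(p, pt.RohrerCoefficients(k1 + 0.05, k2)) < base
            assert pt.maneuver_volume(p, pt.RohrerCoefficients(k1, k2 + 0.05)) < base


class TestTwoManeuverCalibrate:
    def test_matches_constant_pressure_closed_form(self, constant_pressure_pair):
        m1, m2 = constant_pressure_pair
        res = pt.two_maneuver_calibrate(m1, m2)
        k1_exp, k2_exp = constant_pressure_oracle(0.08, 5.0, 1.0, 0.35, 2.0, 1.0)
        assert (k1_exp, k2_exp) == pytest.approx((0.2, 1.0), rel=1e-12)
        assert res.coefficients.k1 == pytest.approx(k1_exp, rel=1e-8)
        assert res.coefficients.k2 == pytest.approx(k2_exp, rel=1e-8)

    def test_matches_grid_search_oracle(self, constant_pressure_pair):
        m1, m2 = constant_pressure_pair
        res = pt.two_maneuver_calibrate(m1, m2)
        records = [(m.pressure.t, m.pressure.y) for m in (m1, m2)]
        k1_hi = np.trapezoid(m1.pressure.y, m1.pressure.t) / m1.volume
        k2_hi = (np.trapezoid(np.sqrt(m1.pressure.y), m1.pressure.t) / m1.volume) ** 2
        g1, g2, (c1, c2) = grid_search_oracle(records, [1.0, 1.0], k1_hi, k2_hi)
        assert abs(res.coefficients.k1 - g1) <= c1
        assert abs(res.coefficients.k2 - g2) <= c2

    def test_residual_guarantee(self, constant_pressure_pair):
        m1, m2 = constant_pressure_pair
        res = pt.two_maneuver_calibrate(m1, m2)
        assert abs(res.residuals[0]) < 1e-8
        assert abs(res.residuals[1]) < 1e-8

    def test_identical_maneuvers_not_identifiable(self, constant_pressure_pair):
        m1, _ = constant_pressure_pair
        with pytest.raises(pt.IdentifiabilityError):
            pt.two_maneuver_calibrate(m1, m1)

    def test_noise_free_synthetic_recovery(self, p2):
        slow = pt.generate_bag_maneuver("slow")
        fast = pt.generate_bag_maneuver("fast", profile="trapezoid")
        sensor = pt.SensorModel(spec=p2, noise_sd=0, offset=0)
        m1 = pt.ManeuverRecord(pt.sense(slow, sensor), 1.0, "slow")
        m2 = pt.ManeuverRecord(pt.sense(fast, sensor), 1.0, "fast")
        res = pt.two_maneuver_calibrate(m1, m2)
        assert res.coefficients.k1 == pytest.approx(0.273, rel=1e-6)
        assert res.coefficients.k2 == pytest.approx(1.232, rel=1e-6)


class TestConditioningMetric:
    def test_identical_waveforms_are_singular(self, constant_pressure_pair):
        m1, _ = constant_pressure_pair
        c = pt.RohrerCoefficients(0.2, 1.0)
        assert pt.conditioning_metric(m1, m1, c) > 1e6

    def test_slow_fast_pair_well_conditioned(self, constant_pressure_pair):
        m1, m2 = constant_pressure_pair
        c = pt.RohrerCoefficients(0.2, 1.0)
        assert pt.conditioning_metric(m1, m2, c) < 1e3

    def test_symmetric_under_relabeling(self, constant_pressure_pair):
        m1, m2 = constant_pressure_pair
        c = pt.RohrerCoefficients(0.2, 1.0)
        a = pt.conditioning_metric(m1, m2, c)
        b = pt.conditioning_metric(m2, m1, c)
        assert a == pytest.approx(b, rel=1e-9)


@pytest.fixture(scope="module")
def bag_pairs():
    text = (
        resources.files("pneumotach")
        .joinpath("data/bag_calibrations.json")
        .read_text()
    )
    return json.loads(text)["pairs"]


class TestReproducibilityStats:

    def test_bag_calibration_pair_statistics(self, bag_pairs):
        coeffs = [pt.RohrerCoefficients(p["K1"], p["K2"]) for p in bag_pairs]
        st = pt.reproducibility_stats(coeffs)
        assert st.n_pairs == 4
        assert st.k1_mean == pytest.approx(0.215, abs=1e-3)
        assert st.k1_sd == pytest.approx(0.005, abs=1e-3)
        assert st.k2_mean == pytest.approx(1.101, abs=1e-3)
        assert st.k2_sd == pytest.approx(0.022, abs=1e-3)
        assert st.k2_cv_pct == pytest.approx(2.1, abs=0.1)

    def test_identical_results_have_zero_spread(self):
        c = pt.RohrerCoefficients(0.2, 1.0)
        st = pt.reproducibility_stats([c, c, c])
        assert st.k1_sd == pytest.approx(0.0, abs=1e-15)
        assert st.k2_cv_pct == pytest.approx(0.0, abs=1e-12)

    def test_single_result_rejected(self):
        with pytest.raises(pt.InputError):
            pt.reproducibility_stats([pt.RohrerCoefficients(0.2, 1.0)])


class TestManeuverRecordInvariants:
    def test_nonpositive_volume_rejected(self):
        t = np.linspace(0, 2, 100)
        p = pt.PressureSignal(t=t, y=np.full(100, 0.1))
        with pytest.raises(pt.InputError):
            pt.ManeuverRecord(p, 0.0)

    def test_mixed_sign_record_rejected(self):
        t = np.linspace(0, 2, 100)
        y = np.where(t < 1, 0.5, -0.4)
        with pytest.raises(pt.InputError, match="one-signed"):
            pt.ManeuverRecord(pt.PressureSignal(t=t, y=y), 1.0)

    def test_short_record_rejected(self):
        p = pt.PressureSignal(t=np.linspace(0, 1, 5), y=np.full(5, 0.1))
        with pytest.raises(pt.InputError):
            pt.ManeuverRecord(p, 1.0)
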