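"""Two-maneuver calibration of a Rohrer-type pneumotachograph.

The calibration problem: the sensor's (K1, K2) are unknown, but we hold two
recorded pressure signals P1(t), P2(t) from maneuvers whose total volumes
V1, V2 are known independently (e.g. by water displacement). Since

    volume_i(K1, K2) = ∫ flow_from_pressure(P_i(t); K1, K2) dt

is strictly decreasing in both K1 and K2 (larger resistance means less flow
for the same pressure), the 2x2 nonlinear system

    volume_1(K1, K2) = V1,   volume_2(K1, K2) = V2

can be solved by nested bracketed bisection with guaranteed convergence:
the inner loop solves K1 from maneuver 1 at fixed K2, the outer loop
bisects K2 on the sign change of maneuver 2's residual. The brackets come
from analytic single-coefficient bounds, and nonnegativity is enforced by
construction. The two maneuvers must differ in flow distribution (one slow,
one fast) or the system is ill-conditioned — quantified here by the
condition number of the volume Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import IdentifiabilityError, InputError
from .rohrer import FlowDirection, RohrerCoefficients, _invert_magnitude
from .signals import PressureSignal, active_window, zero_offset_correct

__all__ = [
    "ManeuverRecord",
    "CalibrationOptions",
    "CalibrationResult",
    "ReproducibilityStats",
    "maneuver_volume",
    "two_maneuver_calibrate",
    "conditioning_metric",
    "reproducibility_stats",
]

#: weighted fraction of wrong-signed pressure tolerated in a maneuver record
_SIGN_PURITY_TOL = 0.05


@dataclass(frozen=True)
class ManeuverRecord:
    """One calibration maneuver: pressure record plus its known volume.

    Parameters
    ----------
    pressure : PressureSignal
        Offset-corrected differential pressure, cmH2O. Must be predominantly
        one-signed: the |P|-weighted fraction of samples opposing the
        majority sign must stay below 5%.
    volume : float
        Independently measured maneuver volume, L (e.g. displaced water).
    label : str
        Identifier used in provenance reporting.
    conditions : object, optional
        Ambient conditions under which the volume was measured.
    """

    pressure: PressureSignal
    volume: float
    label: str = ""
    conditions: object | None = None
    validate_sign: bool = True

    def __post_init__(self) -> None:
        if not (self.volume > 0):
            raise InputError("maneuver volume must be positive")
        if len(self.pressure) < 10:
            raise InputError("maneuver pressure record needs >= 10 samples")
        if self.validate_sign:
            w = np.abs(self.pressure.y)
            total = float(w.sum())
            if total > 0:
                sign = 1.0 if float(np.trapezoid(self.pressure.y, self.pressure.t)) >= 0 else -1.0
                minority = float(w[np.sign(self.pressure.y) == -sign].sum())
                if minority / total > _SIGN_PURITY_TOL:
                    raise InputError(
                        "pressure record is not predominantly one-signed; "
                        "apply zero-offset correction first"
                    )

    @property
    def duration(self) -> float:
        return float(self.pressure.t[-1] - self.pressure.t[0])


@dataclass(frozen=True)
class CalibrationOptions:
    """Solver and preprocessing knobs for :func:`two_maneuver_calibrate`.

    ``rel_tol`` is the relative volume-residual target; ``bracket_tol`` the
    absolute half-width at which a coefficient bisection bracket is deemed
    converged.

    With ``auto_offset`` each record is preprocessed before inversion:

    1. a coarse offset (mean of the first ``baseline_window`` seconds, which
       must be quiet) is subtracted;
    2. the active window is located by thresholding a ``crop_smooth``-second
       moving average of |P| at ``crop_factor`` x the smoothed baseline SD —
       smoothing first is what lets the threshold sit far below the maneuver
       pressures without clipping the low-pressure ramps;
    3. the offset is re-estimated from *every* sample outside the active
       window (lead and trail), maximizing the averaging length, and
       subtracted;
    4. the record is cropped to the active window plus ``crop_margin``
       seconds, so baseline noise outside it cannot bias the volume
       integral (the pressure-to-flow inversion is concave near zero, so
       zero-mean noise there would otherwise integrate to spurious volume).

    ``noise_floor`` additionally clamps |P| below the floor to zero.
    """

    rel_tol: float = 1e-10
    bracket_tol: float = 1e-12
    max_iter: int = 100
    auto_offset: bool = False
    baseline_window: float = 1.0
    max_baseline_sd: float | None = None
    crop_factor: float = 5.0
    crop_smooth: float = 0.25
    crop_margin: float = 0.25
    bias_correction: bool = True
    noise_floor: float = 0.0
    condition_threshold: float = 1e3
    direction: FlowDirection = FlowDirection.INHALATION


@dataclass(frozen=True)
class CalibrationResult:
    """Solved coefficients plus residuals and conditioning diagnostics."""

    coefficients: RohrerCoefficients
    residuals: tuple[float, float]
    condition_metric: float
    pair_labels: tuple[str, str]
    offsets: tuple[float, float] = (0.0, 0.0)
    warnings: tuple[str, ...] = ()


def _prepared_pressure(p: PressureSignal, noise_floor: float) -> np.ndarray:
    """Majority-sign-normalized pressure ready for signed inversion.

    The record's majority sign is taken from its integral and factored
    out. Wrong-signed samples below the noise floor are clamped to zero;
    the rest keep their sign and are inverted as (small) reverse flows.
    Keeping the inversion odd around zero means zero-mean sensor noise at
    zero flow integrates to (nearly) zero volume instead of rectifying
    into a positive bias.
    """
    sign = 1.0 if float(np.trapezoid(p.y, p.t)) >= 0 else -1.0
    y = sign * np.asarray(p.y, dtype=float)
    if noise_floor > 0:
        y = np.where((y < 0) & (y > -noise_floor), 0.0, y)
    return y


def _inverted_flow(mag: np.ndarray, k1: float, k2: float, noise_sd: float) -> np.ndarray:
    """Flow magnitudes from pressure magnitudes, optionally bias-corrected.

    Inverting noisy pressure through the concave Rohrer inverse biases the
    flow low: E[v(P + n)] ≈ v(P) + v''(P) σ²/2 with v'' < 0. When the
    sensor noise SD is known (estimated from the quiescent baseline), the
    delta-method correction v(P) − v''(P) σ²/2 removes the second-order
    bias; it is identically zero for noise-free records.
    """
    v = _invert_magnitude(mag, k1, k2)
    if noise_sd > 0 and k2 > 0:
        # evaluate the curvature no closer to zero than the noise scale:
        # below it the second-order expansion is invalid and v'' diverges
        d2 = -2.0 * k2 / np.power(k1 * k1 + 4.0 * k2 * np.maximum(mag, noise_sd), 1.5)
        v = v - 0.5 * d2 * noise_sd**2
    return v


def maneuver_volume(
    pressure: PressureSignal,
    coeffs: RohrerCoefficients,
    noise_floor: float = 0.0,
    noise_sd: float = 0.0,
) -> float:
    """Maneuver volume (L): time integral of the inverted pressure record.

    The record must already be offset-corrected and predominantly
    one-signed. Wrong-signed samples below ``noise_floor`` are clamped to
    zero; remaining wrong-signed samples (noise excursions around zero
    flow) are inverted as reverse flows, which keeps zero-mean noise from
    rectifying into spurious volume. A nonzero ``noise_sd`` enables the
    second-order noise-bias correction of the inversion.
    """
    y = _prepared_pressure(pressure, noise_floor)
    v = np.sign(y) * _inverted_flow(np.abs(y), coeffs.k1, coeffs.k2, noise_sd)
    return float(np.trapezoid(v, pressure.t))


def _volume_fn(pressure: PressureSignal, noise_floor: float, noise_sd: float = 0.0):
    """Precompute the clamped record; return vol(k1, k2) on it."""
    y = _prepared_pressure(pressure, noise_floor)
    t = pressure.t

    sgn = np.sign(y)
    mag = np.abs(y)

    def vol(k1: float, k2: float) -> float:
        v = sgn * _inverted_flow(mag, k1, k2, noise_sd)
        return float(np.trapezoid(v, t))

    return vol, y


def _smooth(y: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return y
    kernel = np.ones(n) / n
    return np.convolve(y, kernel, mode="same")


def _preprocess(
    m: ManeuverRecord, opts: CalibrationOptions
) -> tuple[ManeuverRecord, float, float]:
    """Offset-correct and crop a record; returns (record, offset, noise SD estimate)."""
    if not opts.auto_offset:
        return m, 0.0, 0.0
    # coarse offset from the leading quiet window
    corrected, offset = zero_offset_correct(
        m.pressure, opts.baseline_window, opts.max_baseline_sd
    )
    dt = float(np.median(np.diff(corrected.t)))
    n_smooth = max(int(round(opts.crop_smooth / dt)), 1)
    smooth = _smooth(corrected.y, n_smooth)
    i_base = int(np.searchsorted(corrected.t, corrected.t[0] + opts.baseline_window))
    sd_smooth = float(np.std(smooth[: max(i_base, 5)]))
    noise_sd = float(np.std(corrected.y[: max(i_base, 5)]))
    thr = opts.crop_factor * sd_smooth
    if thr > 0 and np.any(np.abs(smooth) > thr):
        i0, i1 = active_window(
            replace(corrected, y=smooth), thr, margin=opts.crop_margin
        )
        # refine the offset on every quiescent sample (lead + trail)
        quiet = np.ones(len(corrected), dtype=bool)
        quiet[i0 : i1 + 1] = False
        if quiet.sum() >= 5:
            refine = float(np.mean(corrected.y[quiet]))
            noise_sd = float(np.std(corrected.y[quiet]))
            corrected = replace(corrected, y=corrected.y - refine)
            offset += refine
        corrected = corrected.slice(i0, i1)
    return replace(m, pressure=corrected), offset, noise_sd


def two_maneuver_calibrate(
    m1: ManeuverRecord,
    m2: ManeuverRecord,
    options: CalibrationOptions | None = None,
) -> CalibrationResult:
    """Determine (K1, K2) from two maneuvers of known volume.

    Solves ``maneuver_volume(P_i; K1, K2) = V_i`` for i = 1, 2 by nested
    bracketed bisection (see module docstring). Raises
    :class:`IdentifiabilityError` when the pair admits no solution with
    K1, K2 >= 0 — identical maneuvers, or volumes inconsistent with a
    physical resistor. An ill-conditioned but solvable pair returns a
    result carrying a warning and a large ``condition_metric``.
    """
    opts = options or CalibrationOptions()
    m1, off1, sd1 = _preprocess(m1, opts)
    m2, off2, sd2 = _preprocess(m2, opts)
    if not opts.bias_correction:
        sd1 = sd2 = 0.0

    vol1, y1 = _volume_fn(m1.pressure, opts.noise_floor, sd1)
    vol2, y2 = _volume_fn(m2.pressure, opts.noise_floor, sd2)
    t1, t2 = m1.pressure.t, m2.pressure.t
    V1, V2 = m1.volume, m2.volume

    I1 = float(np.trapezoid(y1, t1))  # ∫P1 dt (signed)
    S1 = float(np.trapezoid(np.sign(y1) * np.sqrt(np.abs(y1)), t1))
    if I1 <= 0 or S1 <= 0:
        raise InputError("maneuver 1 pressure record has no signal")
    # single-coefficient bounds: vol1(K1_hi, 0) = V1 and vol1(0, K2_hi) = V1
    k1_hi = I1 / V1
    k2_hi = (S1 / V1) ** 2

    def k1_given_k2(k2: float) -> float:
        """Inner solve: K1 >= 0 with vol1(K1, k2) = V1 (residual decreasing in K1)."""
        if k2 >= k2_hi:
            return 0.0
        lo, hi = 0.0, k1_hi
        for _ in range(opts.max_iter):
            mid = 0.5 * (lo + hi)
            if vol1(mid, k2) > V1:
                lo = mid
            else:
                hi = mid
            if hi - lo < opts.bracket_tol:
                break
        return 0.5 * (lo + hi)

    def outer_residual(k2: float) -> float:
        return vol2(k1_given_k2(k2), k2) - V2

    g0 = outer_residual(0.0)
    g1 = outer_residual(k2_hi)
    # both boundaries satisfying maneuver 2 means every point on maneuver 1's
    # solution curve does: the pair carries one constraint, not two
    degenerate_tol = max(opts.rel_tol, 1e-9)
    if abs(g0) <= degenerate_tol * V2 and abs(g1) <= degenerate_tol * V2:
        raise IdentifiabilityError(
            "maneuvers not identifiable / no physical solution: the two "
            "records constrain (K1, K2) identically (same normalized "
            "waveform); use two maneuvers with different flow magnitudes"
        )
    # boundary solutions (purely linear / purely quadratic resistor)
    if abs(g0) <= opts.rel_tol * V2:
        k1s, k2s = k1_hi, 0.0
    elif abs(g1) <= opts.rel_tol * V2:
        k1s, k2s = 0.0, k2_hi
    elif g0 * g1 > 0:
        raise IdentifiabilityError(
            "maneuvers not identifiable / no physical solution: the volume "
            "residual does not change sign over the admissible (K1, K2) range; "
            "use two maneuvers with clearly different flow magnitudes"
        )
    else:
        lo, hi = 0.0, k2_hi
        glo = g0
        for _ in range(opts.max_iter):
            mid = 0.5 * (lo + hi)
            gm = outer_residual(mid)
            if gm == 0.0:
                lo = hi = mid
                break
            if gm * glo > 0:
                lo, glo = mid, gm
            else:
                hi = mid
            if hi - lo < opts.bracket_tol:
                break
        k2s = 0.5 * (lo + hi)
        k1s = k1_given_k2(k2s)

    coeffs = RohrerCoefficients(k1s, k2s, opts.direction)
    r1 = (vol1(k1s, k2s) - V1) / V1
    r2 = (vol2(k1s, k2s) - V2) / V2

    cond = conditioning_metric(m1, m2, coeffs, noise_floor=opts.noise_floor)
    warns = []
    if cond > opts.condition_threshold:
        msg = (
            f"ill-conditioned maneuver pair (condition metric {cond:.3g} > "
            f"{opts.condition_threshold:.3g}); coefficients are unreliable"
        )
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
    return CalibrationResult(
        coefficients=coeffs,
        residuals=(r1, r2),
        condition_metric=cond,
        pair_labels=(m1.label, m2.label),
        offsets=(off1, off2),
        warnings=tuple(warns),
    )


def conditioning_metric(
    m1: ManeuverRecord,
    m2: ManeuverRecord,
    coeffs: RohrerCoefficients,
    rel_step: float = 1e-6,
    noise_floor: float = 0.0,
) -> float:
    """Condition number of the volume Jacobian at the solved coefficients.

    Central-difference Jacobian of (volume_1/V1, volume_2/V2) with respect
    to (K1, K2). Two maneuvers with the same normalized pressure waveform
    give proportional rows and an (effectively) infinite condition number;
    a well-chosen slow/fast pair stays below ~1e3. Symmetric in (m1, m2)
    up to row order, which the condition number ignores.
    """
    vol1, _ = _volume_fn(m1.pressure, noise_floor)
    vol2, _ = _volume_fn(m2.pressure, noise_floor)
    scale = max(coeffs.k1, coeffs.k2, 1e-6)
    h = rel_step * scale
    J = np.empty((2, 2))
    for j, (k1p, k2p, k1m, k2m) in enumerate(
        [
            (coeffs.k1 + h, coeffs.k2, max(coeffs.k1 - h, 0.0), coeffs.k2),
            (coeffs.k1, coeffs.k2 + h, coeffs.k1, max(coeffs.k2 - h, 0.0)),
        ]
    ):
        dk = (k1p - k1m) if j == 0 else (k2p - k2m)
        J[0, j] = (vol1(k1p, k2p) - vol1(k1m, k2m)) / dk / m1.volume
        J[1, j] = (vol2(k1p, k2p) - vol2(k1m, k2m)) / dk / m2.volume
    cond = float(np.linalg.cond(J))
    return cond


@dataclass(frozen=True)
class ReproducibilityStats:
    """Mean, sample SD (n-1 denominator) and CV% of repeated calibrations."""

    k1_mean: float
    k1_sd: float
    k1_cv_pct: float
    k2_mean: float
    k2_sd: float
    k2_cv_pct: float
    n_pairs: int


def reproducibility_stats(
    results: Sequence[CalibrationResult | RohrerCoefficients],
) -> ReproducibilityStats:
    """Summary statistics across repeated two-maneuver calibrations.

    Accepts CalibrationResult objects or bare coefficient pairs. CV% is
    100 * SD / mean per parameter, the standard dimensionless measure of
    calibration reproducibility.
    """
    if len(results) < 2:
        raise InputError("need at least 2 calibration results")
    coeffs = [
        r.coefficients if isinstance(r, CalibrationResult) else r for r in results
    ]
    k1 = np.array([c.k1 for c in coeffs])
    k2 = np.array([c.k2 for c in coeffs])
    stats = {}
    for name, arr in (("k1", k1), ("k2", k2)):
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        stats[name] = (mean, sd, 100.0 * sd / mean if mean != 0 else float("inf"))
    return ReproducibilityStats(
        k1_mean=stats["k1"][0],
        k1_sd=stats["k1"][1],
        k1_cv_pct=stats["k1"][2],
        k2_mean=stats["k2"][0],
        k2_sd=stats["k2"][1],
        k2_cv_pct=stats["k2"][2],
        n_pairs=len(results),
    )
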