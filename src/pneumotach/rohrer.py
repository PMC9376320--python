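"""Rohrer quadratic resistor model.

A pneumotachograph infers airflow from the pressure drop across a known
resistive element.  For the drilled-channel resistors this package targets,
the pressure–flow relationship is not linear (Poiseuille) but quadratic
(Rohrer):

    P = K1 * V' + K2 * V'**2

with ``K1`` the linear (viscous) component in cmH2O·s/L and ``K2`` the
nonlinear (orifice) component in cmH2O·s²/L².  The effective resistance is
flow dependent, ``R = P/V' = K1 + K2*V'``.

This module provides the forward model, its exact inverse (flow from
pressure), effective resistance, least-squares fitting of the resistance
line, and an analysis of the error incurred when a single mean coefficient
pair replaces direction-specific pairs.

Sign convention: positive flow and positive pressure correspond to the
inhalation direction through the sensor; the caller maps physical
orientation onto this convention.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np

from .errors import CoefficientError, DomainError, InputError, SingularDesignError

__all__ = [
    "FlowDirection",
    "RohrerCoefficients",
    "PneumotachSpec",
    "RohrerFit",
    "SymmetryErrorReport",
    "pressure_from_flow",
    "flow_from_pressure",
    "resistance_at_flow",
    "fit_rohrer",
    "symmetry_error",
    "load_device_table",
]


class FlowDirection(str, enum.Enum):
    INHALATION = "inhalation"
    EXHALATION = "exhalation"
    MEAN = "mean"


@dataclass(frozen=True)
class RohrerCoefficients:
    """A (K1, K2) pair for one flow direction.

    Parameters
    ----------
    k1 : float
        Linear component, cmH2O·s/L. Must be >= 0.
    k2 : float
        Nonlinear component, cmH2O·s²/L². Must be >= 0.
    direction : FlowDirection
        Which flow direction these coefficients describe.
    """

    k1: float
    k2: float
    direction: FlowDirection = FlowDirection.MEAN

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and np.isfinite(self.k2)):
            raise CoefficientError("K1 and K2 must be finite")
        if self.k1 < 0 or self.k2 < 0:
            raise CoefficientError(
                f"negative Rohrer coefficients are unphysical: K1={self.k1}, K2={self.k2}"
            )
        if self.k1 == 0 and self.k2 == 0:
            raise CoefficientError("K1 and K2 cannot both be zero")

    def mean_with(self, other: "RohrerCoefficients") -> "RohrerCoefficients":
        """Element-wise mean of two coefficient pairs."""
        return RohrerCoefficients(
            (self.k1 + other.k1) / 2.0,
            (self.k2 + other.k2) / 2.0,
            FlowDirection.MEAN,
        )


@dataclass(frozen=True)
class PneumotachSpec:
    """A physical device: directional coefficients plus channel geometry."""

    name: str
    inhalation: RohrerCoefficients
    exhalation: RohrerCoefficients
    channel_diameter_mm: float | None = None
    channel_count: int | None = None

    def __post_init__(self) -> None:
        if self.inhalation.direction is not FlowDirection.INHALATION:
            raise InputError("inhalation coefficients must carry direction=inhalation")
        if self.exhalation.direction is not FlowDirection.EXHALATION:
            raise InputError("exhalation coefficients must carry direction=exhalation")

    @classmethod
    def from_dict(cls, d: dict) -> "PneumotachSpec":
        return cls(
            name=str(d["name"]),
            inhalation=RohrerCoefficients(
                d["inhalation"]["K1"], d["inhalation"]["K2"], FlowDirection.INHALATION
            ),
            exhalation=RohrerCoefficients(
                d["exhalation"]["K1"], d["exhalation"]["K2"], FlowDirection.EXHALATION
            ),
            channel_diameter_mm=d.get("channel_diameter_mm"),
            channel_count=d.get("channel_count"),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channel_diameter_mm": self.channel_diameter_mm,
            "channel_count": self.channel_count,
            "inhalation": {"K1": self.inhalation.k1, "K2": self.inhalation.k2},
            "exhalation": {"K1": self.exhalation.k1, "K2": self.exhalation.k2},
        }


def _invert_magnitude(p, k1: float, k2: float):
    """Nonnegative root of K2 v^2 + K1 v - P = 0 for P >= 0 (array-safe).

    Uses v = 2P / (K1 + sqrt(K1^2 + 4 K2 P)), which has no subtractive
    cancellation anywhere in the parameter range, plus explicit linear
    (K2 = 0) and square-root (K1 = 0) limits.
    """
    p = np.asarray(p, dtype=float)
    if k2 == 0.0:
        return p / k1
    if k1 == 0.0:
        return np.sqrt(p / k2)
    return 2.0 * p / (k1 + np.sqrt(k1 * k1 + 4.0 * k2 * p))


def pressure_from_flow(
    flow,
    coeffs_in: RohrerCoefficients,
    coeffs_ex: RohrerCoefficients | None = None,
):
    """Pressure drop (cmH2O, signed) produced by a signed flow (L/s).

    Positive flow uses the inhalation coefficients; negative flow uses the
    exhalation coefficients with the mirrored sign. Continuous and zero at
    zero flow. Accepts scalars or arrays.
    """
    if coeffs_ex is None:
        coeffs_ex = coeffs_in
    v = np.asarray(flow, dtype=float)
    a = np.abs(v)
    p_in = coeffs_in.k1 * a + coeffs_in.k2 * a * a
    p_ex = coeffs_ex.k1 * a + coeffs_ex.k2 * a * a
    out = np.where(v >= 0, p_in, -p_ex)
    return out if out.ndim else float(out)


def flow_from_pressure(
    pressure,
    coeffs_in: RohrerCoefficients,
    coeffs_ex: RohrerCoefficients | None = None,
):
    """Signed flow (L/s) from a signed pressure drop (cmH2O).

    Exact inverse of :func:`pressure_from_flow` on the matching branch:
    positive pressure is inverted with the inhalation coefficients,
    negative with the exhalation coefficients.
    """
    if coeffs_ex is None:
        coeffs_ex = coeffs_in
    p = np.asarray(pressure, dtype=float)
    a = np.abs(p)
    v_in = _invert_magnitude(a, coeffs_in.k1, coeffs_in.k2)
    v_ex = _invert_magnitude(a, coeffs_ex.k1, coeffs_ex.k2)
    out = np.where(p >= 0, v_in, -v_ex)
    return out if out.ndim else float(out)


def resistance_at_flow(flow, coeffs: RohrerCoefficients):
    """Effective resistance R = K1 + K2 * V' (cmH2O·s/L) at flow >= 0."""
    v = np.asarray(flow, dtype=float)
    if np.any(v < 0):
        raise DomainError(
            "resistance_at_flow expects nonnegative flow; dispatch direction upstream"
        )
    out = coeffs.k1 + coeffs.k2 * v
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RohrerFit:
    """Result of fitting the resistance line R = K1 + K2 * V'."""

    coefficients: RohrerCoefficients
    r_squared: float
    n_used: int
    clipped: bool = False


def fit_rohrer(
    samples: Iterable[tuple[float, float]],
    direction: FlowDirection = FlowDirection.MEAN,
) -> RohrerFit:
    """Least-squares fit of the resistance line to (flow, pressure) samples.

    Each sample with flow v > 0 contributes a resistance point
    R = P / v; a straight line R = K1 + K2 * v is fitted by unweighted
    least squares. Zero-flow samples carry no resistance information and
    are excluded. A negative unconstrained intercept or slope is clipped
    to zero with a warning (noise can push a physical coefficient slightly
    past the boundary).

    Returns
    -------
    RohrerFit
        Fitted coefficients, coefficient of determination r² of the
        resistance line, and the number of samples used.
    """
    pts = [(float(v), float(p)) for v, p in samples]
    usable = [(v, p) for v, p in pts if v > 0]
    if len(usable) < 3:
        raise InputError(f"need >= 3 samples with nonzero flow, got {len(usable)}")
    v = np.array([s[0] for s in usable])
    p = np.array([s[1] for s in usable])
    if np.unique(v).size < 2:
        raise SingularDesignError("all flows identical: K1 and K2 are not separable")
    r = p / v
    k2, k1 = np.polyfit(v, r, 1)
    clipped = False
    if k1 < 0 or k2 < 0:
        warnings.warn(
            "unconstrained Rohrer fit gave a negative coefficient; clipping to 0",
            stacklevel=2,
        )
        k1, k2 = max(k1, 0.0), max(k2, 0.0)
        clipped = True
    pred = k1 + k2 * v
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RohrerFit(RohrerCoefficients(k1, k2, direction), r2, len(usable), clipped)


@dataclass(frozen=True)
class SymmetryErrorReport:
    """Worst-case relative flow error from using mean coefficients.

    For each direction, the true directional coefficients generate the
    pressure and the mean pair re-inverts it; the report holds the maximum
    of |v_est - v| / v over the flow grid, and the flow where it occurs.
    """

    mean_coefficients: RohrerCoefficients
    max_error_inhalation: float
    max_error_exhalation: float
    argmax_flow_inhalation: float
    argmax_flow_exhalation: float
    flow_floor: float
    flow_max: float

    @property
    def worst(self) -> float:
        return max(self.max_error_inhalation, self.max_error_exhalation)


def symmetry_error(
    spec: PneumotachSpec,
    flow_max: float,
    n_grid: int = 200,
    flow_floor: float = 0.05,
) -> SymmetryErrorReport:
    """Relative flow error when mean (K1, K2) replace directional pairs.

    The relative-error metric diverges as v -> 0 when K1 differs between
    directions, so flows below ``flow_floor`` (default 0.05 L/s) are
    excluded from the grid.
    """
    if flow_max <= 0:
        raise InputError("flow_max must be positive")
    if flow_floor >= flow_max:
        raise InputError("flow_floor must be below flow_max")
    mean = spec.inhalation.mean_with(spec.exhalation)
    grid = np.linspace(flow_floor, flow_max, n_grid)
    errs = {}
    arg = {}
    for label, coeffs in (("in", spec.inhalation), ("ex", spec.exhalation)):
        p_true = coeffs.k1 * grid + coeffs.k2 * grid * grid
        v_est = _invert_magnitude(p_true, mean.k1, mean.k2)
        rel = np.abs(v_est - grid) / grid
        i = int(np.argmax(rel))
        errs[label] = float(rel[i])
        arg[label] = float(grid[i])
    return SymmetryErrorReport(
        mean_coefficients=mean,
        max_error_inhalation=errs["in"],
        max_error_exhalation=errs["ex"],
        argmax_flow_inhalation=arg["in"],
        argmax_flow_exhalation=arg["ex"],
        flow_floor=flow_floor,
        flow_max=flow_max,
    )


def load_device_table(path: str | None = None) -> dict[str, PneumotachSpec]:
    """Load a JSON table of devices; defaults to the packaged five-device set.

    The packaged table holds the syringe-calibrated coefficients of the five
    drilled-channel pneumotachographs this package was validated against.
    """
    if path is None:
        text = (
            resources.files("pneumotach").joinpath("data/devices.json").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    devices = [PneumotachSpec.from_dict(d) for d in raw["devices"]]
    return {d.name: d for d in devices}
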