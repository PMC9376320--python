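"""Water-displacement volumetry support.

A maneuver's air volume can be measured with no reference flow meter by
pushing the air into a water-filled chamber and collecting the displaced
water. Two physical corrections matter at the ~1% level:

* the displaced water is usually weighed, so converting mass to volume
  needs the temperature-dependent water density (Kell's rational
  polynomial); treating density as exactly 1 g/mL is in error by < 0.5%
  over lab temperatures;
* the chamber air is saturated with vapor while room air is not, so the
  admitted dry air picks up vapor and the displaced volume slightly
  overestimates the maneuver volume. A dry-gas mole balance bounds this
  error.

Both corrections are reported, not silently applied: at typical bench
conditions they are below the reproducibility of the manual maneuvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InputError

__all__ = [
    "AmbientConditions",
    "DisplacementMeasurement",
    "MassVolumeResult",
    "water_density",
    "volume_from_mass",
    "saturation_vapor_pressure",
    "humidity_error_bound",
    "corrected_maneuver_volume",
]


@dataclass(frozen=True)
class AmbientConditions:
    """Lab conditions: temperature (°C), relative humidity (0–1), pressure (kPa)."""

    temperature: float = 20.0
    relative_humidity: float = 0.5
    barometric_pressure: float = 101.325

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 40.0:
            raise DomainError("temperature must be in [0, 40] °C")
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise DomainError("relative humidity must be a fraction in [0, 1]")
        if not 80.0 <= self.barometric_pressure <= 110.0:
            raise DomainError("barometric pressure must be in [80, 110] kPa")


@dataclass(frozen=True)
class DisplacementMeasurement:
    """One water-displacement reading: a mass (g) or a direct volume (mL)."""

    water_mass_g: float | None = None
    direct_volume_ml: float | None = None
    conditions: AmbientConditions = AmbientConditions()
    chamber_initial_volume_l: float | None = None
    mixture_volume_l: float | None = None

    def __post_init__(self) -> None:
        provided = [v for v in (self.water_mass_g, self.direct_volume_ml) if v is not None]
        if len(provided) != 1:
            raise InputError("provide exactly one of water_mass_g or direct_volume_ml")
        if provided[0] <= 0:
            raise InputError("measurement must be positive")

    def volume_l(self, assume_unit_density: bool = False) -> float:
        if self.direct_volume_ml is not None:
            return self.direct_volume_ml / 1000.0
        return volume_from_mass(
            self.water_mass_g, self.conditions.temperature, assume_unit_density
        ).volume_l


# Kell (1975) rational polynomial for air-free pure water, kg/m^3, 0-150 °C;
# matches standard tables within 1e-4 g/mL over [0, 40] °C.
_KELL_NUM = (999.83952, 16.945176, -7.9870401e-3, -46.170461e-6, 105.56302e-9, -280.54253e-12)
_KELL_DEN_B = 16.879850e-3


def water_density(temperature: float) -> float:
    """Density of pure water in g/mL at ``temperature`` °C (range 0–40)."""
    t = float(temperature)
    if not 0.0 <= t <= 40.0:
        raise DomainError(f"temperature {t} °C outside supported range [0, 40]")
    num = 0.0
    for i, c in enumerate(_KELL_NUM):
        num += c * t**i
    return num / (1.0 + _KELL_DEN_B * t) / 1000.0


@dataclass(frozen=True)
class MassVolumeResult:
    """Volume from displaced-water mass, with the unit-density discrepancy."""

    volume_l: float
    density_g_per_ml: float
    unit_density_volume_l: float

    @property
    def unit_density_relative_error(self) -> float:
        """|V_unit - V_exact| / V_exact; < 0.5% over lab temperatures."""
        if self.volume_l == 0:
            return 0.0
        return abs(self.unit_density_volume_l - self.volume_l) / self.volume_l


def volume_from_mass(
    mass_g: float, temperature: float = 20.0, assume_unit_density: bool = False
) -> MassVolumeResult:
    """Convert a displaced-water mass (g) to a volume (L).

    With ``assume_unit_density`` the returned ``volume_l`` is mass/1000
    exactly (the kitchen-scale convention); otherwise the Kell density at
    the given temperature divides the mass. Both conventions are always
    reported so the caller can see the discrepancy.
    """
    if mass_g < 0:
        raise InputError("mass must be nonnegative")
    rho = water_density(temperature)
    exact = mass_g / rho / 1000.0
    unit = mass_g / 1000.0
    return MassVolumeResult(
        volume_l=unit if assume_unit_density else exact,
        density_g_per_ml=rho,
        unit_density_volume_l=unit,
    )


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation vapor pressure of water in kPa (Magnus approximation).

    Accurate to well under 1% over 0–40 °C, far below the ~1% humidity
    effect it feeds into.
    """
    t = float(temperature)
    if not 0.0 <= t <= 40.0:
        raise DomainError(f"temperature {t} °C outside supported range [0, 40]")
    return 0.61094 * math.exp(17.625 * t / (t + 243.04))


def humidity_error_bound(
    conditions: AmbientConditions, saturation_fraction: float = 1.0
) -> float:
    """Relative overestimate of the maneuver volume by water displacement.

    The chamber method reads the maneuver volume as ΔV = V12 − V1, the
    displaced-water volume. The chamber gas sits over liquid water and is
    saturated with vapor; the admitted room air (relative humidity RH) is
    not. If the admitted air reaches a fraction ``s`` of full saturation
    during the maneuver, conserving dry-gas moles at constant temperature
    and pressure gives a relative error

        ε = s · x · (1 − RH) / (1 − x),     x = p_sat(T) / P_atm.

    ``s = 1`` (full saturation, the worst case) at 20 °C, 50% RH and
    standard pressure gives ε ≈ 1.2% — of the order of, and bounding, the
    error of uncorrected displacement volumetry. ``s = 0`` (no evaporation)
    and RH = 1 (saturated room air) both give ε = 0.
    """
    if not 0.0 <= saturation_fraction <= 1.0:
        raise DomainError("saturation_fraction must be in [0, 1]")
    x = saturation_vapor_pressure(conditions.temperature) / conditions.barometric_pressure
    if x >= 1.0:
        raise DomainError("saturation pressure exceeds barometric pressure")
    return saturation_fraction * x * (1.0 - conditions.relative_humidity) / (1.0 - x)


def corrected_maneuver_volume(
    displaced_volume_l: float,
    conditions: AmbientConditions,
    saturation_fraction: float = 1.0,
) -> float:
    """Opt-in humidity correction: ΔV / (1 + ε).

    By default the package reports ε rather than applying it, because at
    bench conditions it is smaller than maneuver-to-maneuver variability.
    """
    eps = humidity_error_bound(conditions, saturation_fraction)
    return displaced_volume_l / (1.0 + eps)
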