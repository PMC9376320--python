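"""Synthetic waveform generator: the hardware-free test bed.

Emulates the three signal sources the calibration and monitoring pipeline
meets on a real bench:

* manual resuscitation-bag maneuvers — a slow one (~1 L in 6–10 s, plateau
  flow 0.1–0.2 L/s) and a fast one (~1 L in 2–3 s), the pair the
  two-maneuver calibration needs;
* ventilator breaths delivered to a one-compartment patient model
  (resistance R, compliance C, time constant τ = R·C): pressure-control
  gives an exponentially decaying inspiratory flow (ΔP/R)·e^(−t/τ) with
  tidal volume ΔP·C·(1 − e^(−Ti/τ)); volume-control gives constant flow
  VT/Ti. Only the inspiratory limb is emitted — the sensor sits in the
  inspiratory line;
* the pneumotachograph itself: the Rohrer forward model plus additive
  Gaussian sensor noise and a constant transducer offset, all seeded and
  bit-reproducible.

Every generated flow carries its exact analytic volume in ``meta``, so
downstream reconstructions can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .rohrer import PneumotachSpec, pressure_from_flow
from .signals import FlowSignal, PressureSignal

__all__ = [
    "PatientModel",
    "SensorModel",
    "generate_bag_maneuver",
    "generate_ventilation",
    "sense",
]

#: defaults chosen to emulate a hand-held bag against a low-cost transducer
DEFAULT_SAMPLE_RATE = 200.0  # Hz
DEFAULT_NOISE_SD = 0.01  # cmH2O
DEFAULT_OFFSET = 0.02  # cmH2O

_SLOW_RANGE = (6.0, 10.0)
_FAST_RANGE = (2.0, 3.0)


@dataclass(frozen=True)
class PatientModel:
    """One-compartment respiratory system: R in cmH2O·s/L, C in L/cmH2O.

    Defaults mimic severe lung disease: R = 20 cmH2O·s/L, C = 20 mL/cmH2O.
    """

    resistance: float = 20.0
    compliance: float = 0.020

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.compliance <= 0:
            raise InputError("resistance and compliance must be positive")

    @property
    def tau(self) -> float:
        """Expiratory/inspiratory time constant τ = R·C, seconds."""
        return self.resistance * self.compliance


@dataclass(frozen=True)
class SensorModel:
    """Pneumotachograph + transducer chain: Rohrer spec, noise, offset, rate."""

    spec: PneumotachSpec
    noise_sd: float = DEFAULT_NOISE_SD
    offset: float = DEFAULT_OFFSET
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")


def _time_base(total: float, sample_rate: float) -> np.ndarray:
    n = int(round(total * sample_rate))
    return np.arange(n + 1) / sample_rate


def generate_bag_maneuver(
    kind: str,
    volume: float = 1.0,
    duration: float | None = None,
    profile: str | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    lead: float = 1.0,
    trail: float = 1.0,
    ramp: float = 1.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> FlowSignal:
    """One manual resuscitation-bag emptying as a unidirectional flow signal.

    Parameters
    ----------
    kind : {"slow", "fast"}
        Slow maneuvers last 6–10 s (default 8 s, trapezoid profile whose
        plateau V/(T − ramp) sits in the 0.1–0.2 L/s band at the 1 L
        default); fast maneuvers last 2–3 s (default 2.5 s, half-sine,
        peak π·V/(2T)).
    volume : float
        Exact delivered volume, L; recorded in ``meta["exact_volume"]``.
    lead, trail : float
        Zero-flow padding (s) before/after the maneuver — the quiescent
        baseline that offset correction needs.
    jitter : float
        Optional hand-tremor emulation: the profile is multiplied by a
        seeded smooth perturbation of this relative amplitude and
        renormalized so the sampled integral is unchanged.
    """
    if kind not in ("slow", "fast"):
        raise InputError("kind must be 'slow' or 'fast'")
    if volume < 0:
        raise InputError("volume must be nonnegative")
    lo, hi = _SLOW_RANGE if kind == "slow" else _FAST_RANGE
    if duration is None:
        duration = 8.0 if kind == "slow" else 2.5
    if not lo <= duration <= hi:
        raise InputError(f"{kind} maneuver duration must be in [{lo}, {hi}] s")
    if profile is None:
        profile = "trapezoid" if kind == "slow" else "half_sine"
    if profile not in ("trapezoid", "half_sine"):
        raise InputError("profile must be 'trapezoid' or 'half_sine'")

    t = _time_base(lead + duration + trail, sample_rate)
    tm = t - lead  # time within the maneuver
    y = np.zeros_like(t)
    inside = (tm >= 0) & (tm <= duration)
    if volume > 0:
        if profile == "half_sine":
            peak = np.pi * volume / (2.0 * duration)
            y[inside] = peak * np.sin(np.pi * tm[inside] / duration)
        else:
            if not 0 < 2 * ramp < duration:
                raise InputError("trapezoid ramp must satisfy 0 < 2*ramp < duration")
            plateau = volume / (duration - ramp)
            x = tm[inside]
            y[inside] = plateau * np.minimum(
                1.0, np.minimum(x / ramp, (duration - x) / ramp)
            )
        if jitter > 0:
            rng = np.random.default_rng(seed)
            phases = rng.uniform(0, 2 * np.pi, 3)
            freqs = rng.uniform(0.5, 2.0, 3)
            mod = 1.0 + jitter * np.mean(
                [np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)],
                axis=0,
            )
            base_integral = np.trapezoid(y, t)
            y = y * mod
            y *= base_integral / np.trapezoid(y, t)
    return FlowSignal(
        t=t,
        y=y,
        meta={
            "exact_volume": float(volume),
            "kind": kind,
            "profile": profile,
            "t_start": float(lead),
            "t_end": float(lead + duration),
        },
    )


def generate_ventilation(
    mode: str,
    setting: float,
    patient: PatientModel = PatientModel(),
    n_breaths: int = 10,
    rate: float = 15.0,
    ti: float = 1.2,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    lead: float = 0.0,
) -> FlowSignal:
    """Inspiratory-line flow of a ventilator breath train.

    Parameters
    ----------
    mode : {"pressure_control", "volume_control"}
    setting : float
        Driving pressure ΔP (cmH2O) for pressure control, or tidal volume
        VT (L) for volume control.
    rate : float
        Breaths per minute; the breath period is 60/rate s and must exceed
        ``ti``.

    Notes
    -----
    Pressure control drives the one-compartment model from zero volume
    each breath: flow (ΔP/R)·e^(−t/τ) during [0, Ti), zero after; the
    exact tidal volume ΔP·C·(1 − e^(−Ti/τ)) per breath is recorded in
    ``meta["tidal_volumes"]``. Volume control delivers VT at constant flow
    VT/Ti. Peak flows above 5 L/s are rejected as implausible for adult
    ventilation.
    """
    if mode not in ("pressure_control", "volume_control"):
        raise InputError("mode must be 'pressure_control' or 'volume_control'")
    if n_breaths < 0:
        raise InputError("n_breaths must be nonnegative")
    period = 60.0 / rate
    if ti >= period:
        raise InputError("inspiratory time must be shorter than the breath period")

    if mode == "pressure_control":
        dp = setting
        if dp <= 0:
            raise InputError("driving pressure must be positive")
        peak = dp / patient.resistance
        vt = dp * patient.compliance * (1.0 - np.exp(-ti / patient.tau))
    else:
        vt = setting
        if vt <= 0:
            raise InputError("tidal volume must be positive")
        peak = vt / ti
    if peak > 5.0:
        raise InputError(f"peak flow {peak:.2f} L/s implausible for adult ventilation")

    total = lead + n_breaths * period
    if n_breaths == 0:
        t = _time_base(max(lead, 2.0 / sample_rate), sample_rate)
        return FlowSignal(t=t, y=np.zeros_like(t), meta={"tidal_volumes": [], "mode": mode})

    t = _time_base(total, sample_rate)
    y = np.zeros_like(t)
    for k in range(n_breaths):
        t0 = lead + k * period
        tm = t - t0
        ins = (tm >= 0) & (tm < ti)
        if mode == "pressure_control":
            y[ins] = peak * np.exp(-tm[ins] / patient.tau)
        else:
            y[ins] = peak
    return FlowSignal(
        t=t,
        y=y,
        meta={
            "tidal_volumes": [float(vt)] * n_breaths,
            "mode": mode,
            "ti": float(ti),
            "period": float(period),
            "peak_flow": float(peak),
        },
    )


def sense(flow: FlowSignal, sensor: SensorModel) -> PressureSignal:
    """Pressure record the transducer would produce for a given true flow.

    Applies the directional Rohrer forward model sample-wise, resamples to
    the sensor rate by linear interpolation, then adds seeded Gaussian
    noise and the constant offset. Identical seeds give bit-identical
    output.
    """
    span = flow.t[-1] - flow.t[0]
    n = int(round(span * sensor.sample_rate))
    t = flow.t[0] + np.arange(n + 1) / sensor.sample_rate
    v = np.interp(t, flow.t, flow.y)
    p = pressure_from_flow(v, sensor.spec.inhalation, sensor.spec.exhalation)
    p = np.asarray(p, dtype=float)
    if sensor.noise_sd > 0:
        rng = np.random.default_rng(sensor.seed)
        p = p + rng.normal(0.0, sensor.noise_sd, p.shape)
    p = p + sensor.offset
    meta = dict(flow.meta)
    meta.update(noise_sd=sensor.noise_sd, offset=sensor.offset, seed=sensor.seed)
    return PressureSignal(t=t, y=p, meta=meta)
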