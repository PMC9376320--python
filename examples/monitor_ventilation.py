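"""Tidal-volume monitoring of mechanical ventilation with a calibrated sensor.

Drives a one-compartment patient model (R = 20 cmH2O·s/L, C = 20 mL/cmH2O,
severe lung disease) in pressure-control and volume-control modes, senses
the inspiratory flow through a calibrated drilled pneumotachograph, and
reconstructs per-breath tidal volumes by inverting and integrating the
pressure signal.
"""

import numpy as np

import pneumotach as pt

device = pt.load_device_table()["pneumotach-2"]
coeffs = device.inhalation  # in practice: from two_maneuver_calibrate
sensor = pt.SensorModel(spec=device, noise_sd=0.0, offset=0.0)

print(f"{'mode':>18} {'setting':>9} {'true VT (L)':>12} {'measured (L)':>13} {'err %':>7}")
for mode, setting, label in [
    ("pressure_control", 10.0, "dP=10 cmH2O"),
    ("pressure_control", 25.0, "dP=25 cmH2O"),
    ("volume_control", 0.3, "VT=0.3 L"),
    ("volume_control", 0.6, "VT=0.6 L"),
]:
    vent = pt.generate_ventilation(mode, setting, n_breaths=5)
    pressure = pt.sense(vent, sensor)
    flow = pt.FlowSignal(
        t=pressure.t, y=np.asarray(pt.flow_from_pressure(pressure.y, coeffs))
    )
    breaths = pt.detect_breaths(flow, threshold=0.05, min_duration=0.1)
    vt_true = vent.meta["tidal_volumes"][0]
    vt_meas = float(np.mean([b.volume for b in breaths]))
    err = 100 * abs(vt_meas - vt_true) / vt_true
    print(f"{mode:>18} {label:>9} {vt_true:12.4f} {vt_meas:13.4f} {err:7.3f}")
# Pressure control delivers a decaying-exponential flow (time constant
# tau = R*C = 0.4 s); volume control a constant flow. Errors stay well
# below the few-percent level that matters clinically.
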