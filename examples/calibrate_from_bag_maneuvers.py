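"""Two-maneuver calibration of a drilled pneumotachograph, hardware-free.

Synthesizes the bench procedure: one slow resuscitation-bag emptying
(1 L over 8 s, plateau flow ~0.14 L/s) and one fast one (1 L over 2.5 s),
both sensed through a Rohrer resistor with realistic transducer noise and
a zero-flow offset. The calibrator then recovers the resistor's (K1, K2)
from the two pressure records plus the two known volumes alone.
"""

import pneumotach as pt

device = pt.load_device_table()["pneumotach-2"]
true = device.inhalation
print(f"true coefficients: K1 = {true.k1}, K2 = {true.k2}")

slow = pt.generate_bag_maneuver("slow")  # 1 L in 8 s, trapezoid profile
fast = pt.generate_bag_maneuver("fast")  # 1 L in 2.5 s, half-sine profile

# a low-cost transducer: 0.01 cmH2O RMS noise, +0.02 cmH2O zero-flow offset
noisy = lambda seed: pt.SensorModel(spec=device, noise_sd=0.01, offset=0.02, seed=seed)
m_slow = pt.ManeuverRecord(pt.sense(slow, noisy(0)), 1.0, "slow", validate_sign=False)
m_fast = pt.ManeuverRecord(pt.sense(fast, noisy(1)), 1.0, "fast", validate_sign=False)

opts = pt.CalibrationOptions(auto_offset=True, baseline_window=0.9, max_baseline_sd=0.05)
result = pt.two_maneuver_calibrate(m_slow, m_fast, opts)
c = result.coefficients

print(f"recovered:         K1 = {c.k1:.4f}, K2 = {c.k2:.4f}")
print(f"relative errors:   {100*abs(c.k1-true.k1)/true.k1:.2f}%, "
      f"{100*abs(c.k2-true.k2)/true.k2:.2f}%")
print(f"volume residuals:  {result.residuals[0]:.2e}, {result.residuals[1]:.2e}")
print(f"condition metric:  {result.condition_metric:.1f}  (pairs above ~1e3 are unreliable)")
print(f"estimated offsets: {result.offsets[0]:.4f}, {result.offsets[1]:.4f} cmH2O (true 0.02)")
# The recovered pair reproduces both maneuver volumes exactly (residuals ~0)
# and lands within a few percent of the true coefficients despite the noise.
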