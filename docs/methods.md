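# Methods

## The sensor model

A drilled-channel flow resistor behaves like a perforated plate: its
pressure–flow relationship is quadratic (Rohrer),

    P = K1·V' + K2·V'²,        R(V') = K1 + K2·V',

with K1 ≥ 0 (cmH₂O·s/L) the viscous and K2 ≥ 0 (cmH₂O·s²/L²) the orifice
component. Each physical device carries one coefficient pair per flow
direction; the package's sign convention is positive flow/pressure =
inhalation through the sensor, with the caller mapping physical
orientation. The packaged `data/devices.json` table holds the
syringe-calibrated pairs of the five drilled devices the toolkit was
designed around (channel diameters 2–3 mm, 19–32 channels, zero-flow
resistances 0.08–0.38 cmH₂O·s/L).

### Inversion

Flow from pressure is the unique nonnegative root of the quadratic,
implemented as

    V' = 2P / (K1 + √(K1² + 4·K2·P)),

which is algebraically identical to the usual quadratic-formula root but
contains no subtraction, so it is numerically stable for every admissible
(K1, K2, P) — including the near-linear regime 4·K2·P ≪ K1² where the
textbook form cancels catastrophically. K2 = 0 (pure linear, V' = P/K1)
and K1 = 0 (pure orifice, V' = √(P/K2)) are explicit branches. Negative
pressures invert through the exhalation pair with mirrored sign, making
the full map continuous and odd-like at zero.

### Fitting and symmetry

`fit_rohrer` fits the *resistance line* R_i = P_i/V'_i against V'_i by
unweighted least squares (zero-flow samples carry no information and are
excluded); a negative unconstrained intercept or slope is clipped to zero
with a warning, since noise can push a physical coefficient slightly past
the boundary. `symmetry_error` quantifies the cost of replacing the two
directional pairs by their element-wise mean: the maximum relative flow
error over a grid of true flows, per direction. The relative metric
diverges as V' → 0 whenever the directional K1 differ, so the grid
excludes flows below a configurable floor (default 0.05 L/s); with that
floor the worst error typically sits *at the floor* (≈4% for the most
asymmetric packaged device), while at 1 L/s the pointwise error is ≈1.3%.
Both views are exposed in the report; neither is collapsed into a single
scalar claim.

## Two-maneuver calibration

The calibration problem: given two recorded pressure signals P₁(t), P₂(t)
and the independently measured volumes V₁, V₂ of the maneuvers that
produced them, find (K1, K2) with

    volume_i(K1, K2) = ∫ flow(P_i(t); K1, K2) dt = V_i,   i = 1, 2.

`volume_i` is strictly decreasing in both K1 and K2 (more resistance ⇒
less flow at the same pressure), which yields a solver with guaranteed
convergence and no initial-guess sensitivity:

1. **Brackets.** K1_hi = (∫P₁ dt)/V₁ solves maneuver 1 exactly with
   K2 = 0; K2_hi = ((∫√P₁ dt)/V₁)² solves it with K1 = 0. Any solution
   lies in [0, K1_hi] × [0, K2_hi]; nonnegativity is enforced by the
   bracket itself.
2. **Inner loop.** For fixed K2, bisect K1 on [0, K1_hi] to satisfy
   maneuver 1 (its residual is strictly decreasing in K1).
3. **Outer loop.** Bisect K2 on the sign change of maneuver 2's residual
   evaluated along the inner solution curve.

Bisection runs to an absolute bracket width of 1e-12 (coefficients are
O(0.1–1) in physical units), giving volume residuals far below the ~2%
empirical reproducibility of manual maneuvers. If the outer residual has
the same sign at both brackets, or both bracket endpoints already satisfy
maneuver 2 (the two records constrain (K1, K2) identically), the pair is
not identifiable and the solver raises instead of returning an arbitrary
point. No Newton-type accelerator is layered on top: full bisection
converges in well under a second at the package's sampling rates, so the
simple path is also the only path.

**Conditioning.** The quality of a pair is the condition number of the
2×2 Jacobian ∂(volume₁/V₁, volume₂/V₂)/∂(K1, K2) (central differences at
the solution). One slow maneuver (plateau flow 0.1–0.2 L/s) plus one fast
maneuver (~0.5 L/s) gives a condition metric ≈ 9; identical waveforms are
singular. Results above a threshold (default 1e3) carry a warning.

**Validation.** Two independent oracles back the solver in the tests:
constant-pressure maneuver pairs reduce to a linear 2×2 system in
(K1, K2) solved in closed form, and a 401×401 brute-force grid search
minimizing the maximum relative residual must agree within one grid cell.

## Preprocessing of noisy records

Real transducer records carry a zero-flow offset and broadband noise;
three steps precede inversion when auto-correction is requested:

1. **Coarse offset.** Mean of a leading baseline window known to be quiet
   (guarded by requiring the window SD below a threshold, typically 5× the
   expected noise SD).
2. **Active-window cropping.** The maneuver is located by thresholding a
   0.25 s moving average of |P| at 5× the *smoothed* baseline SD.
   Smoothing first is essential: the raw-noise threshold (≈0.05 cmH₂O at
   the default noise level) would sit just below a slow maneuver's plateau
   pressure (≈0.064 cmH₂O) and crop away real ramp volume. The offset is
   then re-estimated from every sample outside the active window — the
   longest available averaging window — and the record cropped to the
   active window plus a margin equal to the smoothing length.
3. **Unbiased inversion.** Two effects would otherwise bias the volume
   integral. (a) Clamping wrong-signed samples to zero rectifies zero-mean
   baseline noise into a positive bias (~1% at the default noise level);
   instead, wrong-signed samples are inverted as reverse flows, keeping the
   inversion odd around zero and the noise contribution zero-mean. An
   explicit `noise_floor` option still clamps sub-floor wrong-signed
   samples, for records with known quantization floors. (b) The inverse
   map is concave, so noise biases flow low by ≈ v''(P)σ²/2 per sample
   (≈−0.7% on a slow maneuver); with σ estimated from the baseline, the
   delta-method correction v(P) − v''(P)σ²/2 removes this second-order
   bias. The curvature is evaluated no closer to zero than σ itself, where
   the expansion breaks down. Both corrections vanish identically for
   clean signals.

## Water-displacement volumetry

The maneuver volume is measured as the volume of water the air displaces
from a sealed chamber, usually by weighing. Two physical corrections are
computed (and reported rather than silently applied, because both sit at
or below the manual procedure's own variability):

* **Density.** Mass → volume uses Kell's (1975) rational polynomial for
  air-free pure water, accurate to better than 1e-4 g/mL over 0–40 °C
  (0.9982 g/mL at 20 °C; 0.2% variation between 15 and 25 °C). The
  1 g = 1 mL shortcut errs by < 0.5% at lab temperatures, and both
  conventions are always returned side by side.
* **Humidity.** The chamber gas is saturated with vapor; admitted room
  air at relative humidity RH is not. If the admitted air reaches a
  fraction s of saturation during the maneuver, dry-gas mole conservation
  at constant temperature and pressure gives a relative overestimate of
  the maneuver volume

      ε = s·x·(1 − RH)/(1 − x),   x = p_sat(T)/P_atm,

  with p_sat from the Magnus approximation (error ≪ the ~1% effect over
  0–40 °C). Worst case (s = 1) at 20 °C, 50% RH, 101.325 kPa: ε ≈ 1.2%.
  ε = 0 when the room air is saturated (RH = 1) or nothing evaporates
  (s = 0). An opt-in helper applies ΔV/(1 + ε).

## The synthetic bench

The generator emulates the three signal sources of the physical
procedure; all outputs carry their exact analytic volumes in metadata and
are bit-reproducible given (parameters, seed).

* **Bag maneuvers.** Slow: 1 L in 6–10 s (default 8 s), trapezoid profile
  with 1 s ramps, plateau V/(T−r) = 1/7 ≈ 0.143 L/s — inside the 0.1–0.2
  L/s band the slow maneuver targets. Fast: 1 L in 2–3 s (default 2.5 s),
  half-sine profile, peak πV/2T ≈ 0.63 L/s. Each record includes 1 s of
  zero-flow lead-in and tail — the quiescent baseline a real recording
  needs for offset correction. An optional seeded low-frequency jitter
  (renormalized to preserve the integral) emulates hand tremor.
* **Ventilator breaths.** One-compartment patient model, default R = 20
  cmH₂O·s/L and C = 20 mL/cmH₂O (severe lung disease, τ = 0.4 s).
  Pressure control: inspiratory flow (ΔP/R)e^(−t/τ), exact tidal volume
  ΔP·C·(1 − e^(−Ti/τ)). Volume control: constant flow VT/Ti. Only the
  inspiratory limb is emitted, matching a sensor placed in the
  inspiratory line; peak flows above 5 L/s are rejected as implausible.
* **Sensor chain.** Rohrer forward model per direction, linear-interp
  resampling to the transducer rate (default 200 Hz), seeded Gaussian
  noise (default SD 0.01 cmH₂O) plus a constant offset (default 0.02
  cmH₂O) — magnitudes representative of low-cost unthermostated
  differential-pressure transducers.

**What the generator does not model:** transducer frequency response and
colored noise, thermal offset drift within a record, circuit leaks,
expiratory limbs, patient effort/triggering, and gas-composition effects
on (K1, K2). Passing tests therefore demonstrate the correctness of the
mathematics and robustness to white noise and constant offset, not
immunity to every bench artifact.

**Calibration protocol emulated.** One slow record is combined with each
of several fast records ("slowest paired with each other maneuver"), and
reproducibility is summarized as mean, sample SD (n−1), and CV% per
coefficient across the pairs. Under the default noise conditions this
recovers coefficients within ~1–3% per pair with CVs of a few percent —
the same order as the bench procedure's published reproducibility.

## Problem sizes and numerical choices

Default sampling is 200 Hz (well above the ≤10 Hz content of ventilation
waveforms); synthetic experiments in the test suite use single maneuvers
of 2.5–8 s and breath trains of 5–10 breaths, which exercise every code
path while keeping the full suite around a second of runtime. Integration
is trapezoidal throughout — exact for the generator's piecewise-linear
profiles, second-order otherwise, on uniform or non-uniform time bases.
Solver tolerances (volume residual 1e-10 relative, bracket width 1e-12)
sit orders of magnitude below the empirical reproducibility of the manual
procedure. Degenerate inputs (all-zero pressure, identical maneuvers,
rank-deficient fits, non-monotone time bases) raise typed exceptions
rather than returning silently wrong numbers.
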