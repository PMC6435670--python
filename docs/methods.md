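# Methods

## Model

The package treats BCG genesis as a linear chain: aortic pressure waves →
recoil force → vibrational transmission → limb motion.

**Force model.**  The head-to-foot force is the area-weighted sum of the two
aortic pressure gradients, `F = A_D (P1 − P2) − A_A (P0 − P1)`, with pressures
converted from mmHg to Pa (× 133.322) at the point of use.  This is a
two-segment lumping of the momentum the pressure wave exchanges with the body:
while the pulse travels the ascending aorta the gradient `P0 − P1` pushes blood
footward and the body recoils headward (negative force, the I dip); when the
pulse reaches the descending aorta the gradient `P1 − P2` reverses the
exchange (the J peak).  Linearity makes the ascending/descending decomposition
exact: the responses to the two component forces sum to the total response to
machine precision, which `run_decomposition` asserts on every call.

**Body and instrument.**  Five lumped masses on the head-to-foot axis — upper
torso `m1` (force input), upper limbs `m2`, internal organs `m3`, lower limbs
`m4`, weighing-scale platform `m5` — coupled by six damper/spring pairs on the
connections (1,2), (1,3), (1,4), (3,4), (4,5) and (5, ground).  The ground
spring `k5` is the only connection to a fixed frame, so at DC the entire
applied force crosses it: `H_S(0) = 1/k5` exactly, a closed-form anchor used
in the tests.  The model is linear vibration about standing equilibrium —
gravity and posture enter only through the calibrated parameter values, and
displacements are deviations from rest.  Positive displacement is headward.

Default parameters (masses in kg, dampers in N·s/m, springs stored in N/m,
entered in kN/m as printed in the biomechanics literature):

| m1 9.0 | m2 8.0 | m3 23 | m4 25 | m5 2.5 |
|---|---|---|---|---|
| c12 271 | c13 53 | c14 1056 | c34 32 | c45 1141, c5 722 |
| k12 40.7k | k13 3.15k | k14 31.3k | k34 2.28k | k45 425.3k, k5 833k |

With these values all ten eigenvalues of the first-order system lie strictly
in the left half-plane (slowest decay rate ≈ 1.78 s⁻¹, so transients are gone
to ~1e-9 after 12 beats at 60 bpm).

**Aorta geometry.**  `A_A = 5.0e-4 m²`, `A_D = 3.2e-4 m²` correspond to
typical adult aortic diameters (~2.5 / 2.0 cm) and are documented stand-ins;
absolute (not relative) BCG amplitudes scale proportionally with them.

## Synthetic pressure generator

The generator emulates the features of a three-site aortic recording that the
force model consumes:

* periodicity at the configured heart rate (default 60 bpm, dt = 1 ms — BCG
  content lies below ~20 Hz, and 1 ms resolves the ms-scale intervals);
* per-site diastolic level (70 mmHg) and pulse pressure (40/42/48 mmHg inlet
  → outlet, i.e. built-in distal amplification);
* foot-to-foot transit delays tau01 = 20 ms (inlet→arch) and tau02 = 90 ms
  (inlet→outlet), the handles through which pulse wave velocity enters;
* optional seeded inter-subject variability: independent log-normal factors
  (mean 1, configurable CV) on pulse pressures, delays and times-to-peak.

Each wave is `diastolic + pulse_pressure · g(t − tau_site)` with a single
documented beat template `g`: a systolic raised-cosine lobe (peak at
`time_to_peak`, support twice that), a dicrotic raised-cosine lobe (relative
amplitude 0.2, peak at 2.2 × time-to-peak), plus a small `0.05 sin²(πt/T)`
diastolic-baseline term, all normalized to unit peak and zero minimum.  The
sin² term matters structurally: it is C¹-periodic and vanishes only at the
beat foot, giving each period a unique minimum exactly at the foot, so
foot-to-foot delay estimates (argmin per beat) recover the configured transit
times to within one sample.  Without it the raised-cosine template has a flat
zero baseline and no well-defined foot.

PWV perturbations multiply both delays by `(1 − f)` (positive `f` = faster
wave); PPA perturbations multiply the outlet pulse pressure by `(1 + f)`.
Perturbations edit generator parameters and regenerate — never resample an
existing waveform — avoiding interpolation artifacts.

What the generator does **not** emulate: reflected-wave shoulders, beat-to-beat
(respiratory) variability, measurement noise, or any propagation physics —
delays and amplification are imposed, not derived from a tube model.  Passing
tests therefore demonstrate the mechanics of the pressure→BCG chain under
clean periodic excitation, not detector robustness on noisy recordings.

## Numerics

* **Time simulation** uses the exact zero-order-hold (ZOH) discretization via
  the matrix exponential of the augmented 11×11 system — exact for
  piecewise-constant input and bit-reproducible at fixed dt.
* **Steady-state beats** are computed in the frequency domain with the
  *hold-equivalent* transfer function `H_d(z_k) = C (z_k I − A_d)⁻¹ B_d` at
  the beat harmonics, so the steady beat equals the long-run limit of the time
  simulation to ~1e-13 relative RMS rather than the O(dt) ≈ 1% discrepancy a
  continuous-frequency evaluation would leave.
* **Frequency responses and sensitivities** use per-frequency batched linear
  solves of `Z(jω) = −ω²M + jωC + K` (never an explicit inverse).  The
  sensitivity is fully analytic: `∂H/∂θ = −outᵀ Z⁻¹ (∂Z/∂θ) Z⁻¹ in`, with
  `∂Z/∂θ` the sparse structural pattern each parameter contributes to M, C or
  K.  The `(jω)²` acceleration output factor is parameter-free and cancels in
  the normalized ratio, so wrist displacement and acceleration share one
  sensitivity.  The verification against central finite differences is scored
  relative to each curve's in-band peak: where |S| itself is ~1e-8, the
  difference quotient is round-off noise and a pointwise ratio would be
  meaningless.
* **An independent ODE oracle** (adaptive RK, ZOH input, max step one sample)
  cross-checks the ZOH propagator in tests; it is deliberately not used in the
  production path.
* **Beat window**: one steady-state beat is windowed so the pulsatile force's
  global maximum sits at 15% of the window.  This anchors the window in the
  quiescent diastolic stretch just before the systolic recoil, keeps the whole
  I-J-K response inside one window, and — unlike a zero-crossing anchor —
  varies continuously under timing/amplitude perturbations (a mean-crossing
  can appear or vanish as the force shape changes, tearing the window).
* **Wave detection** lists extrema with prominence ≥ 5% of the beat's
  peak-to-peak (suppressing numerical ripple; configurable), then labels
  displacement beats from J = global maximum (I, K the flanking minima, H the
  maximum preceding I) and acceleration beats from **K = global minimum**
  (J the preceding maximum, L the following maximum, I the minimum preceding
  J).  Anchoring the acceleration rule at the deepest valley rather than the
  tallest peak makes it the exact mirror of the displacement rule, so the
  correspondence that double differentiation implies for band-limited beats —
  acceleration I/J/K/L at the instants of displacement H/I/J/K after a sign
  flip — holds by construction.  The tallest acceleration peak is *not* a safe
  anchor: with the default inputs the descending-gradient response (the L
  wave) outgrows J.  Extremum times and values are refined by a parabola
  through the three surrounding samples, removing the 1 ms grid quantization
  from interval statistics.
* **Wave amplitudes** are measured from the zero-mean steady-state baseline
  (the model oscillates about equilibrium; no other baseline is defined).
* **Calibration** minimizes `J = Σ ((A_model − A_target)/A_target)²` over the
  six primary wave amplitudes (scale I/J/K, wrist-acceleration J/K/L) with
  Nelder-Mead in log-parameter space (parameters are positive and span orders
  of magnitude), box bounds 0.05×–20× nominal, and a seeded 8-start multistart
  around the initial guess.  Trials where a wave becomes undetectable receive
  a large finite penalty (1e6) and are counted, not raised.

## Identifiability and known limitations

* **c5 is weakly identified by amplitudes.**  Its peak in-band normalized
  sensitivity is ≈ 0.12 on the scale channel and ≈ 0.03 at the wrist, so the
  six amplitude targets barely constrain it: noiseless self-consistency
  recovery is exact, but 5% target noise leaves c5 essentially free (it can
  run to its box bound) while c14 and k5 stay within a few percent.
* **Component interaction shifts wave timing.**  The ascending and descending
  gradient responses overlap; the rising descending response pulls the summed
  I minimum ~17 ms earlier than the ascending-only extremum, and the ascending
  rebound pushes the summed J maximum ~16 ms past the descending-only peak
  (default conditions).  Wave times are therefore good *relative* markers but
  biased absolute markers of the underlying gradient timing — the body filter
  adds a further ~19 ms of phase lag.
* **Late acceleration waves are ring-down dominated.**  K and L of the wrist
  acceleration are spaced by the body's resonant ringing (~80 ms), so under
  strong PWV increases the J-L interval flattens and can reverse by a fraction
  of a millisecond even as J-K continues to shrink; interval-based PWV
  surrogates should prefer the early intervals (scale I-J/I-K, wrist J-K).
* The model predicts only gradient-driven waves: features tied directly to
  ventricular ejection (the secondary H wave of the scale BCG, the I wave of
  measured wrist acceleration) are outside its scope, as are multi-axis and
  rotational dynamics, nonlinear tissue behavior, and sensor models beyond the
  single-DOF scale dynamics.

## Study sizes used in tests and the acceptance script

Representative beats use 10-beat records at 1 kHz; oracle-agreement checks use
30 beats (ZOH propagator) and 12 beats (adaptive-step oracle, past the ~1e-9
transient floor); cohorts use 10 subjects at 10% CV; sweeps use the
−20%…+20% grid in 5% steps; sensitivity verification uses 200 log-spaced
points over 0.3–20 Hz.  These sizes were chosen so every statistic sits well
past its convergence floor while the full suite stays quick to run.
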