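# bcgsim

Simulation and analysis of **limb ballistocardiogram (BCG) waveforms** driven by
aortic blood-pressure (BP) waves.

The BCG is the recoil motion of the body in reaction to the blood the heart
ejects.  Measured unobtrusively — as the displacement of a weighing scale under
a standing subject, or as wrist acceleration from a wearable — it is a
candidate signal for cuff-less cardiovascular monitoring.  Interpreting it
requires a physical chain from arterial pressure to limb motion, and that chain
is what this package implements for researchers studying BCG genesis and
BCG-based risk-marker surrogates:

1. **Force generation.**  Three aortic BP waves — inlet `P0`, arch `P1`, outlet
   `P2` (mmHg) — produce a net head-to-foot force through the two aortic
   pressure gradients, weighted by the ascending/descending aortic
   cross-sections `A_A`, `A_D`:

   ```
   F(t) = A_D [P1(t) − P2(t)] − A_A [P0(t) − P1(t)]        [N]
   ```

2. **Vibrational transmission.**  The force excites the upper torso `m1` of a
   5-DOF lumped mass-damper-spring model of the standing body — upper limbs
   `m2`, internal organs `m3`, lower limbs `m4` — plus the weighing-scale
   instrument `m5` on its ground spring `k5`:

   ```
   M q̈ + C q̇ + K q = e₁ F(t)
   ```

   The scale-displacement BCG is `q₅`, the wrist channels are `q₂` and `q̈₂`.

3. **Analysis.**  Frequency-domain transfer functions `H_S(s)`, `H_W(s)`;
   analytic normalized parametric sensitivities
   `S_θ(jω) = (θ₀/H) ∂H/∂θ` for all 17 biomechanical parameters; fiducial
   detection of the named waves (I/J/K on displacement, I/J/K/L on
   acceleration); calibration of `{c14, c5, k5}` by a sum of squared relative
   wave-amplitude errors; exact superposition decomposition into
   ascending/descending gradient components; and perturbation studies of pulse
   wave velocity (PWV, via the inter-site transit delays) and pulse pressure
   amplification (PPA, via the outlet pulse amplitude).

Because invasive three-site aortic recordings are rarely available, the package
includes a parametric generator of synthetic `P0/P1/P2` triples with periodic
beats, site-specific diastolic and pulse levels, transit delays, distal
amplification and seeded inter-subject variability.

## Worked example

```bash
python examples/03_simulate_limb_bcg.py
```

```
scale_disp: I @  86.5 ms =    -0.53 um, J @ 169.5 ms =    +2.62 um, K @ 258.4 ms =    -2.61 um
wrist_disp: I @ 106.4 ms =   -10.07 um, J @ 190.2 ms =   +64.36 um, K @ 281.5 ms =   -59.25 um
 wrist_acc: I @  67.2 ms =   -13.85 mm/s^2, J @ 121.1 ms =   +41.61 mm/s^2, K @ 194.9 ms =   -67.85 mm/s^2, L @ 274.9 ms =   +73.92 mm/s^2

scale I-J interval 83.0 ms, J-K interval 88.9 ms
scale I-J amplitude 3.15 um, J-K amplitude 5.23 um
wrist J-K interval 73.7 ms, K-L interval 80.0 ms
```

One cardiac cycle of the default synthetic subject (60 bpm, 1 kHz): the scale
displacement shows the classical I-valley / J-peak / K-valley triplet a few
micrometers in amplitude, the wrist acceleration the corresponding I/J/K/L
sequence around 0.1 m/s², and the wave-to-wave intervals sit in the
tens-of-milliseconds band reported for standing adults.  The other examples
cover pressure-wave synthesis, force decomposition, sensitivity ranking
(`m2` prominent on both channels, `c14` the leading damper), calibration
recovery, PWV/PPA sweeps (faster pulse waves shorten I-J from 87 to 79 ms and
shrink its amplitude from 3.9 to 2.3 µm; +20% distal amplification raises the
scale J-K amplitude by ~17%), and cohort morphometry with mean ± SE tables.

The `bcgsim` command-line tool exposes the same studies
(`bcgsim --out-dir out simulate | decompose | sweep --kind pwv | sensitivity |
calibrate | cohort`) with a flat YAML config and a run manifest.

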