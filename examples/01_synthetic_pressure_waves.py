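"""Generate the three synthetic aortic pressure waves that drive the model.

The generator produces inlet (P0), arch (P1) and outlet (P2) pressure
waveforms with site-specific diastolic levels, pulse-pressure amplification
toward the outlet, and foot-to-foot transit delays that encode the aortic
pulse wave velocity.
"""

import numpy as np

import bcgsim as b

params = b.BPGeneratorParams()  # 60 bpm, 1 kHz sampling, 10 beats
bp = b.generate_bp_set(params)

print(f"period: {bp.period} s, samples per beat: {bp.p0.samples_per_period}")
for wave in bp.waves():
    print(
        f"{wave.site:>7}: diastolic {np.min(wave.values):6.1f} mmHg, "
        f"systolic {np.max(wave.values):6.1f} mmHg, "
        f"pulse pressure {np.ptp(wave.values):5.1f} mmHg"
    )

n = bp.p0.samples_per_period
lag = (np.argmin(bp.p2.values[:n]) - np.argmin(bp.p0.values[:n])) * params.dt
print(f"foot-to-foot inlet->outlet delay: {lag * 1e3:.0f} ms (configured {params.tau02 * 1e3:.0f} ms)")
print("The delay is the transit time of the pressure pulse down the aorta;")
print("a faster pulse wave velocity shortens it.")

b.write_bp_csv(bp, "bp_example.csv")
print("wrote bp_example.csv (columns time_s,p0_mmhg,p1_mmhg,p2_mmhg)")
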