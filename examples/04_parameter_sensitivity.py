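"""Rank the 17 biomechanical parameters by their influence on each BCG channel.

The normalized sensitivity S(jw) = (theta0/H) dH/dtheta measures the relative
change of the transfer function per relative parameter change; parameters are
ranked by the peak |S| over the 0.3-20 Hz band.
"""

import bcgsim as b

body = b.BodyParameters()
for channel in ("scale_disp", "wrist_acc"):
    ranked = b.rank_parameters(body, channel)
    print(f"{channel}: top five of 17")
    for i, (name, mag) in enumerate(ranked[:5], 1):
        print(f"  {i}. {name:<4} peak |S| = {mag:.2f}")
    top_damper = next(n for n, _ in ranked if n.startswith("c"))
    print(f"  most influential damping element: {top_damper}")

print("\nA peak |S| of 1 means a 1% parameter change moves the response ~1%")
print("at the most affected frequency.  The spinal damping c14 leads the")
print("dampers on both channels, which is why it is the one damping element")
print("worth calibrating against measured wave amplitudes.")
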