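"""Turing space of the Schnakenberg kinetics: membership, sampling, area.

Checks whether parameter points admit diffusion-driven instability, samples
the admissible region uniformly, and estimates how small it is relative to
a vague prior box.
"""

import numpy as np

from turingbayes import sample_turing_space, turing_conditions, turing_space_area

# the reference kinetic parameters used to generate the 2-D pattern data
a, b, d = 0.126779, 0.792366, 10.0
values, inside = turing_conditions(a, b, d)
print(f"(a, b, d) = ({a}, {b}, {d})")
print(f"  trace = {values[0]:+.4f}  (< 0 required)")
print(f"  determinant = {values[1]:+.4f}  (> 0 required)")
print(f"  d-weighted trace = {values[2]:+.4f}  (> 0 required)")
print(f"  discriminant = {values[3]:+.4f}  (> 0 required)")
print(f"  Turing-unstable: {inside}")
# all four inequalities hold: small perturbations of the homogeneous steady
# state grow into stationary spatial patterns

area, ratio = turing_space_area(d, resolution=800)
print(f"\nTuring-space area inside [0.1, 10]^2: {area:.5f}")
print(f"box area / Turing area: {ratio:.0f}")
# the vague prior box is thousands of times larger than the region that can
# pattern at all -- instability theory is extremely informative prior knowledge

points = sample_turing_space(5, d, seed=0)
print("\nfive uniform draws from the Turing space (a, b):")
print(np.round(points, 4))
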