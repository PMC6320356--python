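"""Recover (a, b) from a noisy steady-state pattern (takes a few minutes).

Runs the staged posterior study: Turing-space initialization, annealed
pCN descent, curvature probing, and parallel Metropolis-Hastings sampling,
then summarizes the 95% highest-posterior-density region.
"""

import numpy as np

from turingbayes.posterior import hpd_region
from turingbayes.studies import recover_kinetics_2d

study = recover_kinetics_2d(seed=0)

print(f"true (a, b): ({study.truth[0]}, {study.truth[1]})")
print(f"located mode: {np.round(study.mode.p, 6)} with potential {study.mode.phi:.1f}")
print(f"post-burn-in samples: {len(study.samples)}")
print(f"posterior mean: {np.round(study.samples.mean(axis=0), 6)}")
print(f"posterior sd:   {np.round(study.samples.std(axis=0), 6)}")

region = hpd_region(study.samples, level=0.95, grid_resolution=120)
box = region.bounding_box()
lengths = region.side_lengths()
print(f"95% HPD bounding box: a in [{box[0,0]:.5f}, {box[0,1]:.5f}], "
      f"b in [{box[1,0]:.5f}, {box[1,1]:.5f}]")
print(f"contains the truth: {region.contains(study.truth)}")
print(f"region length ratio b/a: {lengths[1]/lengths[0]:.2f}")
# the credible region is a tiny, anisotropic patch around the truth: b is a
# few times less well determined than a, and both are recovered to three
# significant figures from a single noisy pattern
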