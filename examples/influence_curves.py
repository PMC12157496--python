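"""Evaluate the influence kernel and the model's three sigmoidal laws.

Prints the distance-decay weights of the 7x7 neighborhood, the cumulative
influence maximum used for normalization, and the calibration midpoints of
the switching, division and kill curves.
"""

import numpy as np

from astroabm import InfluenceKernel, influence_weight
from astroabm.astrocytes import switch_probability
from astroabm.chemo import death_probability
from astroabm.tumor import division_probability

kernel = InfluenceKernel(steepness=3.0, half_distance=1.5)

print("distance -> unit influence weight")
for d in (1.0, np.sqrt(2), 1.5, 2.0, 3.0):
    print(f"  d={d:5.3f}   w={influence_weight(d):.4f}")
print(f"kernel maximum (48 offsets, unit magnitude): I_max = {kernel.i_max:.4f}")
print("a fully tumor-occupied neighborhood therefore normalizes to exactly 1\n")

print("calibration midpoints (all exactly 0.5):")
print(f"  division probability at zero influence     = {division_probability(0.0, 8)}")
print(f"  switch probability at the threshold        = {switch_probability(0.3, 16, 0.3)}")
print(f"  kill probability at the half-kill dose     = {death_probability(0.5, 10.0, 0.5)}")
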