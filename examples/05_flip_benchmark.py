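"""Landmark correspondences versus naive x-coordinate flipping.

The classic volume-space estimate of a homotopic partner negates the
x-coordinate. This example measures, for synthetic volume-space
correspondences that are mirrored then shifted 7 mm, how far the true
(landmark-derived) correspondences lie from the flipped locations, and
how often flipping lands outside a grey-matter mask.
"""

import numpy as np

import hemicorr as hc

rng = np.random.default_rng(8)
seeds = rng.uniform(5, 40, size=(500, 3))        # right-of-midline seeds (mm)
acs = seeds.copy()
acs[:, 0] *= -1                                   # true mirror...
acs[:, 1] += 7.0                                  # ...shifted 7 mm posteriorly

# grey-matter mask: two 12 mm-thick slabs flanking the midline
shape = (100, 100, 100)
affine = np.eye(4)
affine[:3, 3] = -50
data = np.zeros(shape)
data[8:42, :, :] = 1
data[58:92, :, :] = 1

res = hc.flip_distance(list(zip(seeds, acs)), (data, affine))
print(f"seeds                          : {len(res.distances)}")
print(f"median flip distance           : {np.median(res.distances):.2f} mm")
print(f"fraction > 5 mm from flip      : {(res.distances > 5).mean():.1%}")
print(f"flipped seeds outside the mask : {res.fraction_flipped_outside_mask:.1%}")
# Every distance equals the constructed 7 mm offset, so 100% of
# correspondences are >5 mm from their flipped estimate — the situation
# the landmark-based method is designed to resolve.
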