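"""Find anatomically homotopic vertex pairs from landmark label vectors.

Builds a mirrored synthetic hemisphere pair with a 24-region
parcellation, describes every vertex by its geodesic distances to the
region centroids, and matches each left vertex to the right vertex with
the most similar (maximally Pearson-correlated) label vector.
"""

import numpy as np

import hemicorr as hc

left, right, mirror = hc.make_hemisphere_pair(n_subdiv=3, perturb=0.0, seed=1)
parc_left = hc.make_parcellation(left, n_regions=24, seed=2)
parc_right = hc.mirror_parcellation(parc_left, mirror, right)

lv_left = hc.build_label_vectors(left, parc_left)
lv_right = hc.build_label_vectors(right, parc_right)
ac = hc.match_anatomical(lv_left, lv_right)

hit = (ac.target_index == mirror).mean()
print(f"vertices per hemisphere : {left.n_vertices}")
print(f"label-vector dimensions : {lv_left.n_regions}")
print(f"AC == true mirror       : {hit:.1%}")
print(f"median match score (rho): {np.nanmedian(ac.score):.6f}")
# On a perfectly mirrored pair the landmark match recovers the true
# homotopic partner at every vertex with correlation 1: the label-vector
# coordinate system is mirror-invariant by construction.
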