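"""Why FAD is needed: a symmetric criss-cross pattern with large AFCD.

Constructs functional correspondences that swap two anatomically paired
nodes: each seed's FC lands far from its own anatomical correspondence
(large AFCD), yet the pattern is perfectly mirror-symmetric — the two
FCs are anatomical correspondences of each other — so FAD is zero.
"""

import numpy as np

import hemicorr as hc

left, right, mirror = hc.make_hemisphere_pair(n_subdiv=3, perturb=0.0, seed=5)
parc_l = hc.make_parcellation(left, 24, seed=6)
parc_r = hc.mirror_parcellation(parc_l, mirror, right)
ac_lr = hc.match_anatomical(hc.build_label_vectors(left, parc_l),
                            hc.build_label_vectors(right, parc_r))
ac_rl = hc.match_anatomical(hc.build_label_vectors(right, parc_r),
                            hc.build_label_vectors(left, parc_l))

v1 = 0
v2 = int(np.argmax(hc.geodesic_from_sources(left, {v1})))  # antipodal seed
w1, w2 = ac_lr.target_index[[v1, v2]]

fc_lr_t = ac_lr.target_index.copy()
fc_lr_t[[v1, v2]] = [w2, w1]          # left seeds' FCs swapped
fc_rl_t = ac_rl.target_index.copy()
fc_rl_t[[w1, w2]] = [v2, v1]          # right seeds mirror the swap
ones = np.ones(left.n_vertices)
fc_lr = hc.CorrespondenceMap(fc_lr_t, ones, "L->R", "functional")
fc_rl = hc.CorrespondenceMap(fc_rl_t, ones.copy(), "R->L", "functional")

afcd_vals = hc.afcd(ac_lr, fc_lr, right)
fad_vals = hc.fad(ac_lr, fc_lr, fc_rl, left, ac_rl)
swap = hc.geodesic_from_sources(right, {int(w1)})[w2]
print(f"swap distance          : {swap:7.2f} mm")
print(f"AFCD at swapped seeds  : {afcd_vals[v1]:7.2f} / {afcd_vals[v2]:7.2f} mm")
print(f"FAD  at swapped seeds  : {fad_vals[v1]:7.2f} / {fad_vals[v2]:7.2f} mm")
# AFCD equals the (large) swap distance, but FAD is zero: a large AFCD
# alone never proves a left/right asymmetry.
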