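"""Quantify functional symmetry with AFCD and FAD.

Runs the full method twice: on a mirror-symmetric scene and on the same
scene with a 25 mm functional displacement injected over one
parcellation region of the right hemisphere. AFCD measures how far each
seed's functional correspondence sits from its anatomical
correspondence; FAD measures genuine left/right asymmetry after
projecting both seeds' functional correspondences to one hemisphere.
"""

import numpy as np

import hemicorr as hc

base = hc.make_scene(n_subdiv=3, n_regions=24, n_networks=4, n_subjects=6,
                     n_timepoints=120, seed=42, simulate=False)
patch = np.flatnonzero(base.parc_left.labels == 0)

for label, asym in (("symmetric", None), ("25 mm displaced patch",
                                          hc.AsymmetrySpec(patch, 25.0))):
    scene = hc.make_scene(n_subdiv=3, n_regions=24, n_networks=4, n_subjects=6,
                          n_timepoints=120, seed=42, asymmetry=asym)
    res = hc.analyze_scene(scene, fwhm=None, fad_threshold=15.0, min_cluster=10)
    print(f"--- {label} ---")
    print(f"median AFCD (L->R) : {np.nanmedian(res['afcd_lr']):6.2f} mm")
    print(f"median FAD         : {np.nanmedian(res['fad']):6.2f} mm")
    print(f"patch mean AFCD    : {np.nanmean(res['afcd_lr'][patch]):6.2f} mm")
    print(f"patch mean FAD     : {np.nanmean(res['fad'][patch]):6.2f} mm")
    print(f"high-FAD clusters  : {len(res['clusters'])}")
# The symmetric scene yields near-zero AFCD/FAD everywhere. With the
# displacement injected, both patch means recover ~25 mm while the rest
# of the cortex stays at zero — the displaced patch shows up as a
# high-FAD cluster.
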