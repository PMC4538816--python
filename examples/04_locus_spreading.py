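"""Quantify factor spreading around a single tethered-nuclease locus.

Simulates nuclei carrying one bright locus each, with a factor channel
decaying as a Gaussian halo from the locus. Compares two conditions whose
planted spreading scales differ twofold using the R50 metric (radius
containing half the background-corrected signal).
"""

import numpy as np

import focimetry as fm

for spread in (2.5, 5.0):
    p = fm.SceneParams(shape=(512, 512), n_nuclei=10, seed=9)
    scene, truth = fm.simulate_locus_scene(p, spread_radius=spread,
                                           factor_amplitude=12000.0)
    nmap = fm.segment_nuclei(scene.channel("dapi"))
    profiles = fm.profile_scene(scene.channel("factor"),
                                scene.channel("locus"), nmap, bin_width=0.5)
    r50 = np.mean([pr.r50 for pr in profiles])
    area = np.mean([pr.expansion_area for pr in profiles])
    print(f"spread SD {spread} px: mean R50 {r50:.2f} px "
          f"(analytic {1.1774 * spread:.2f}), mean expansion area {area:.0f} px")
# R50 tracks sqrt(2 ln 2) x the halo SD; a condition with doubled spreading
# shows a doubled R50, the readout used to compare chromatin spreading
# between perturbations.
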