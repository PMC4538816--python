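"""Simulate a field of nuclei and count DNA-damage foci per cell.

Generates one synthetic scene with a known Poisson foci rate, segments the
nuclei from the DAPI channel, detects foci with the adaptive two-criterion
procedure, and compares per-cell counts against the planted ground truth.
"""

import numpy as np

import focimetry as fm
from focimetry.evaluation import match_foci

params = fm.SceneParams(foci_lambda=6.0, focus_amplitude=(6000.0, 600.0),
                        seed=11)
scene, truth = fm.simulate_scene(params)
print(f"scene: {scene.channels.shape[0]} channels, roles {scene.channel_roles}")

nmap = fm.segment_nuclei(scene.channel("dapi"))
print(f"segmented {nmap.n_nuclei} nuclei "
      f"(ground truth: {truth.labels.max()})")

dog = fm.dog_subtract(scene.channel("foci_A"), 1.0, 4.0)
stats = fm.estimate_background(dog, nmap)
print(f"image-wide median background SD on the DoG raster: "
      f"{stats.median_sd:.1f} intensity units")

foci = fm.detect_foci(dog, nmap, stats, fm.FociParams(k=3.0))
counts = {}
for f in foci:
    counts[f.nucleus_id] = counts.get(f.nucleus_id, 0) + 1
per_cell = [counts.get(int(k), 0) for k in nmap.ids]
print(f"detected {len(foci)} foci; per-cell counts {per_cell}")
print(f"mean foci per cell {np.mean(per_cell):.2f} (planted rate 6.0)")

m = match_foci(foci, truth)
print(f"against ground truth: recall {m['recall']:.3f}, "
      f"precision {m['precision']:.3f}")
# recall/precision near 1 mean the detector recovers almost exactly the
# planted spots; the mean count estimates the per-cell damage load.
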