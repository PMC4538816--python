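# focimetry

Automated, objective quantification of DNA-damage foci (ionizing-radiation-
induced foci, IRIF) in multi-channel fluorescence microscopy images — for
researchers who count repair-factor foci (53BP1, RAD51, BRCA1, γH2AX, …)
per nucleus across conditions, score over-expression/knockdown screens by
their effect on foci formation, measure focus-size distributions, and
quantify how far a factor spreads from a single tethered-nuclease break site.

## The method

1. **Nucleus segmentation.** Nuclei are detected by thresholding the
   median-filtered DAPI channel (Otsu by default), holes are filled, and
   touching nuclei are separated by a watershed on the Euclidean distance
   transform. Undersized and border-truncated objects are discarded.
2. **Adaptive foci detection.** The foci channel is background-subtracted
   with a Difference-of-Gaussians band-pass, I<sub>DoG</sub> = G<sub>σs</sub>∗I − G<sub>σl</sub>∗I.
   Per nucleus *j*, a robust background level b<sub>j</sub> (median) and scale
   s<sub>j</sub> (1.4826·MAD) are estimated on I<sub>DoG</sub>; the image-wide noise scale
   is m = median<sub>j</sub>(s<sub>j</sub>). A pixel is a focus candidate iff

   I<sub>DoG</sub> &gt; b<sub>j</sub> + k·m  (k typically 2–4)  **and**  I<sub>DoG</sub> &gt; absolute minimum,

   and candidates form foci as connected components within one nucleus whose
   area strictly exceeds a minimum (typically 2 px). The per-nucleus offset
   adapts to each cell; the shared scale m makes counts comparable across
   cells. A brute-force flood-fill re-implementation serves as an
   independent oracle in the tests.
3. **Cell-cycle gating.** Cells are gated on a marker channel (e.g.
   mAG-geminin for S/G2) by Otsu over the distribution of per-nucleus means.
4. **Morphometry and screen scoring.** Per-condition mean foci/cell with SD
   and SEM (optionally nested by experiment); focus-size histograms and an
   automatic small/large cutoff (Otsu on log areas); two-channel screen
   entries scored as relative reduction 1 − treated/control per channel and
   categorized (*both* iff &gt;85 % reduction in both channels).
5. **Spreading from a locus.** Around one bright locus per nucleus, a radial
   profile of the factor channel gives R50 (radius containing half the
   background-corrected signal; R50 = √(2 ln 2)·σ ≈ 1.1774 σ for a Gaussian
   halo) and a thresholded expansion area.

No public image data accompany the method, so a synthetic scene generator
(elliptical textured nuclei, Poisson-distributed Gaussian spots, shading
gradient, Poisson+Gaussian camera noise, full ground truth) makes every
stage verifiable at desk scale.

## Worked example

```bash
python examples/01_simulate_and_count.py
```

```
scene: 3 channels, roles {'dapi': 0, 'foci_A': 1, 'marker': 2}
segmented 15 nuclei (ground truth: 15)
image-wide median background SD on the DoG raster: 214.2 intensity units
detected 93 foci; per-cell counts [4, 11, 7, 6, 5, 8, 8, 4, 2, 6, 3, 6, 7, 5, 11]
mean foci per cell 6.20 (planted rate 6.0)
against ground truth: recall 1.000, precision 1.000
```

The scene plants Poisson(6) foci per nucleus; the pipeline recovers every
planted spot (recall/precision 1.0) and the mean count estimates the
planted rate. The other examples cover screen scoring, size morphometry,
locus spreading, and the end-to-end TIFF pipeline; `focimetry --help`
exposes the same stages as shell subcommands (`simulate`, `segment`,
`detect`, `summarize`, `screen`, `spread`, `run`).

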