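# Methods

## Scope and model

focimetry quantifies discrete protein accumulations ("foci") in cell nuclei
from multi-channel fluorescence images. The underlying measurement model:
nuclei are bright, roughly elliptical regions in a DNA counterstain (DAPI);
foci are diffraction-limited or near-diffraction-limited spots riding on a
spatially varying nucleoplasmic background; the camera adds Poisson shot
noise and Gaussian read noise. Counting is per cell, optionally restricted
to cells positive for a cell-cycle or expression marker, and aggregated per
experimental condition.

## Nucleus segmentation

The DAPI channel is median-filtered (disk radius 2 px by default, to
suppress speckle without eroding the boundary), thresholded — Otsu on the
filtered histogram by default, manual override available — and hole-filled.
Touching nuclei are separated by a watershed on the (Gaussian-smoothed,
σ = 1 px) Euclidean distance transform, seeded at distance-map maxima after
h-maxima suppression (h = 2 px). The suppression depth trades
under-segmentation against splitting elongated nuclei: h = 2 px keeps a
single seed in ellipses up to an axis ratio of about 0.5 while still
separating pairs overlapping by a few pixels. Components smaller than
100 px are removed, and border-touching nuclei are excluded by default
(truncated nuclei bias per-cell counts downward). Connectivity is
8-connected throughout. All steps are deterministic; a flat or empty image
yields an empty map, not an error.

Marker gating declares a nucleus positive when its mean marker intensity
exceeds a threshold: Otsu over the distribution of per-nucleus means by
default, requiring at least two nuclei with distinct means (otherwise the
caller is instructed to pass a manual threshold).

## Foci detection

The foci channel is band-passed with a Difference of Gaussians,
σ_small = 1 px and σ_large = 4 px by default, spanning diffraction-limited
spots at typical 63–100× sampling; both are configurable. Gaussian kernels
are truncated at 6σ so the discrete impulse response matches the continuous
two-Gaussian kernel difference to ~1e-9 — an analytic identity the tests
exploit. The filter removes DC, so detections are invariant to constant
offsets in the raw image.

Background statistics are computed per nucleus **on the DoG raster**:
level = median, scale = 1.4826×MAD (robust to focus pixels inflating the
estimate, so no iterative focus exclusion is needed; an alternative
mean/SD-with-3σ-clipping mode is provided). The image-wide noise scale is
the median across nuclei of the per-nucleus scales: per-nucleus offset,
image-wide scale. Nuclei under 10 px are flagged unreliable but computed.

A pixel is a candidate iff its DoG value **strictly** exceeds
(nucleus level + k × image-wide median SD) and strictly exceeds a
user-defined absolute minimum; candidates form connected components
(8-connected by default) that never cross nucleus boundaries, and a
component is a focus iff its area **strictly** exceeds the minimum area
(default 2 px). Strict inequalities implement the "exceeds"/"larger than"
reading of both criteria. Output ordering is deterministic
(nucleus id, centroid y, centroid x).

The absolute minimum is not redundant with the k-fold criterion: the DoG
responds to the step between nucleoplasmic and extranuclear intensity with
a faint positive ring (~4× the noise scale) just inside the nuclear rim.
In cells with few genuine foci the adaptive threshold alone admits this
ring; an absolute minimum set between the ring and genuine spot peaks
removes it. This mirrors how such thresholds are tuned in practice, by
comparing detections with the raw signal. The simulation studies set it to
0.6× the planted DoG-domain spot peak.

`detect_foci_bruteforce` re-implements the identical contract as per-pixel
predicate evaluation plus explicit BFS flood fill, restricted to ≤128×128
rasters; it exists purely as an independent oracle. The dual-route check
caught a genuine defect during development (candidate components bridging
two touching nuclei through boundary pixels and being mis-split), which is
why it is kept as a first-class, permanently tested code path.

## Morphometry

A cell record holds condition, marker status, foci count and focus areas.
Condition summaries report mean foci/cell with both SD and SEM
(SD/√n over cells); when every record carries an experiment id, the nested
convention is used instead — mean of experiment means, SEM across
experiments. Single-cell (or single-experiment) conditions report SEM 0
with an explicit undefined flag and a warning. Focus "size" is the pixel
area of the detected component — the detector's native output — not a
fitted spot width. Size histograms use open-ended outer bins so no focus is
silently dropped. The small/large dichotomy is drawn at a configurable area
cutoff; "auto" applies Otsu to the pooled log-area distribution of a
designated control condition (log domain makes the cutoff scale-equivariant:
multiplying all areas by c multiplies the cutoff by c). A degenerate
distribution (zero spread) is an error instructing a manual cutoff. A
convenience bimodality flag compares 1- vs 2-component Gaussian-mixture BIC
on log areas.

## Screen scoring

Each perturbation is scored per channel as relative reduction
1 − treated/control (negative = increase; control mean must be positive).
Categories, with strict inequalities: **both** iff reduction > 0.85 in both
channels; **A-/B-dominant** iff reduction > threshold_single (default 0.60)
in exactly that channel; otherwise **none**. The 0.85 "both" threshold is
the screen's hit convention; the single-channel threshold is not externally
fixed, so it defaults to 0.60 and is echoed in every output. Means should
be computed over expressing (marker-gated) cells, since over-expression
screens score only transfected cells.

## Spreading from a locus

For tethered-nuclease assays the locus is found per nucleus as the
intensity-weighted centroid of the brightest Otsu-thresholded marker
component; nuclei without a component are skipped with a logged reason.
The factor channel is averaged in concentric annuli (default bin width
1 px) about the locus over nuclear pixels only. Background is the mean
intensity over the outermost quartile of distance bins — the locus signal
is central by construction in this assay, so the nuclear periphery
approximates factor-free chromatin. Two complementary metrics are
reported, because no single canonical definition of "spreading" exists:

* **R50**: the radius at which the cumulative background-corrected signal
  (bin mean × bin pixel count) reaches half its total, linearly
  interpolated between bin edges. For a Gaussian halo of SD σ,
  R50 = √(2 ln 2)·σ ≈ 1.1774 σ. Invariant to positive intensity scaling.
  If the corrected total is non-positive (no excess signal), R50 = 0.
* **Expansion area**: nuclear pixels whose corrected intensity exceeds
  k_spread (default 2) × the background SD; non-increasing in k_spread.

R50 of a tight halo is biased outward when noise contributes comparable
integrated mass at large radii; comparisons should therefore use matched
acquisition settings, and the simulation studies use halo amplitudes high
enough that this bias is negligible.

## Synthetic scenes

The generator emulates what the analysis assumes: rotated-ellipse nuclei
(semi-axes 26–38 px, placed by rejection with ≤5 % pairwise mask overlap)
with Gaussian-filtered-noise texture; per-nucleus Poisson(λ) foci rendered
as 2D Gaussians (σ = 1.5 px, truncated at 4σ) added before noise; a linear
shading gradient; Poisson shot noise on scaled photon counts followed by
Gaussian read noise, clipped to the 16-bit camera range (both noise stages
can be switched off for analytic oracles); an optional marker channel
filling a random fraction of nuclei; and a locus variant with one bright
spot per nucleus plus a Gaussian factor halo of configurable SD. Identical
parameters and seed give bit-identical rasters. Scenes export as
multi-page TIFF plus ground-truth CSVs and a JSON parameter sidecar.

Geometry is chosen self-consistently with the optics: at a sampling where
spots have σ ≈ 1.5 px, nuclei span many tens of pixels. Planted foci keep a
minimum separation of 8 px (~5 spot SDs) by default: spots closer than the
resolution limit merge into one connected component, which no
intensity-thresholding counter can resolve in principle, so the generator
models optically countable foci (set `min_focus_separation=0` to disable).

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: mitotic/apoptotic morphology, nucleoli and
other structured intranuclear background, focus shape irregularity,
chromatic shift between channels, saturation, uneven illumination beyond a
linear gradient, and 3D defocus. Results on simulation bound the
algorithmic error, not the biological error of real images.

## Study problem sizes and numerical choices

The validation studies use 512×512 fields of 15 nuclei; rate-recovery runs
accumulate ≥200 marker-gated cells per condition (λ ∈ {1, 5, 10}) with spot
peaks at 10× the measured DoG-domain noise scale; the screen study draws
150 cells × 2 channels for 60 perturbations; the size study pools ~450 foci
from σ = 1 px vs σ = 3 px populations (detected with a wider band,
σ_large = 8 px, and 20× peaks so that area reflects spot size rather than
threshold marginality); the spreading study profiles 80 nuclei at halo SDs
2.5 vs 5 px. These sizes keep the full suite and the reproduction script to
about a minute each while leaving every recovery criterion several standard
errors of headroom.

Ties and degenerate inputs: strict inequalities at both detection criteria
(a value exactly at threshold, or a component exactly at the minimum area,
is rejected); areas exactly at the small/large cutoff are "small";
reductions exactly at a screen threshold do not qualify; flat images
segment to empty maps; empty inputs to aggregation functions raise with the
gate or field named.

## Known limitations

Per-nucleus background assumes foci occupy a minority of nuclear pixels;
at very high foci density the MAD scale inflates and counts become
conservative. Watershed seeding by h-maxima can split strongly concave or
dumbbell-shaped nuclei. The absolute-minimum parameter is per-experiment
tuning by design, as in the original procedure, and the package provides no
automatic setting for real data. Sub-pixel localization and 3D stacks are
out of scope.
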