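"""Synthetic fluorescence-microscopy scene generator with full ground truth.

Emulates the imaging regime the foci pipeline assumes: fields of view with
elliptical, textured nuclei (DAPI channel), per-nucleus Poisson-distributed
diffraction-limited foci rendered as 2D Gaussian spots on a textured nuclear
background (foci channels), an optional cell-cycle marker channel (a fraction
of nuclei "marker-positive", e.g. geminin-expressing S/G2 cells), a spatially
varying additive background, and a Poisson + Gaussian camera noise model.

Every scene carries its ground truth (nucleus label raster, true focus
positions/amplitudes/sigmas, per-nucleus marker status), so segmentation,
detection, morphometry, screen scoring and spreading can all be validated
against known answers without external image data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage


class PlacementError(RuntimeError):
    """Nucleus placement failed: requested count/radii infeasible for the field."""


@dataclass
class SceneParams:
    """Parameters of one synthetic field of view.

    Intensities are in arbitrary camera units (the rendered rasters are
    clipped to the 16-bit range on export). Lengths are in pixels.
    """

    shape: tuple[int, int] = (512, 512)          # (H, W)
    n_nuclei: int = 15
    nucleus_radius: tuple[float, float] = (26.0, 38.0)  # semi-axis range
    axis_ratio_min: float = 0.7                  # minor/major semi-axis ratio lower bound
    nucleus_intensity: float = 8000.0            # DAPI interior mean
    nucleus_texture_sd: float = 600.0            # interior texture SD (Gaussian-filtered noise)
    foci_lambda: float = 8.0                     # Poisson mean foci per nucleus
    focus_amplitude: tuple[float, float] = (4000.0, 800.0)  # (mean, SD) above local bg
    focus_sigma: float = 1.5                     # Gaussian spot width
    min_focus_separation: float = 8.0            # hard-core distance between foci, px; 0 disables
    foci_background: float = 1200.0              # foci-channel intensity inside nuclei
    foci_texture_sd: float = 150.0               # foci-channel nuclear texture SD
    background_level: float = 300.0              # extranuclear background
    background_gradient: float = 100.0           # amplitude of a linear shading gradient
    read_noise_sd: float = 30.0                  # additive Gaussian read noise; 0 disables
    photon_scale: float | None = 0.05            # photons per camera unit; None disables shot noise
    marker_positive_fraction: float = 0.5        # fraction of nuclei marker-positive
    marker_intensity: float = 5000.0             # marker-channel interior mean for positives
    n_foci_channels: int = 1
    include_marker_channel: bool = True
    max_overlap_fraction: float = 0.05           # allowed pairwise nucleus mask overlap
    max_placement_retries: int = 200
    pixel_size_um: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        rmin, rmax = self.nucleus_radius
        if h <= 0 or w <= 0:
            raise ValueError("field size must be positive")
        if self.n_nuclei < 0:
            raise ValueError("nucleus count must be >= 0")
        if not (0 < rmin <= rmax):
            raise ValueError("nucleus radius range must be strictly positive and ordered")
        if 2 * rmax >= min(h, w):
            raise ValueError("nucleus axes must be smaller than the field")
        if self.foci_lambda < 0:
            raise ValueError("foci rate lambda must be >= 0")
        if not (0.0 <= self.marker_positive_fraction <= 1.0):
            raise ValueError("marker-positive fraction must lie in [0, 1]")
        for name in ("nucleus_intensity", "focus_sigma", "foci_background",
                     "marker_intensity", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.focus_amplitude[0] <= 0:
            raise ValueError("focus amplitude mean must be strictly positive")
        if self.n_foci_channels not in (1, 2):
            raise ValueError("n_foci_channels must be 1 or 2")


@dataclass
class Scene:
    """Multi-channel pixel raster plus channel-role metadata; the unit of processing."""

    channels: np.ndarray                 # float64, shape (C, H, W)
    channel_roles: dict[str, int]        # role -> channel index
    pixel_size_um: float = 0.1

    def channel(self, role: str) -> np.ndarray:
        return self.channels[self.channel_roles[role]]

    def to_uint16(self) -> np.ndarray:
        return np.clip(np.rint(self.channels), 0, 65535).astype(np.uint16)


@dataclass
class TrueFocus:
    nucleus_id: int
    x: float          # column, 0-based, subpixel
    y: float          # row
    amplitude: float
    sigma: float
    channel: str = "foci_A"


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    labels: np.ndarray                       # int32 nucleus label raster, 0 = background
    foci: list[TrueFocus] = field(default_factory=list)
    marker_positive: dict[int, bool] = field(default_factory=dict)
    locus_xy: dict[int, tuple[float, float]] = field(default_factory=dict)

    def foci_per_nucleus(self, channel: str = "foci_A") -> dict[int, int]:
        counts = {int(k): 0 for k in np.unique(self.labels) if k > 0}
        for f in self.foci:
            if f.channel == channel:
                counts[f.nucleus_id] += 1
        return counts

    @property
    def n_foci(self) -> int:
        return len(self.foci)


# ---------------------------------------------------------------------------
# rendering primitives

def _ellipse_mask(shape, cy, cx, a, b, theta):
    """Boolean mask of a rotated ellipse with semi-axes a (along theta) and b."""
    h, w = shape
    # bounding window keeps this O(ellipse), not O(field)
    r = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _smooth_noise(shape, sd, rng, smoothing_sigma=4.0):
    """Gaussian-filtered white noise rescaled to the requested SD (nuclear texture)."""
    if sd <= 0:
        return np.zeros(shape)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), smoothing_sigma)
    s = raw.std()
    return raw * (sd / s) if s > 0 else raw


def add_gaussian_spot(img: np.ndarray, x: float, y: float, amplitude: float,
                      sigma: float, truncate: float = 4.0) -> None:
    """Add a 2D Gaussian spot in place, truncated at ``truncate`` sigmas."""
    h, w = img.shape
    r = int(np.ceil(truncate * sigma))
    y0, y1 = max(0, int(round(y)) - r), min(h, int(round(y)) + r + 1)
    x0, x1 = max(0, int(round(x)) - r), min(w, int(round(x)) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma ** 2)
    )


def apply_camera_noise(img: np.ndarray, params: SceneParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on scaled photon counts, then additive Gaussian read noise."""
    out = img
    if params.photon_scale is not None:
        photons = rng.poisson(np.clip(out, 0, None) * params.photon_scale)
        out = photons / params.photon_scale
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, size=out.shape)
    if params.photon_scale is not None or params.read_noise_sd > 0:
        out = np.clip(out, 0.0, 65535.0)  # camera range; matches uint16 export
    return out


# ---------------------------------------------------------------------------
# nucleus placement

def _place_nuclei(params: SceneParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping rotated ellipses; returns (labels, geoms)."""
    h, w = params.shape
    rmin, rmax = params.nucleus_radius
    labels = np.zeros((h, w), dtype=np.int32)
    geoms = []
    for k in range(1, params.n_nuclei + 1):
        placed = False
        for _ in range(params.max_placement_retries):
            a = rng.uniform(rmin, rmax)
            b = a * rng.uniform(params.axis_ratio_min, 1.0)
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(rmax + 1, h - rmax - 1)
            cx = rng.uniform(rmax + 1, w - rmax - 1)
            mask = _ellipse_mask((h, w), cy, cx, a, b, theta)
            overlap = np.count_nonzero(labels[mask])
            if overlap <= params.max_overlap_fraction * mask.sum():
                labels[mask & (labels == 0)] = k
                geoms.append((cy, cx, a, b, theta))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {k}/{params.n_nuclei} after "
                f"{params.max_placement_retries} retries: field {h}x{w} too dense "
                f"for radii {params.nucleus_radius} at max overlap "
                f"{params.max_overlap_fraction}"
            )
    return labels, geoms


def _sample_point_in_nucleus(labels, k, geom, rng, margin=1.0):
    """Uniform subpixel point inside nucleus k (rejection on the label mask)."""
    cy, cx, a, b, theta = geom
    for _ in range(1000):
        # sample in the ellipse, shrunk by `margin` so the 4-sigma spot core stays inside
        u = rng.uniform(-1, 1)
        v = rng.uniform(-1, 1)
        if u * u + v * v > 1:
            continue
        ct, st = np.cos(theta), np.sin(theta)
        aa = max(a - margin, 0.5)
        bb = max(b - margin, 0.5)
        x = cx + u * aa * ct - v * bb * st
        y = cy + u * aa * st + v * bb * ct
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < labels.shape[0] and 0 <= ix < labels.shape[1] and labels[iy, ix] == k:
            return x, y
    # fall back to the centroid, always inside
    return cx, cy


# ---------------------------------------------------------------------------
# public generators

def simulate_scene(params: SceneParams,
                   foci_lambda_by_channel: dict[str, float] | None = None,
                   ) -> tuple[Scene, GroundTruth]:
    """Render one synthetic field of view with ground truth.

    Parameters
    ----------
    params
        Scene parameters; ``params.seed`` fixes all randomness (identical
        params + seed give bit-identical rasters).
    foci_lambda_by_channel
        Optional per-channel Poisson rates (keys ``foci_A``/``foci_B``)
        overriding ``params.foci_lambda``; used to plant screen effects.

    Returns
    -------
    (Scene, GroundTruth)
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    labels, geoms = _place_nuclei(params, rng)

    foci_roles = ["foci_A"] + (["foci_B"] if params.n_foci_channels == 2 else [])
    lam = {role: params.foci_lambda for role in foci_roles}
    if foci_lambda_by_channel:
        lam.update(foci_lambda_by_channel)

    yy, xx = np.mgrid[0:h, 0:w]
    gradient = params.background_gradient * (xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0
    base_bg = params.background_level + gradient

    dapi = base_bg.copy()
    inside = labels > 0
    dapi[inside] += params.nucleus_intensity
    dapi += _smooth_noise((h, w), params.nucleus_texture_sd, rng) * inside

    foci_imgs = {}
    gt = GroundTruth(labels=labels)
    for role in foci_roles:
        img = base_bg.copy()
        img[inside] += params.foci_background
        img += _smooth_noise((h, w), params.foci_texture_sd, rng) * inside
        counts = rng.poisson(lam[role], size=params.n_nuclei)
        amp_mean, amp_sd = params.focus_amplitude
        for k, geom in enumerate(geoms, start=1):
            placed: list[tuple[float, float]] = []
            for _ in range(int(counts[k - 1])):
                # hard-core placement: foci below the optical resolution limit
                # would merge into one spot, which no intensity-based counter
                # can resolve; the separation floor keeps planted counts
                # physically countable (set min_focus_separation=0 to disable)
                x, y = _sample_point_in_nucleus(labels, k, geom, rng,
                                                margin=2.0 * params.focus_sigma)
                if params.min_focus_separation > 0:
                    for _retry in range(100):
                        if all(np.hypot(x - px, y - py) >= params.min_focus_separation
                               for px, py in placed):
                            break
                        x, y = _sample_point_in_nucleus(
                            labels, k, geom, rng, margin=2.0 * params.focus_sigma)
                placed.append((x, y))
                amp = max(rng.normal(amp_mean, amp_sd), 0.1 * amp_mean)
                add_gaussian_spot(img, x, y, amp, params.focus_sigma)
                gt.foci.append(TrueFocus(k, x, y, amp, params.focus_sigma, role))
        foci_imgs[role] = img

    # marker channel: positives get a bright nuclear fill, negatives stay at background
    marker = None
    status = rng.random(params.n_nuclei) < params.marker_positive_fraction
    gt.marker_positive = {k: bool(status[k - 1]) for k in range(1, params.n_nuclei + 1)}
    if params.include_marker_channel:
        marker = base_bg.copy()
        for k in range(1, params.n_nuclei + 1):
            if status[k - 1]:
                marker[labels == k] += params.marker_intensity

    stack, roles = [dapi], {"dapi": 0}
    for role in foci_roles:
        roles[role] = len(stack)
        stack.append(foci_imgs[role])
    if marker is not None:
        roles["marker"] = len(stack)
        stack.append(marker)

    noisy = np.stack([apply_camera_noise(c, params, rng) for c in stack])
    scene = Scene(channels=noisy, channel_roles=roles,
                  pixel_size_um=params.pixel_size_um)
    return scene, gt


def simulate_locus_scene(params: SceneParams, spread_radius: float,
                         factor_amplitude: float = 4000.0,
                         locus_amplitude: float = 10000.0,
                         locus_sigma: float = 1.2,
                         ) -> tuple[Scene, GroundTruth]:
    """Render a tethered-nuclease (FokI/LacO-style) scene for spreading analysis.

    Each nucleus carries exactly one designated locus: the ``locus`` channel
    holds one bright diffraction-limited spot per nucleus, and the ``factor``
    channel decays as an isotropic Gaussian of SD ``spread_radius`` from the
    locus, on top of the nuclear background.
    """
    if spread_radius <= 0:
        raise ValueError("spread_radius must be strictly positive")
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    labels, geoms = _place_nuclei(params, rng)
    inside = labels > 0

    yy, xx = np.mgrid[0:h, 0:w]
    base_bg = params.background_level + params.background_gradient * (
        xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0

    dapi = base_bg.copy()
    dapi[inside] += params.nucleus_intensity
    dapi += _smooth_noise((h, w), params.nucleus_texture_sd, rng) * inside

    locus = base_bg.copy()
    factor = base_bg.copy()
    factor[inside] += params.foci_background
    factor += _smooth_noise((h, w), params.foci_texture_sd, rng) * inside

    gt = GroundTruth(labels=labels)
    gt.marker_positive = {k: True for k in range(1, params.n_nuclei + 1)}
    for k, (cy, cx, a, b, theta) in enumerate(geoms, start=1):
        # locus near the nucleus center so the spreading halo stays nuclear
        x = cx + rng.uniform(-0.15, 0.15) * a
        y = cy + rng.uniform(-0.15, 0.15) * b
        gt.locus_xy[k] = (x, y)
        add_gaussian_spot(locus, x, y, locus_amplitude, locus_sigma)
        add_gaussian_spot(factor, x, y, factor_amplitude, spread_radius,
                          truncate=6.0)

    stack = np.stack([apply_camera_noise(c, params, rng)
                      for c in (dapi, factor, locus)])
    scene = Scene(channels=stack,
                  channel_roles={"dapi": 0, "factor": 1, "locus": 2},
                  pixel_size_um=params.pixel_size_um)
    return scene, gt


# ---------------------------------------------------------------------------
# disk round-trip

def write_scene(out_dir: str | Path, scene: Scene, gt: GroundTruth,
                params: SceneParams, stem: str = "scene") -> dict[str, Path]:
    """Write TIFF (one page per channel), ground-truth CSVs and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    tiff = out / f"{stem}.tif"
    tifffile.imwrite(tiff, scene.to_uint16(), photometric="minisblack")
    paths["image"] = tiff

    lab = out / f"{stem}_labels.tif"
    tifffile.imwrite(lab, gt.labels.astype(np.uint16))
    paths["labels"] = lab

    foci_csv = out / f"{stem}_true_foci.csv"
    pd.DataFrame(
        [{"nucleus_id": f.nucleus_id, "x": f.x, "y": f.y,
          "amplitude": f.amplitude, "sigma": f.sigma, "channel": f.channel}
         for f in gt.foci]
    ).to_csv(foci_csv, index=False)
    paths["true_foci"] = foci_csv

    nuc_csv = out / f"{stem}_true_nuclei.csv"
    counts = gt.foci_per_nucleus()
    pd.DataFrame(
        [{"nucleus_id": k, "true_foci_count": counts.get(k, 0),
          "marker_positive": gt.marker_positive.get(k, False)}
         for k in sorted(counts)]
    ).to_csv(nuc_csv, index=False)
    paths["true_nuclei"] = nuc_csv

    sidecar = out / f"{stem}_params.json"
    meta = dataclasses.asdict(params)
    meta["channel_roles"] = scene.channel_roles
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    paths["params"] = sidecar
    return paths
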