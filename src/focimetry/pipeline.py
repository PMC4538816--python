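"""End-to-end pipeline: segmentation → background → detection → records.

``PipelineConfig`` is a serializable description of one analysis run
(channel roles, all stage parameters, output directory, seed); given the
same inputs and config, deterministic stages reproduce bit-identical
outputs. ``run_pipeline`` chains the stages per image and aggregates
per-cell records across images, mirroring how a batch of microscopy fields
is analyzed per condition.

Coordinates in every exported CSV are 0-based pixel indices with
x = column and y = row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .foci import (BackgroundStats, FociParams, Focus, detect_foci,
                   dog_subtract, estimate_background, foci_to_frame)
from .morphometry import CellRecord, summaries_to_frame, summarize_condition
from .segmentation import (MarkerGating, NucleusMap, SegmentationParams,
                           gate_marker_positive, segment_nuclei)
from .simulate import Scene

logger = logging.getLogger(__name__)

ROLES = ("dapi", "foci_A", "foci_B", "marker", "locus")


class ConfigError(ValueError):
    """Pipeline configuration violates its schema."""


@dataclass
class PipelineConfig:
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"dapi": 0, "foci_A": 1})
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    foci: FociParams = field(default_factory=FociParams)
    gate_marker: bool = False
    marker_gate_method: str = "otsu"
    marker_gate_threshold: float | None = None
    screen_threshold_both: float = 0.85
    screen_threshold_single: float = 0.60
    size_cutoff: float | str | None = None     # area px, "auto", or None
    spread_bin_width: float = 1.0
    spread_k: float = 2.0
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        roles = self.channel_roles
        bad = set(roles) - set(ROLES)
        if bad:
            raise ConfigError(f"unknown channel roles: {sorted(bad)}")
        if list(roles.values()) != sorted(set(roles.values())):
            raise ConfigError("channel indices must be unique")
        if sum(r == "dapi" for r in roles) != 1:
            raise ConfigError("config must map exactly one channel to 'dapi'")
        self.segmentation.validate()
        self.foci.validate()

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            seg = dict(d["segmentation"])
            if "manual_threshold" not in seg:
                seg["manual_threshold"] = None
            d["segmentation"] = SegmentationParams(**seg)
        if "foci" in d and isinstance(d["foci"], dict):
            d["foci"] = FociParams(**d["foci"])
        try:
            cfg = cls(**d)
        except TypeError as err:
            raise ConfigError(str(err)) from err
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SceneResult:
    scene_id: str
    nmap: NucleusMap
    stats_by_channel: dict[str, BackgroundStats]
    foci_by_channel: dict[str, list[Focus]]
    gating: MarkerGating | None
    records: list[CellRecord]


@dataclass
class ResultBundle:
    scenes: list[SceneResult]
    records: list[CellRecord]
    summary: pd.DataFrame
    config: PipelineConfig


def read_tiff_scene(path: str | Path, roles: dict[str, int]) -> Scene:
    """Read a multi-page TIFF into a Scene using the configured channel roles."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ConfigError(f"{path}: expected a 2D or multi-page TIFF, "
                          f"got shape {arr.shape}")
    n = arr.shape[0]
    for role, idx in roles.items():
        if not (0 <= idx < n):
            raise ConfigError(
                f"{path}: channel role '{role}' maps to index {idx} but the "
                f"image has {n} channel(s)")
    return Scene(channels=arr.astype(np.float64), channel_roles=dict(roles))


def analyze_scene(scene: Scene, config: PipelineConfig,
                  scene_id: str = "scene", condition: str = "control",
                  experiment_id: str | None = None) -> SceneResult:
    """Run segmentation → DoG → background → detection on one scene."""
    config.validate()
    nmap = segment_nuclei(scene.channel("dapi"), config.segmentation)

    gating = None
    if "marker" in scene.channel_roles and nmap.n_nuclei >= 1:
        try:
            gating = gate_marker_positive(
                scene.channel("marker"), nmap,
                method=config.marker_gate_method,
                manual_threshold=config.marker_gate_threshold)
        except ValueError as err:
            logger.info("%s: marker gating unavailable (%s)", scene_id, err)

    foci_by_channel: dict[str, list[Focus]] = {}
    stats_by_channel: dict[str, BackgroundStats] = {}
    for role in ("foci_A", "foci_B"):
        if role not in scene.channel_roles:
            continue
        if nmap.n_nuclei == 0:
            foci_by_channel[role] = []
            continue
        dog = dog_subtract(scene.channel(role), config.foci.dog_sigma_small,
                           config.foci.dog_sigma_large)
        stats = estimate_background(dog, nmap, mode=config.foci.background_mode)
        stats_by_channel[role] = stats
        foci_by_channel[role] = detect_foci(dog, nmap, stats, config.foci)

    primary = foci_by_channel.get("foci_A", [])
    by_nucleus: dict[int, list[Focus]] = {int(k): [] for k in nmap.ids}
    for f in primary:
        by_nucleus[f.nucleus_id].append(f)
    records = []
    for k in nmap.ids:
        k = int(k)
        pos = bool(gating.positive.loc[k]) if gating is not None else True
        fl = by_nucleus[k]
        records.append(CellRecord(
            scene_id=scene_id, nucleus_id=k, condition=condition,
            marker_positive=pos, foci_count=len(fl),
            focus_areas=[f.area for f in fl],
            focus_intensities=[f.integrated_value for f in fl],
            experiment_id=experiment_id))
    logger.info("%s: %d nuclei, %d foci (channel A)",
                scene_id, nmap.n_nuclei, len(primary))
    return SceneResult(scene_id, nmap, stats_by_channel, foci_by_channel,
                       gating, records)


def run_pipeline(inputs, config: PipelineConfig,
                 conditions: list[str] | None = None,
                 out_dir: str | Path | None = None) -> ResultBundle:
    """Analyze a batch of images (paths or in-memory Scenes).

    ``conditions`` optionally labels each input; otherwise all inputs share
    the label "control". Artifacts (per-focus/per-nucleus CSVs, condition
    summary, resolved config) are written when an output directory is given.
    """
    config.validate()
    inputs = list(inputs)
    if conditions is not None and len(conditions) != len(inputs):
        raise ConfigError("conditions list must match the number of inputs")
    if not inputs:
        logger.warning("empty image list: nothing to analyze")
        return ResultBundle([], [], pd.DataFrame(), config)

    scene_results, all_records = [], []
    for i, item in enumerate(inputs):
        cond = conditions[i] if conditions else "control"
        if isinstance(item, Scene):
            scene, sid = item, f"scene_{i:03d}"
        else:
            scene = read_tiff_scene(item, config.channel_roles)
            sid = Path(item).stem
        res = analyze_scene(scene, config, scene_id=sid, condition=cond)
        scene_results.append(res)
        all_records.extend(res.records)

    summaries = []
    for cond in dict.fromkeys(r.condition for r in all_records):
        recs = [r for r in all_records if r.condition == cond]
        try:
            cut = None if config.size_cutoff in (None, "auto") else float(config.size_cutoff)
            summaries.append(summarize_condition(
                recs, gate_marker=config.gate_marker, size_cutoff=cut))
        except ValueError as err:
            logger.warning("condition %s not summarized: %s", cond, err)
    summary = summaries_to_frame(summaries)

    bundle = ResultBundle(scene_results, all_records, summary, config)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# export

def _write_csv(df: pd.DataFrame, path: Path, schema_note: str) -> None:
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".schema.json")
    sidecar.write_text(json.dumps({
        "columns": list(df.columns),
        "note": schema_note,
        "coordinates": "0-based pixel indices, x = column, y = row",
    }, indent=2))


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"scene_id": r.scene_id, "nucleus_id": r.nucleus_id,
          "condition": r.condition, "marker_positive": r.marker_positive,
          "foci_count": r.foci_count,
          "mean_focus_area": float(np.mean(r.focus_areas)) if r.focus_areas else float("nan")}
         for r in records])


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sr in bundle.scenes:
        for role, foci in sr.foci_by_channel.items():
            df = foci_to_frame(foci)
            df.insert(0, "scene_id", sr.scene_id)
            df.insert(1, "channel", role)
            rows.append(df)
    foci_df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    _write_csv(foci_df, out / "foci.csv", "one row per detected focus")
    _write_csv(records_to_frame(bundle.records), out / "cells.csv",
               "one row per analyzed nucleus")
    _write_csv(bundle.summary, out / "condition_summary.csv",
               "one row per condition")
    bundle.config.to_yaml(out / "resolved_config.yaml")
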