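"""Per-cell aggregation, focus-size histograms and small/large classification.

Condition summaries report mean foci per cell with both SD and SEM (figure
conventions in this field use either), optionally nested by experiment
(mean of experiment means, SEM across experiments). Focus "size" is the
pixel area of the detected connected component. The small/large dichotomy —
small foci of typical homologous-recombination size versus larger
signaling-factor foci — is drawn at a configurable area cutoff, or
automatically by Otsu on the pooled log-area distribution of a control
condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu


@dataclass
class CellRecord:
    """One analyzed cell: the atomic row of every downstream aggregate."""

    scene_id: str
    nucleus_id: int
    condition: str
    marker_positive: bool
    foci_count: int
    focus_areas: list[float] = field(default_factory=list)
    focus_intensities: list[float] = field(default_factory=list)
    experiment_id: str | None = None

    def __post_init__(self):
        if self.foci_count != len(self.focus_areas):
            raise ValueError("foci_count must equal len(focus_areas)")


@dataclass
class ConditionSummary:
    condition: str
    n_cells: int
    mean_foci: float
    sd_foci: float
    sem_foci: float
    sem_undefined: bool            # single cell (or single experiment): SEM reported 0
    mean_focus_area: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    fraction_small: float | None = None
    fraction_large: float | None = None
    size_cutoff: float | None = None
    n_experiments: int | None = None


def _gate(records: list[CellRecord], gate_marker: bool) -> list[CellRecord]:
    if not gate_marker:
        return list(records)
    kept = [r for r in records if r.marker_positive]
    if not kept:
        raise ValueError("no cells left after marker-positive gating")
    return kept


def summarize_condition(records: list[CellRecord], gate_marker: bool = False,
                        bin_edges: np.ndarray | None = None,
                        size_cutoff: float | None = None) -> ConditionSummary:
    """Summarize one condition over (optionally marker-gated) cells.

    SEM = SD/sqrt(n) over cells; when every record carries an experiment id,
    the mean is the mean of experiment means and the SEM is taken across
    experiments instead (the nested design used for replicate experiments).
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    gated = _gate(records, gate_marker)
    condition = gated[0].condition
    counts = np.array([r.foci_count for r in gated], dtype=float)

    exp_ids = {r.experiment_id for r in gated}
    n_experiments = None
    if None not in exp_ids and len(exp_ids) >= 1:
        per_exp = {}
        for r in gated:
            per_exp.setdefault(r.experiment_id, []).append(r.foci_count)
        exp_means = np.array([np.mean(v) for v in per_exp.values()])
        n_experiments = len(exp_means)
        mean = float(exp_means.mean())
        if n_experiments > 1:
            sd = float(exp_means.std(ddof=1))
            sem, sem_undefined = sd / np.sqrt(n_experiments), False
        else:
            sd, sem, sem_undefined = 0.0, 0.0, True
            warnings.warn("single experiment: SEM undefined, reported as 0")
    else:
        mean = float(counts.mean())
        if len(counts) > 1:
            sd = float(counts.std(ddof=1))
            sem, sem_undefined = sd / np.sqrt(len(counts)), False
        else:
            sd, sem, sem_undefined = 0.0, 0.0, True
            warnings.warn("single cell: SEM undefined, reported as 0")

    areas = np.concatenate([np.asarray(r.focus_areas, float) for r in gated]) \
        if any(r.focus_areas for r in gated) else np.array([])
    mean_area = float(areas.mean()) if areas.size else float("nan")

    if bin_edges is None:
        top = max(areas.max() if areas.size else 1.0, 10.0)
        bin_edges = np.linspace(0.0, top, 11)
    edges, hist = size_histogram(gated, bin_edges)

    frac_small = frac_large = None
    if size_cutoff is not None and areas.size:
        frac_small = float(np.mean(areas <= size_cutoff))
        frac_large = 1.0 - frac_small

    return ConditionSummary(
        condition=condition, n_cells=len(gated), mean_foci=mean,
        sd_foci=sd, sem_foci=sem, sem_undefined=sem_undefined,
        mean_focus_area=mean_area, hist_edges=edges, hist_counts=hist,
        fraction_small=frac_small, fraction_large=frac_large,
        size_cutoff=size_cutoff, n_experiments=n_experiments)


def size_histogram(records: list[CellRecord],
                   bin_edges) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of focus areas across cells; open-ended outer bins.

    Areas below the first edge land in the first bin, above the last edge
    in the last bin, so no focus is silently dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1D sequence")
    areas = [a for r in records for a in r.focus_areas]
    if not areas:
        return edges, np.zeros(edges.size - 1, dtype=int)
    clipped = np.clip(np.asarray(areas, float),
                      edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return edges, counts


def classify_small_large(records: list[CellRecord],
                         cutoff: float | str = "auto",
                         control_condition: str | None = None,
                         ) -> tuple[pd.DataFrame, dict]:
    """Label every focus "small" (area <= cutoff) or "large".

    ``cutoff="auto"`` sets the boundary by Otsu on the pooled log-area
    distribution of the control condition (all records if no control label
    is given). Returns the per-focus table and a summary dict echoing the
    cutoff and the small/large fractions.
    """
    rows = [{"scene_id": r.scene_id, "nucleus_id": r.nucleus_id,
             "condition": r.condition, "area": float(a)}
            for r in records for a in r.focus_areas]
    if not rows:
        raise ValueError("no foci to classify")
    table = pd.DataFrame(rows)

    if cutoff == "auto":
        pool = table if control_condition is None else \
            table[table.condition == control_condition]
        if pool.empty:
            raise ValueError(f"control condition {control_condition!r} has no foci")
        log_areas = np.log(pool["area"].to_numpy())
        if np.ptp(log_areas) == 0:
            raise ValueError(
                "degenerate size distribution (zero spread): automatic cutoff "
                "impossible, pass a manual cutoff")
        cut = float(np.exp(threshold_otsu(log_areas)))
    else:
        cut = float(cutoff)

    table["size_class"] = np.where(table["area"] <= cut, "small", "large")
    fractions = {
        "cutoff": cut,
        "fraction_small": float((table.size_class == "small").mean()),
        "fraction_large": float((table.size_class == "large").mean()),
        "n_foci": len(table),
    }
    return table, fractions


def is_bimodal(values, n_min: int = 10) -> bool:
    """Heuristic two-mode flag: does a 2-component Gaussian mixture beat one?

    Fits 1- and 2-component mixtures to log-values and compares BIC; used to
    flag bimodal focus-size distributions (two spot-size populations).
    """
    from sklearn.mixture import GaussianMixture

    x = np.log(np.asarray(values, float)).reshape(-1, 1)
    if x.shape[0] < n_min or np.ptp(x) == 0:
        return False
    bic = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, random_state=0, n_init=3).fit(x)
        bic.append(gm.bic(x))
    return bic[1] < bic[0]


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"condition": s.condition, "n_cells": s.n_cells,
          "mean_foci": s.mean_foci, "sd_foci": s.sd_foci,
          "sem_foci": s.sem_foci, "mean_focus_area": s.mean_focus_area,
          "fraction_small": s.fraction_small, "fraction_large": s.fraction_large}
         for s in summaries])
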