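"""Two-channel over-expression screen scoring.

Each perturbation (e.g. an over-expressed de-ubiquitylating enzyme) is scored
by the relative reduction in mean foci per cell in two readout channels
(channel A, a 53BP1-like marker; channel B, a RAD51-like marker) against a
matched control, then placed in a bi-dimensional category:

* ``both``       — reduction strictly > ``threshold_both`` (default 0.85,
                   i.e. >85%) in BOTH channels;
* ``A-dominant`` / ``B-dominant`` — reduction strictly > ``threshold_single``
                   in exactly that channel;
* ``none``       — otherwise.

Means should be computed only over cells expressing the perturbation
(marker-positive gating upstream), as over-expression screens score only
transfected cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORIES = ("none", "A-dominant", "B-dominant", "both")


@dataclass
class ScreenEntry:
    perturbation: str
    mean_a: float
    mean_b: float
    control_mean_a: float
    control_mean_b: float
    reduction_a: float | None = None
    reduction_b: float | None = None
    category: str | None = None


def relative_reduction(treated_mean: float, control_mean: float) -> float:
    """1 - treated/control; negative values mean an increase over control."""
    if control_mean <= 0:
        raise ValueError("control mean must be strictly positive")
    return 1.0 - treated_mean / control_mean


def compute_reductions(entries: list[ScreenEntry]) -> list[ScreenEntry]:
    for e in entries:
        e.reduction_a = relative_reduction(e.mean_a, e.control_mean_a)
        e.reduction_b = relative_reduction(e.mean_b, e.control_mean_b)
    return entries


def categorize(entries: list[ScreenEntry], threshold_both: float = 0.85,
               threshold_single: float = 0.60) -> list[ScreenEntry]:
    """Assign each entry its bi-dimensional category (strict > comparisons).

    A reduction exactly equal to a threshold does NOT qualify. Thresholds
    are echoed back in the exported table.
    """
    for name, thr in (("threshold_both", threshold_both),
                      ("threshold_single", threshold_single)):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1]")
    for e in entries:
        if e.reduction_a is None or e.reduction_b is None:
            compute_reductions([e])
        a_hit = e.reduction_a > threshold_single
        b_hit = e.reduction_b > threshold_single
        if e.reduction_a > threshold_both and e.reduction_b > threshold_both:
            e.category = "both"
        elif a_hit and not b_hit:
            e.category = "A-dominant"
        elif b_hit and not a_hit:
            e.category = "B-dominant"
        else:
            e.category = "none"
    return entries


def score_screen(counts: pd.DataFrame, control: str,
                 threshold_both: float = 0.85,
                 threshold_single: float = 0.60) -> pd.DataFrame:
    """Score a screen from long-format cell-level counts.

    ``counts`` columns: ``perturbation``, ``channel`` ("A" or "B"),
    ``count`` (foci per cell, one row per cell). ``control`` names the
    control perturbation; every other perturbation is scored against it.
    """
    required = {"perturbation", "channel", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    if control not in set(counts.perturbation):
        raise ValueError(f"control perturbation {control!r} not present")

    means = counts.groupby(["perturbation", "channel"])["count"].mean().unstack()
    for ch in ("A", "B"):
        if ch not in means.columns:
            raise ValueError(f"channel {ch!r} missing from counts table")
    ctrl_a, ctrl_b = means.loc[control, "A"], means.loc[control, "B"]

    entries = [ScreenEntry(p, means.loc[p, "A"], means.loc[p, "B"], ctrl_a, ctrl_b)
               for p in means.index if p != control]
    categorize(compute_reductions(entries), threshold_both, threshold_single)

    out = pd.DataFrame(
        [{"perturbation": e.perturbation,
          "mean_A": e.mean_a, "mean_B": e.mean_b,
          "reduction_A": e.reduction_a, "reduction_B": e.reduction_b,
          "category": e.category} for e in entries])
    out.attrs["threshold_both"] = threshold_both
    out.attrs["threshold_single"] = threshold_single
    out.attrs["control"] = control
    return out.sort_values("perturbation").reset_index(drop=True)
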