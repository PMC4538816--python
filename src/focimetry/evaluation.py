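"""Ground-truth matching utilities for validating the pipeline on simulations.

Detected foci are matched one-to-one to planted foci by centroid distance
(greedy nearest-pair assignment); segmented nuclei are matched to true
masks by intersection-over-union.
"""

from __future__ import annotations

import numpy as np

from .foci import Focus
from .segmentation import NucleusMap
from .simulate import GroundTruth


def match_foci(detected: list[Focus], truth: GroundTruth,
               channel: str = "foci_A", max_dist: float = 2.0) -> dict:
    """Greedy one-to-one centroid matching of detections to planted foci.

    Returns recall, precision, F1 and the raw match counts. A detection and
    a true focus may pair only if their centroid distance is <= ``max_dist``
    pixels and they belong to the same nucleus.
    """
    true_pts = [(f.nucleus_id, f.x, f.y) for f in truth.foci
                if f.channel == channel]
    # detected nucleus ids come from the segmentation's labeling, which need
    # not coincide with ground-truth ids: resolve via the true label raster
    h, w = truth.labels.shape

    def _true_label(x, y):
        iy = min(max(int(round(y)), 0), h - 1)
        ix = min(max(int(round(x)), 0), w - 1)
        return int(truth.labels[iy, ix])

    det_pts = [(_true_label(f.centroid_x, f.centroid_y),
                f.centroid_x, f.centroid_y) for f in detected]

    pairs = []
    for i, (nd, xd, yd) in enumerate(det_pts):
        for j, (nt, xt, yt) in enumerate(true_pts):
            if nd != nt:
                continue
            d = float(np.hypot(xd - xt, yd - yt))
            if d <= max_dist:
                pairs.append((d, i, j))
    pairs.sort()
    used_d, used_t = set(), set()
    n_match = 0
    for d, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n_match += 1

    n_true, n_det = len(true_pts), len(det_pts)
    recall = n_match / n_true if n_true else 1.0
    precision = n_match / n_det if n_det else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"recall": recall, "precision": precision, "f1": f1,
            "n_true": n_true, "n_detected": n_det, "n_matched": n_match}


def match_nuclei(nmap: NucleusMap, truth: GroundTruth,
                 iou_threshold: float = 0.8) -> dict:
    """Match segmented nuclei to true masks by best IoU.

    A true nucleus counts as recovered when some predicted label overlaps it
    with IoU above the threshold (each prediction used at most once).
    Border-touching true nuclei are excluded when the segmentation dropped
    border objects (they cannot be recovered by construction).
    """
    pred = nmap.labels
    true = truth.labels
    true_ids = [k for k in np.unique(true) if k > 0]
    # drop true nuclei touching the border if segmentation excluded them
    h, w = true.shape
    border_ids = set(np.unique(np.concatenate([
        true[0, :], true[-1, :], true[:, 0], true[:, -1]])))
    eval_ids = [k for k in true_ids if k not in border_ids]

    used_pred = set()
    matched = 0
    ious = []
    for k in eval_ids:
        tmask = true == k
        overlapping = np.unique(pred[tmask])
        best_iou, best_p = 0.0, None
        for p in overlapping:
            if p == 0 or p in used_pred:
                continue
            pmask = pred == p
            inter = np.count_nonzero(tmask & pmask)
            union = np.count_nonzero(tmask | pmask)
            iou = inter / union
            if iou > best_iou:
                best_iou, best_p = iou, p
        if best_p is not None and best_iou > iou_threshold:
            used_pred.add(best_p)
            matched += 1
            ious.append(best_iou)
    n_eval = len(eval_ids)
    return {"match_rate": matched / n_eval if n_eval else 1.0,
            "n_true": n_eval, "n_matched": matched,
            "n_predicted": nmap.n_nuclei,
            "mean_iou": float(np.mean(ious)) if ious else 0.0}


def per_cell_counts(detected: list[Focus], nmap: NucleusMap) -> dict[int, int]:
    counts = {int(k): 0 for k in nmap.ids}
    for f in detected:
        counts[f.nucleus_id] += 1
    return counts
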