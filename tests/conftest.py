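"""Shared fixtures: synthetic scenes and hand-constructed rasters."""

import numpy as np
import pytest

import focimetry as fm


def dog_attenuation(sigma_f: float, sigma_s: float, sigma_l: float) -> float:
    """Peak attenuation of a Gaussian spot of SD sigma_f under DoG(sigma_s, sigma_l)."""
    f2 = sigma_f ** 2
    return f2 / (f2 + sigma_s ** 2) - f2 / (f2 + sigma_l ** 2)


@pytest.fixture(scope="session")
def high_snr_params():
    """Scene parameters for the high-SNR detection regime used across tests."""
    return fm.SceneParams(foci_lambda=8.0, focus_amplitude=(6000.0, 600.0),
                          seed=7)


@pytest.fixture(scope="session")
def high_snr_scene(high_snr_params):
    return fm.simulate_scene(high_snr_params)


@pytest.fixture(scope="session")
def analyzed_scene(high_snr_scene):
    """Segmentation + DoG + background stats + detections for one scene."""
    scene, gt = high_snr_scene
    nmap = fm.segment_nuclei(scene.channel("dapi"))
    dog = fm.dog_subtract(scene.channel("foci_A"), 1.0, 4.0)
    stats = fm.estimate_background(dog, nmap)
    foci = fm.detect_foci(dog, nmap, stats, fm.FociParams())
    return scene, gt, nmap, dog, stats, foci


def single_nucleus_fixture(size=64, margin=4):
    """A rectangular single-nucleus label map plus zeroed stats (level 0, SD 1)."""
    import pandas as pd
    from focimetry.foci import BackgroundStats
    from focimetry.segmentation import NucleusMap, _build_records

    labels = np.zeros((size, size), dtype=np.int32)
    labels[margin:size - margin, margin:size - margin] = 1
    nmap = NucleusMap(labels=labels, records=_build_records(labels))
    stats = BackgroundStats(
        per_nucleus=pd.DataFrame(
            [{"nucleus_id": 1, "level": 0.0, "sd": 1.0,
              "area": int((size - 2 * margin) ** 2), "unreliable": False}]),
        median_sd=1.0,
        nucleus_ids=np.array([1]))
    return nmap, stats


def random_instance(rng, size=64, n_nuclei=3):
    """A random small raster + label map for oracle-equivalence testing.

    The raster mixes smooth structure, white noise and a few bright plateaus
    so that candidate components of many shapes and areas occur.
    """
    import pandas as pd
    from focimetry.foci import BackgroundStats
    from focimetry.segmentation import NucleusMap, _build_records

    labels = np.zeros((size, size), dtype=np.int32)
    for k in range(1, n_nuclei + 1):
        cy, cx = rng.integers(10, size - 10, 2)
        r = rng.integers(6, 12)
        yy, xx = np.mgrid[0:size, 0:size]
        mask = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2) & (labels == 0)
        labels[mask] = k
    # drop empty labels and relabel contiguously
    from focimetry.segmentation import _relabel
    labels, _ = _relabel(labels)
    nmap = NucleusMap(labels=labels, records=_build_records(labels))

    dog = rng.normal(0, 1.0, (size, size))
    for _ in range(rng.integers(3, 12)):
        y, x = rng.integers(2, size - 2, 2)
        h = rng.uniform(2, 12)
        w = rng.integers(1, 4)
        dog[y:y + w, x:x + w] += h
    if nmap.n_nuclei == 0:
        return None
    rows = [{"nucleus_id": int(k),
             "level": float(rng.uniform(-0.5, 0.5)),
             "sd": float(rng.uniform(0.5, 2.0)),
             "area": int((labels == k).sum()), "unreliable": False}
            for k in nmap.ids]
    per = pd.DataFrame(rows)
    stats = BackgroundStats(per_nucleus=per,
                            median_sd=float(per["sd"].median()),
                            nucleus_ids=np.asarray(nmap.ids))
    return dog, nmap, stats
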