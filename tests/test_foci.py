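"""Foci detection: DoG filter, robust backgrounds, the two adaptive criteria."""

import numpy as np
import pandas as pd
import pytest

import focimetry as fm
from focimetry.evaluation import match_foci
from focimetry.foci import BackgroundStats, FociParams

from conftest import dog_attenuation, random_instance, single_nucleus_fixture


def analytic_dog_kernel(small, large, half=20):
    """Continuous two-Gaussian kernel difference sampled at pixel offsets."""
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    r2 = xx ** 2 + yy ** 2

    def g(s):
        return np.exp(-r2 / (2 * s ** 2)) / (2 * np.pi * s ** 2)

    return g(small) - g(large)


class TestDogSubtract:
    def test_flat_field_maps_to_zero(self):
        out = fm.dog_subtract(np.full((64, 64), 1234.5), 1.0, 4.0)
        assert np.abs(out).max() < 1e-9 * 1234.5

    def test_invalid_sigmas(self):
        with pytest.raises(ValueError):
            fm.dog_subtract(np.zeros((8, 8)), 4.0, 1.0)
        with pytest.raises(ValueError):
            fm.dog_subtract(np.zeros((8, 8)), 2.0, 2.0)

    @pytest.mark.parametrize("sigmas", [(1.0, 4.0), (1.5, 3.0), (2.0, 5.0)])
    def test_impulse_response_matches_analytic_kernel(self, sigmas):
        small, large = sigmas
        n = 101
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = fm.dog_subtract(img, small, large)
        half = 20
        c = n // 2
        got = out[c - half:c + half + 1, c - half:c + half + 1]
        assert np.abs(got - analytic_dog_kernel(small, large, half)).max() < 1e-6

    def test_peak_at_spot_center(self):
        img = np.zeros((64, 64))
        fm.simulate.add_gaussian_spot(img, 30.0, 28.0, 100.0, 1.5)
        out = fm.dog_subtract(img, 1.5, 4.0)
        assert np.unravel_index(np.argmax(out), out.shape) == \
            np.unravel_index(np.argmax(img), img.shape)


class TestEstimateBackground:
    def test_flat_nuclei_give_zero_stats(self):
        nmap, _ = single_nucleus_fixture()
        dog = np.zeros(nmap.labels.shape)
        stats = fm.estimate_background(dog, nmap)
        assert stats.per_nucleus["level"].iloc[0] == 0.0
        assert stats.per_nucleus["sd"].iloc[0] == 0.0
        assert stats.median_sd == 0.0

    def test_image_wide_stat_is_median_of_per_nucleus_sds(self):
        """Three nuclei with noise SDs ~{1, 2, 9}: the image-wide scale is
        the middle one, and equals the median of the per-nucleus column."""
        rng = np.random.default_rng(0)
        labels = np.zeros((60, 180), dtype=np.int32)
        dog = np.zeros((60, 180))
        for i, sd in enumerate([1.0, 2.0, 9.0]):
            sl = np.s_[10:50, 10 + 60 * i:50 + 60 * i]
            labels[sl] = i + 1
            dog[sl] = rng.normal(0, sd, (40, 40))
        from focimetry.segmentation import NucleusMap, _build_records
        nmap = NucleusMap(labels=labels, records=_build_records(labels))
        stats = fm.estimate_background(dog, nmap)
        assert stats.median_sd == pytest.approx(
            float(stats.per_nucleus["sd"].median()))
        assert stats.median_sd == pytest.approx(2.0, rel=0.15)

    def test_mad_tracks_dog_propagated_noise(self):
        """On pure Gaussian noise, the per-nucleus MAD-based SD matches the
        DoG-propagated noise scale measured by brute-force Monte Carlo."""
        rng = np.random.default_rng(1)
        sigma = 5.0
        # independent oracle: empirical SD of the DoG of many noise fields
        samples = [fm.dog_subtract(rng.normal(0, sigma, (96, 96)), 1.0, 4.0)[
            20:-20, 20:-20].ravel() for _ in range(8)]
        oracle_sd = np.concatenate(samples).std()

        nmap, _ = single_nucleus_fixture(size=96, margin=12)
        dog = fm.dog_subtract(rng.normal(0, sigma, (96, 96)), 1.0, 4.0)
        stats = fm.estimate_background(dog, nmap)
        assert stats.per_nucleus["sd"].iloc[0] == pytest.approx(oracle_sd, rel=0.10)

    def test_small_nucleus_flagged_unreliable(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[4:6, 4:6] = 1      # 4 px, below the reliability floor
        labels[10:25, 10:25] = 2
        from focimetry.segmentation import NucleusMap, _build_records
        nmap = NucleusMap(labels=labels, records=_build_records(labels))
        stats = fm.estimate_background(np.zeros((32, 32)), nmap)
        flagged = stats.per_nucleus.set_index("nucleus_id")["unreliable"]
        assert bool(flagged.loc[1]) and not bool(flagged.loc[2])

    def test_empty_map_rejected(self):
        from focimetry.segmentation import NucleusMap
        nmap = NucleusMap(labels=np.zeros((8, 8), dtype=np.int32))
        with pytest.raises(ValueError, match="empty"):
            fm.estimate_background(np.zeros((8, 8)), nmap)


class TestDetectFoci:
    def test_below_absolute_minimum_gives_no_foci(self):
        nmap, stats = single_nucleus_fixture()
        dog = np.full(nmap.labels.shape, 0.4)
        params = FociParams(abs_min=0.5, k=0.1)
        assert fm.detect_foci(dog, nmap, stats, params) == []

    def test_area_criterion_is_strict(self):
        """A plateau of exactly min-area pixels is rejected; one more pixel
        is accepted — 'larger than' means strictly larger."""
        nmap, stats = single_nucleus_fixture()
        params = FociParams(k=3.0, abs_min=0.5, min_area=2)

        dog = np.zeros(nmap.labels.shape)
        dog[20, 20:22] = 10.0            # 2-pixel plateau
        assert fm.detect_foci(dog, nmap, stats, params) == []

        dog[20, 20:23] = 10.0            # 3-pixel plateau
        foci = fm.detect_foci(dog, nmap, stats, params)
        assert len(foci) == 1 and foci[0].area == 3

    @pytest.mark.parametrize("k", [2.0, 3.0, 4.0])
    def test_intensity_criterion_is_strict_and_adaptive(self, k):
        """With per-nucleus background b and image-wide median SD m, value
        b + k*m + eps is detected and b + k*m - eps is not."""
        from focimetry.segmentation import NucleusMap, _build_records
        labels = np.zeros((40, 90), dtype=np.int32)
        labels[5:35, 5:40] = 1
        labels[5:35, 50:85] = 2
        nmap = NucleusMap(labels=labels, records=_build_records(labels))
        b = {1: 0.0, 2: 7.0}
        m = 2.0
        stats = BackgroundStats(
            per_nucleus=pd.DataFrame(
                [{"nucleus_id": i, "level": b[i], "sd": s, "area": 900,
                  "unreliable": False} for i, s in ((1, 1.0), (2, 3.0))]),
            median_sd=m, nucleus_ids=np.array([1, 2]))
        params = FociParams(k=k, abs_min=-np.inf, min_area=2)
        eps = 1e-6
        for nid, (y0, x0) in ((1, (10, 10)), (2, (10, 55))):
            for sign, expected in ((+1, 1), (-1, 0)):
                dog = np.zeros(labels.shape)
                dog[y0:y0 + 2, x0:x0 + 2] = b[nid] + k * m + sign * eps
                foci = fm.detect_foci(dog, nmap, stats, params)
                in_nucleus = [f for f in foci if f.nucleus_id == nid]
                assert len(in_nucleus) == expected, (nid, sign)

    def test_high_snr_recall_and_precision(self, analyzed_scene):
        _, gt, _, _, _, foci = analyzed_scene
        m = match_foci(foci, gt)
        assert m["recall"] >= 0.95
        assert m["precision"] >= 0.95

    def test_containment_in_nucleus(self, analyzed_scene):
        _, _, nmap, _, _, foci = analyzed_scene
        for f in foci:
            for (y, x) in f.pixels:
                assert nmap.labels[y, x] == f.nucleus_id

    def test_dc_offset_invariance(self, high_snr_scene):
        """Adding a constant to the raw image leaves detections unchanged:
        the DoG removes DC before the criteria are applied."""
        scene, _ = high_snr_scene
        raw = scene.channel("foci_A")
        nmap = fm.segment_nuclei(scene.channel("dapi"))
        params = FociParams()

        def detect(img):
            dog = fm.dog_subtract(img, params.dog_sigma_small, params.dog_sigma_large)
            stats = fm.estimate_background(dog, nmap)
            return fm.detect_foci(dog, nmap, stats, params)

        a, b = detect(raw), detect(raw + 500.0)
        assert [f.pixel_set() for f in a] == [f.pixel_set() for f in b]

    def test_monotonicity_in_parameters(self, analyzed_scene):
        _, _, nmap, dog, stats, _ = analyzed_scene

        def count(**kw):
            return len(fm.detect_foci(dog, nmap, stats, FociParams(**kw)))

        for seq in (
            [count(k=v) for v in (2.0, 3.0, 4.0, 6.0)],
            [count(abs_min=v) for v in (0.0, 500.0, 2000.0, 5000.0)],
            [count(min_area=v) for v in (1, 2, 5, 15)],
        ):
            assert seq == sorted(seq, reverse=True)

    def test_stats_mismatch_rejected(self, analyzed_scene):
        _, _, nmap, dog, _, _ = analyzed_scene
        bad = BackgroundStats(
            per_nucleus=pd.DataFrame([{"nucleus_id": 99, "level": 0.0,
                                       "sd": 1.0, "area": 10,
                                       "unreliable": False}]),
            median_sd=1.0, nucleus_ids=np.array([99]))
        with pytest.raises(ValueError, match="different nucleus map"):
            fm.detect_foci(dog, nmap, bad, FociParams())

    def test_deterministic_ordering(self, analyzed_scene):
        _, _, _, _, _, foci = analyzed_scene
        keys = [(f.nucleus_id, f.centroid_y, f.centroid_x) for f in foci]
        assert keys == sorted(keys)


class TestBruteforceOracle:
    def test_raster_size_guard(self):
        nmap, stats = single_nucleus_fixture(size=64)
        with pytest.raises(ValueError, match="128"):
            fm.detect_foci_bruteforce(np.zeros((200, 200)), nmap, stats,
                                      FociParams())

    def test_single_pixel_rejected_by_strict_area(self):
        nmap, stats = single_nucleus_fixture()
        dog = np.zeros(nmap.labels.shape)
        dog[30, 30] = 100.0
        params = FociParams(k=1.0, abs_min=0.0, min_area=1)
        assert fm.detect_foci_bruteforce(dog, nmap, stats, params) == []
        assert fm.detect_foci(dog, nmap, stats, params) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_equivalence_on_random_instances(self, connectivity):
        rng = np.random.default_rng(11 + connectivity)
        for _ in range(25):
            inst = random_instance(rng)
            if inst is None:
                continue
            dog, nmap, stats = inst
            params = FociParams(k=float(rng.uniform(1, 4)),
                                abs_min=float(rng.uniform(0, 3)),
                                min_area=int(rng.integers(1, 5)),
                                connectivity=connectivity)
            fast = fm.detect_foci(dog, nmap, stats, params)
            slow = fm.detect_foci_bruteforce(dog, nmap, stats, params)
            assert [f.pixel_set() for f in fast] == [f.pixel_set() for f in slow]
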