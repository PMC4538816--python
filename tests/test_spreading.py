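"""Spreading-from-locus metrics: locus localization, radial profiles, R50."""

import numpy as np
import pytest

import focimetry as fm
from focimetry.simulate import add_gaussian_spot
from focimetry.spreading import GAUSSIAN_R50_FACTOR


def circular_mask(size, radius, center=None):
    c = center or (size // 2, size // 2)
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius ** 2


class TestLocateLocus:
    def test_single_bright_pixel(self):
        from focimetry.segmentation import NucleusMap, _build_records
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[10:50, 10:50] = 1
        nmap = NucleusMap(labels=labels, records=_build_records(labels))
        marker = np.zeros((64, 64))
        marker[30, 25] = 1000.0
        loci = fm.locate_locus(marker, nmap)
        assert loci[1] == (25.0, 30.0)

    def test_symmetric_spot_centroid(self):
        from focimetry.segmentation import NucleusMap, _build_records
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[5:60, 5:60] = 1
        nmap = NucleusMap(labels=labels, records=_build_records(labels))
        marker = np.zeros((64, 64))
        add_gaussian_spot(marker, 31.3, 28.7, 1000.0, 1.5)
        (x, y) = fm.locate_locus(marker, nmap)[1]
        assert abs(x - 31.3) < 0.5 and abs(y - 28.7) < 0.5

    def test_flat_marker_skipped_not_error(self):
        from focimetry.segmentation import NucleusMap, _build_records
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[5:25, 5:25] = 1
        nmap = NucleusMap(labels=labels, records=_build_records(labels))
        assert fm.locate_locus(np.zeros((32, 32)), nmap) == {}

    def test_synthetic_scene_localization(self):
        """>= 95% of loci localized within 1 px of ground truth."""
        p = fm.SceneParams(shape=(512, 512), n_nuclei=12, seed=13)
        scene, gt = fm.simulate_locus_scene(p, spread_radius=4.0)
        nmap = fm.segment_nuclei(scene.channel("dapi"))
        loci = fm.locate_locus(scene.channel("locus"), nmap)
        hits = 0
        for k, (x, y) in loci.items():
            true_id = int(gt.labels[int(round(y)), int(round(x))])
            tx, ty = gt.locus_xy[true_id]
            hits += np.hypot(x - tx, y - ty) <= 1.0
        assert len(loci) >= 0.95 * len(gt.locus_xy)
        assert hits >= 0.95 * len(loci)


class TestRadialProfile:
    def test_uniform_channel_null_spread(self):
        mask = circular_mask(80, 30)
        prof = fm.radial_profile(np.full((80, 80), 500.0), (40.0, 40.0), mask)
        assert np.nanmax(np.abs(prof.profile)) < 1e-9
        assert prof.expansion_area == 0
        assert prof.r50 == 0.0

    @pytest.mark.parametrize("s", [3.0, 4.0])
    def test_r50_matches_analytic_gaussian_quantile(self, s):
        """Noiseless 2D Gaussian of SD s: R50 = sqrt(2 ln 2) * s ~ 1.1774 s,
        within half a bin width."""
        img = np.zeros((120, 120))
        add_gaussian_spot(img, 60.0, 60.0, 1000.0, s, truncate=10.0)
        mask = circular_mask(120, 45)
        bw = 1.0
        prof = fm.radial_profile(img, (60.0, 60.0), mask, bin_width=bw)
        assert abs(prof.r50 - GAUSSIAN_R50_FACTOR * s) <= 0.5 * bw

    def test_r50_scale_invariance(self):
        img = np.zeros((100, 100))
        add_gaussian_spot(img, 50.0, 50.0, 800.0, 4.0, truncate=10.0)
        img += 100.0
        mask = circular_mask(100, 40)
        a = fm.radial_profile(img, (50.0, 50.0), mask)
        b = fm.radial_profile(img * 7.5, (50.0, 50.0), mask)
        assert b.r50 == pytest.approx(a.r50, abs=1e-9)

    def test_expansion_area_monotone_in_k_spread(self):
        rng = np.random.default_rng(0)
        img = rng.normal(200, 20, (100, 100))
        add_gaussian_spot(img, 50.0, 50.0, 500.0, 5.0)
        mask = circular_mask(100, 40)
        areas = [fm.radial_profile(img, (50.0, 50.0), mask, k_spread=k).expansion_area
                 for k in (1.0, 2.0, 4.0, 8.0)]
        assert areas == sorted(areas, reverse=True)

    def test_centroid_outside_mask_rejected(self):
        mask = circular_mask(64, 20)
        with pytest.raises(ValueError, match="inside"):
            fm.radial_profile(np.zeros((64, 64)), (2.0, 2.0), mask)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:32, 30:32] = True
        with pytest.raises(ValueError, match="too small"):
            fm.radial_profile(np.zeros((64, 64)), (30.0, 30.0), mask)

    def test_wider_spread_gives_larger_r50(self):
        """Scenes differing only in spread radius (2 vs 6 px): measured R50
        strictly ordered."""
        r50s = {}
        for sr in (2.0, 6.0):
            p = fm.SceneParams(shape=(400, 400), n_nuclei=6, seed=17)
            scene, _ = fm.simulate_locus_scene(p, spread_radius=sr)
            nmap = fm.segment_nuclei(scene.channel("dapi"))
            profs = fm.profile_scene(scene.channel("factor"),
                                     scene.channel("locus"), nmap)
            r50s[sr] = np.mean([pr.r50 for pr in profs])
        assert r50s[6.0] > r50s[2.0]

    def test_generated_profile_half_radius_matches_numeric_integral(self):
        """Half-signal radius of a noiseless generated locus scene agrees
        with direct numeric integration of the planted Gaussian."""
        sr = 4.0
        p = fm.SceneParams(shape=(400, 400), n_nuclei=6, seed=19,
                           read_noise_sd=0.0, photon_scale=None,
                           foci_texture_sd=0.0, nucleus_texture_sd=0.0,
                           background_gradient=0.0)
        scene, gt = fm.simulate_locus_scene(p, spread_radius=sr)
        nmap = fm.segment_nuclei(scene.channel("dapi"))
        profs = fm.profile_scene(scene.channel("factor"),
                                 scene.channel("locus"), nmap)
        # oracle: cumulative of r*exp(-r^2/2s^2) reaches half at sqrt(2 ln 2)s
        r = np.linspace(0, 30, 20001)
        cdf = 1.0 - np.exp(-r ** 2 / (2 * sr ** 2))
        oracle = r[np.searchsorted(cdf, 0.5)]
        got = np.mean([pr.r50 for pr in profs])
        # the locus spot itself sits on top of the factor halo, biasing the
        # innermost bins slightly; allow one bin width
        assert abs(got - oracle) <= 1.0


class TestCompareSpreading:
    def _profiles(self, r50s):
        return [fm.SpreadingProfile(
            nucleus_id=i + 1, bin_centers=np.arange(3.0),
            profile=np.zeros(3), locus_x=0, locus_y=0, r50=v,
            expansion_area=int(10 * v), background_level=0.0,
            background_sd=1.0) for i, v in enumerate(r50s)]

    def test_identical_conditions_ratio_one(self):
        t = fm.compare_spreading(
            {"ctrl": self._profiles([3, 4, 5]),
             "kd": self._profiles([3, 4, 5])}, control="ctrl")
        kd = t[t.condition == "kd"].iloc[0]
        assert kd["r50_ratio_to_control"] == pytest.approx(1.0)

    def test_planted_double_spread(self):
        rng = np.random.default_rng(8)
        ctrl = self._profiles(rng.normal(4, 0.3, 40))
        kd = self._profiles(rng.normal(8, 0.6, 40))
        t = fm.compare_spreading({"ctrl": ctrl, "kd": kd}, control="ctrl")
        ratio = float(t.set_index("condition").loc["kd", "r50_ratio_to_control"])
        assert ratio == pytest.approx(2.0, abs=0.15)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            fm.compare_spreading({"a": self._profiles([1]),
                                  "b": self._profiles([2])}, control="zz")

    def test_single_nucleus_sem_flagged(self):
        t = fm.compare_spreading({"ctrl": self._profiles([3, 4]),
                                  "solo": self._profiles([5])}, control="ctrl")
        solo = t[t.condition == "solo"].iloc[0]
        assert bool(solo["sem_undefined"])
        assert np.isnan(solo["sem_r50"])
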