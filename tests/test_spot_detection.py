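"""Spot seeding, growth, and non-redundant registration within contours."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from shapely.geometry import Point

from fishstack.pipeline import analyze_stack, synthetic_analysis_configs
from fishstack.spot_detection import (
    SpotConfig,
    SpotRecord,
    SpotRegistry,
    detect_spots,
    find_spot_centers,
    grow_spot,
    preprocess_signal,
    rasterize_ownership,
    register_spot,
)
from fishstack.synthetic_fishgen import SimulationConfig, render_stack, sample_nuclei, place_spots, simulate
from tests.conftest import make_record, square_contour


class TestPreprocess:
    def test_zero_sigma_is_identity(self, rng):
        img = rng.random((12, 12))
        np.testing.assert_array_equal(preprocess_signal(img, SpotConfig(blur_sigma_px=0)), img)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 42.0)
        np.testing.assert_allclose(preprocess_signal(img, SpotConfig(blur_sigma_px=2)), img)

    def test_impulse_response_is_discrete_gaussian(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        sigma = 1.5
        out = preprocess_signal(img, SpotConfig(blur_sigma_px=sigma))
        # oracle: explicit truncated sampled-Gaussian kernel (4 sigma support)
        half = int(4 * sigma + 0.5)
        x = np.arange(-half, half + 1)
        k = np.exp(-(x**2) / (2 * sigma**2))
        k /= k.sum()
        kernel = np.outer(k, k)
        np.testing.assert_allclose(out[16 - half : 16 + half + 1, 16 - half : 16 + half + 1], kernel, atol=1e-12)

    def test_rgb_plane_is_split_to_channel_color(self, rng):
        rgb = rng.random((8, 8, 3))
        out = preprocess_signal(rgb, SpotConfig(blur_sigma_px=0), channel="FITC")
        np.testing.assert_array_equal(out, rgb[..., 1])


class TestFindSpotCenters:
    def test_blank_channel_has_no_candidates(self, square_registry):
        gray = np.zeros((40, 40))
        assert find_spot_centers(gray, square_registry, SpotConfig(spot_intensity_threshold=10)) == []

    def test_peaks_outside_all_contours_discarded(self, square_registry):
        gray = np.zeros((40, 40))
        gray[19:22, 19:22] = 100.0  # inside the 10..30 square nucleus
        gray[34:37, 34:37] = 100.0  # outside every contour
        cfg = SpotConfig(blur_sigma_px=0, spot_intensity_threshold=50, min_peak_prominence=10)
        candidates = find_spot_centers(gray, square_registry, cfg)
        owners = {nid for nid, _ in candidates}
        assert owners == {1}
        assert all(10 <= r <= 30 and 10 <= c <= 30 for _, (r, c) in candidates)

    def test_planted_spots_recovered_per_nucleus(self, square_registry):
        gray = np.zeros((40, 40))
        for center in [(15, 15), (25, 25)]:
            rr, cc = np.mgrid[0:40, 0:40]
            gray += 100 * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * 1.5**2))
        cfg = SpotConfig(blur_sigma_px=0, spot_intensity_threshold=50, min_peak_prominence=20)
        candidates = find_spot_centers(gray, square_registry, cfg)
        assert len(candidates) == 2


class TestGrowSpot:
    def _owner(self, shape, registry):
        return rasterize_ownership(registry, shape)

    def test_isolated_pixel_has_area_one(self, square_registry):
        gray = np.zeros((40, 40))
        gray[20, 20] = 100.0
        owner = self._owner((40, 40), square_registry)
        cfg = SpotConfig(blur_sigma_px=0, spot_intensity_threshold=50, max_spot_diameter_um=5)
        record = grow_spot((20, 20), gray, cfg, nucleus_id=1, owner=owner, threshold=50)
        assert record.area_px == 1
        assert record.member_pixels == frozenset({(20, 20)})

    def test_uniform_square_grows_fully(self, square_registry):
        gray = np.zeros((40, 40))
        gray[19:22, 19:22] = 100.0
        owner = self._owner((40, 40), square_registry)
        cfg = SpotConfig(blur_sigma_px=0, spot_intensity_threshold=50, max_spot_diameter_um=5)
        record = grow_spot((20, 20), gray, cfg, nucleus_id=1, owner=owner, threshold=50)
        assert record.area_px == 9

    def test_gaussian_spot_halfmax_area_near_analytic(self, square_registry):
        sigma = 3.0
        rr, cc = np.mgrid[0:40, 0:40]
        gray = 200.0 * np.exp(-((rr - 20.0) ** 2 + (cc - 20.0) ** 2) / (2 * sigma**2))
        owner = self._owner((40, 40), square_registry)
        cfg = SpotConfig(blur_sigma_px=0, spot_intensity_threshold=100, max_spot_diameter_um=10)
        record = grow_spot((20, 20), gray, cfg, nucleus_id=1, owner=owner, threshold=100.0)
        analytic = np.pi * (sigma * np.sqrt(2 * np.log(2))) ** 2
        assert abs(record.area_px - analytic) / analytic < 0.2


class TestRegisterSpot:
    def _draft(self, pixels, nucleus_id=1, channel="FITC"):
        pixels = frozenset(pixels)
        center = min(pixels)
        return SpotRecord(
            nucleus_id=nucleus_id,
            channel=channel,
            center=center,
            plane_index=0,
            area_px=len(pixels),
            peak_intensity=10.0,
            member_pixels=pixels,
        )

    def test_first_spot_accepted(self):
        registry = SpotRegistry()
        assert register_spot(registry, self._draft({(1, 1), (1, 2)}))
        assert len(registry) == 1

    def test_identical_draft_rejected(self):
        registry = SpotRegistry()
        register_spot(registry, self._draft({(1, 1)}))
        assert not register_spot(registry, self._draft({(1, 1)}))

    def test_single_shared_pixel_rejects_second(self):
        registry = SpotRegistry()
        register_spot(registry, self._draft({(1, 1), (1, 2)}))
        assert not register_spot(registry, self._draft({(1, 2), (1, 3)}))

    def test_other_channel_unaffected_by_overlap(self):
        registry = SpotRegistry()
        register_spot(registry, self._draft({(1, 1)}, channel="FITC"))
        assert register_spot(registry, self._draft({(1, 1)}, channel="TRITC"))


class TestDetectSpots:
    def test_no_registered_nuclei_gives_empty_registry(self, rng):
        from fishstack.nucleus_registry import NucleusRegistry
        from tests.conftest import random_stack

        stack = random_stack(rng, n_planes=2, shape=(32, 32))
        registry, counts = detect_spots(stack, NucleusRegistry(), SpotConfig())
        assert len(registry) == 0
        assert (counts.n_candidates == 0).all()

    def test_normal_sample_mean_spots_exactly_two(self):
        cfg = SimulationConfig(
            n_nuclei=20,
            field_size_px=(320, 320),
            overlap_fraction=0.0,
            genotype_mix={"normal": 1.0},
            noise_sigma=0.0,
            seed=8,
        )
        stack, truth = simulate(cfg)
        seg, spot, cls = synthetic_analysis_configs(noise_sigma=0.0)
        result = analyze_stack(stack, seg, spot, cls)
        assert len(result.registry) == 20
        assert result.summary["mean_spots_per_nucleus"]["FITC"] == 2.0
        assert result.summary["mean_spots_per_nucleus"]["TRITC"] == 2.0

    def test_spot_centers_inside_owning_contour(self):
        cfg = SimulationConfig(n_nuclei=15, field_size_px=(320, 320), overlap_fraction=0.0, seed=9)
        stack, _ = simulate(cfg)
        seg, spot, cls = synthetic_analysis_configs()
        result = analyze_stack(stack, seg, spot, cls)
        assert len(result.spots) > 0
        for record in result.spots.all_records():
            poly = result.registry.records[record.nucleus_id].polygon()
            assert poly.buffer(0.6).covers(Point(record.center))

    def test_member_pixel_sets_disjoint_per_nucleus_channel(self):
        cfg = SimulationConfig(n_nuclei=15, field_size_px=(320, 320), overlap_fraction=0.0, seed=10)
        stack, _ = simulate(cfg)
        seg, spot, cls = synthetic_analysis_configs()
        result = analyze_stack(stack, seg, spot, cls)
        for nid, chans in result.spots.spots.items():
            for ch, records in chans.items():
                seen = set()
                for record in records:
                    assert not (record.member_pixels & seen)
                    seen |= record.member_pixels

    def test_deterministic_registry(self):
        cfg = SimulationConfig(n_nuclei=10, field_size_px=(256, 256), overlap_fraction=0.0, seed=12)
        stack, _ = simulate(cfg)
        seg, spot, cls = synthetic_analysis_configs()
        first = analyze_stack(stack, seg, spot, cls)
        second = analyze_stack(stack, seg, spot, cls)
        assert first.spots.to_json() == second.spots.to_json()

    def test_identically_placed_channels_strongly_correlated(self):
        cfg = SimulationConfig(n_nuclei=25, field_size_px=(320, 320), overlap_fraction=0.0, seed=13)
        rng = np.random.default_rng(cfg.seed)
        nuclei = sample_nuclei(cfg, rng)
        spots = place_spots(nuclei, cfg, rng)
        # mirror every green spot into the red channel at the same position
        from dataclasses import replace

        mirrored = [s for s in spots if s.channel == "FITC"]
        mirrored = mirrored + [replace(s, channel="TRITC") for s in mirrored]
        stack, _ = render_stack(nuclei, mirrored, cfg, rng)
        seg, spot_cfg, cls = synthetic_analysis_configs()
        result = analyze_stack(stack, seg, spot_cfg, cls)
        table = result.per_plane_spot_counts
        fitc = table[table.channel == "FITC"].sort_values("plane").n_candidates.to_numpy()
        tritc = table[table.channel == "TRITC"].sort_values("plane").n_candidates.to_numpy()
        r = np.corrcoef(fitc, tritc)[0, 1]
        assert r > 0.9

    def test_per_plane_counts_peak_at_focal_plane(self):
        cfg = SimulationConfig(n_nuclei=40, field_size_px=(384, 384), overlap_fraction=0.0, seed=14)
        stack, _ = simulate(cfg)
        seg, spot_cfg, cls = synthetic_analysis_configs()
        result = analyze_stack(stack, seg, spot_cfg, cls)
        f = stack.focal_plane_index
        for ch in ("FITC", "TRITC"):
            t = result.per_plane_spot_counts
            counts = t[t.channel == ch].sort_values("plane").n_candidates.tolist()
            assert counts[f] == max(counts)
            down = counts[: f + 1][::-1]
            up = counts[f:]
            assert all(a >= b for a, b in zip(down, down[1:]))
            assert all(a >= b for a, b in zip(up, up[1:]))
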