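import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinefret import actinmap, synthcell


def exhaustive_rosin_oracle(counts):
    """Per-bin scan of perpendicular distance to the peak-tail chord."""
    counts = np.asarray(counts, dtype=float)
    peak = int(np.argmax(counts))
    last = int(np.nonzero(counts)[0][-1])
    x1, y1, x2, y2 = peak, counts[peak], last, counts[last]
    norm = np.hypot(x2 - x1, y2 - y1)
    best, best_d = None, -1.0
    for i in range(peak, last + 1):
        d = abs((y2 - y1) * (i - x1) - (x2 - x1) * (counts[i] - y1)) / norm
        if d > best_d:
            best, best_d = i, d
    return best


def random_unimodal_histogram(rng):
    nb = int(rng.integers(16, 257))
    peak = int(rng.integers(0, nb // 2))
    decay = rng.uniform(2, 40)
    x = np.arange(nb, dtype=float)
    counts = np.exp(-np.abs(x - peak) / decay) * rng.integers(100, 10000)
    counts += rng.uniform(0, 0.02) * counts.max() * rng.random(nb)
    return np.floor(counts)


class TestUnimodalThreshold:
    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(300):
            counts = random_unimodal_histogram(rng)
            assert actinmap.rosin_threshold_index(counts) == exhaustive_rosin_oracle(counts)

    def test_two_valued_image_threshold_separates(self):
        rng = np.random.default_rng(0)
        img = np.full(10000, 10.0)
        img[rng.choice(10000, 100, replace=False)] = 200.0
        t = actinmap.unimodal_threshold(img)
        assert 10.0 < t < 200.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            actinmap.unimodal_threshold(np.full((8, 8), 3.0))

    def test_close_to_triangle_method_cross_check(self):
        # skimage's triangle threshold implements the same corner criterion;
        # conventions differ slightly, so agreement is to a few bins
        from skimage.filters import threshold_triangle

        rng = np.random.default_rng(7)
        img = np.concatenate(
            [rng.normal(50, 5, 20000), rng.normal(180, 10, 600)]
        )
        mine = actinmap.unimodal_threshold(img, bins=256)
        theirs = threshold_triangle(img, nbins=256)
        assert abs(mine - theirs) < 10 * (img.max() - img.min()) / 256


class TestFractionMap:
    def test_direct_formula_values(self):
        f = np.array([[1.0, 3.0, 1.0]])
        g = np.array([[1.0, 1.0, 0.0]])
        fm = actinmap.fraction_map(f, g, foreground=np.ones_like(f, bool))
        np.testing.assert_allclose(fm.fr[0], [0.5, 0.75, 1.0])
        np.testing.assert_allclose(fm.r[0, :2], [1.0, 3.0])
        assert np.isnan(fm.r[0, 2])  # infinite ratio is masked, FR stays 1

    def test_fr_r_link_and_bounds(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 100, (50, 50))
        g = rng.uniform(0, 100, (50, 50))
        fm = actinmap.fraction_map(f, g, foreground=np.ones_like(f, bool))
        defined = np.isfinite(fm.fr)
        assert ((fm.fr[defined] >= 0) & (fm.fr[defined] <= 1)).all()
        both = defined & np.isfinite(fm.r)
        np.testing.assert_allclose(
            fm.fr[both], fm.r[both] / (1 + fm.r[both]), atol=1e-9
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_to_common_rescaling(self, scale):
        rng = np.random.default_rng(2)
        f = rng.uniform(1, 100, (20, 20))
        g = rng.uniform(1, 100, (20, 20))
        fg = np.ones_like(f, bool)
        a = actinmap.fraction_map(f, g, foreground=fg)
        b = actinmap.fraction_map(f * scale, g * scale, foreground=fg)
        np.testing.assert_allclose(a.fr, b.fr, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            actinmap.fraction_map(np.ones((3, 3)), np.ones((4, 4)))


class TestWholeCellSummary:
    def test_uniform_fraction(self):
        f = np.ones((10, 10))
        fm = actinmap.fraction_map(f, f, foreground=np.ones((10, 10), bool))
        out = actinmap.whole_cell_summary(fm, np.ones((10, 10), bool))
        assert out["mean_fr"] == pytest.approx(0.5)
        assert out["n_voxels"] == 100

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(1, 10, (12, 12))
        g = rng.uniform(1, 10, (12, 12))
        cell = rng.random((12, 12)) < 0.6
        cell[0, 0] = True
        fm = actinmap.fraction_map(f, g, foreground=np.ones((12, 12), bool))
        out = actinmap.whole_cell_summary(fm, cell)
        acc = [
            f[i, j] / (f[i, j] + g[i, j])
            for i in range(12)
            for j in range(12)
            if cell[i, j]
        ]
        assert out["mean_fr"] == pytest.approx(np.mean(acc), abs=1e-9)

    def test_enriched_cell_mean_matches_area_weighting(self, clean_actin_scene):
        spec, stack, truth = clean_actin_scene
        f = stack.voxels[0, 0, 0]
        g = stack.voxels[0, 0, 1]
        fm = actinmap.fraction_map(f, g, foreground=truth.cell_mask)
        out = actinmap.whole_cell_summary(fm, truth.cell_mask)
        band = np.isclose(truth.fr_map, 0.7)
        w = band.sum() / truth.cell_mask.sum()
        expected = 0.7 * w + 0.5 * (1 - w)
        assert 0.5 < out["mean_fr"] < 0.7
        assert out["mean_fr"] == pytest.approx(expected, rel=0.05)

    def test_empty_overlap_rejected(self):
        f = np.ones((4, 4))
        fm = actinmap.fraction_map(f, f, foreground=np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="overlap"):
            actinmap.whole_cell_summary(fm, np.zeros((4, 4), bool))


class TestContour:
    def test_disk_contour_length_near_circumference(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2
        c = actinmap.extract_contour(mask, pixel_size=0.1)
        length = np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))
        assert length == pytest.approx(2 * np.pi * 50 * 0.1, rel=0.02)

    def test_square_corners_recovered(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        c = actinmap.extract_contour(mask)
        for corner in [(10, 10), (10, 29), (29, 10), (29, 29)]:
            d = np.min(np.linalg.norm(c - np.array(corner), axis=1))
            assert d <= 1.0

    def test_counterclockwise_and_closed(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        c = actinmap.extract_contour(mask)
        assert np.array_equal(c[0], c[-1])
        assert actinmap._signed_area(c) > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            actinmap.extract_contour(np.zeros((8, 8), bool))


class TestMembraneProfiles:
    def test_uniform_image_flat_profile(self):
        yy, xx = np.mgrid[0:100, 0:100]
        mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 35**2
        c = actinmap.extract_contour(mask, pixel_size=0.1)
        prof = actinmap.membrane_profiles(
            np.full((100, 100), 7.0), c, 0.1, half_length_um=2.0
        )
        np.testing.assert_allclose(prof.mean, 7.0)

    def test_ring_peak_inside_near_contour(self, clean_actin_scene):
        spec, stack, truth = clean_actin_scene
        f = stack.voxels[0, 0, 0]
        c = actinmap.extract_contour(truth.cell_mask, spec.pixel_size_xy)
        prof = actinmap.membrane_profiles(
            f, c, spec.pixel_size_xy, half_length_um=3.0
        )
        peak_offset = prof.offsets_um[np.argmax(prof.mean)]
        # F-channel elevated in a 1-um band inside the contour
        assert 0.0 <= peak_offset <= truth.ring_width_um

    def test_outside_end_is_background(self, clean_actin_scene):
        spec, stack, truth = clean_actin_scene
        f = stack.voxels[0, 0, 0]
        c = actinmap.extract_contour(truth.cell_mask, spec.pixel_size_xy)
        prof = actinmap.membrane_profiles(
            f, c, spec.pixel_size_xy, half_length_um=3.0
        )
        assert prof.mean[0] == pytest.approx(spec.background_level, abs=1.0)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            actinmap.membrane_profiles(
                np.ones((8, 8)), np.array([[1.0, 1.0], [2.0, 2.0]]), 0.1
            )


class TestGamma:
    def test_identity_and_power_value(self):
        img = np.array([[0.25, 1.0, 0.0]])
        np.testing.assert_allclose(actinmap.gamma_adjust(img, 1.0), img)
        out = actinmap.gamma_adjust(img, 0.8)
        assert out[0, 0] == pytest.approx(0.25**0.8)  # ~0.3299

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(gamma=st.floats(min_value=0.05, max_value=5.0))
    def test_monotonicity_preserved(self, gamma):
        vals = np.linspace(0, 1, 64)
        out = actinmap.gamma_adjust(vals, gamma)
        assert (np.diff(out) >= 0).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            actinmap.gamma_adjust(np.zeros((2, 2)), 0.0)
        with pytest.raises(ValueError, match="normalised"):
            actinmap.gamma_adjust(np.full((2, 2), 2.0), 0.8)


class TestEnrichmentRecovery:
    def test_profile_recovers_programmed_enrichment_at_snr10(self):
        spec = synthcell.SceneSpec(
            "actin_dualstain",
            shape=(200, 200),
            background_level=20.0,
            poisson_scale=3.0,
            gaussian_sd=3.0,
            seed=31,
        )
        stack, truth = synthcell.make_actin_scene(
            spec, enrichment=0.4, ring_width_um=1.0
        )
        f = np.clip(stack.voxels[0, 0, 0] - spec.background_level, 0, None)
        g = np.clip(stack.voxels[0, 0, 1] - spec.background_level, 0, None)
        fm = actinmap.fraction_map(f, g, foreground=truth.cell_mask)
        c = actinmap.extract_contour(truth.cell_mask, spec.pixel_size_xy)
        prof = actinmap.membrane_profiles(
            fm.fr, c, spec.pixel_size_xy, half_length_um=3.0
        )
        inside = prof.offsets_um > 0
        peak = np.nanmax(prof.mean[inside])
        plateau = np.nanmean(prof.mean[prof.offsets_um > 2.0])
        assert 2 * (peak - plateau) == pytest.approx(0.4, rel=0.10)
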