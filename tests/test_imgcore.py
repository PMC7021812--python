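import numpy as np
import pytest
import tifffile

from spinefret import imgcore
from spinefret.imgcore import CalibratedStack


def make_stack(vox, **kw):
    kw.setdefault("pixel_size_xy", 0.07)
    kw.setdefault("channel_names", tuple(f"ch{i}" for i in range(vox.shape[2])))
    return CalibratedStack(np.asarray(vox, dtype=float), **kw)


class TestCalibratedStack:
    def test_validates_dimensions_and_calibration(self):
        with pytest.raises(ValueError, match="5D"):
            make_stack(np.zeros((2, 3, 4)))
        with pytest.raises(ValueError, match="pixel_size"):
            make_stack(np.zeros((1, 1, 1, 4, 4)), pixel_size_xy=0.0)
        with pytest.raises(ValueError, match="unique"):
            make_stack(np.zeros((1, 1, 2, 4, 4)), channel_names=("a", "a"))
        with pytest.raises(ValueError, match="treatment_frame"):
            make_stack(np.zeros((3, 1, 1, 4, 4)), treatment_frame=3)

    def test_times_relative_to_treatment(self):
        st = make_stack(np.zeros((5, 1, 1, 4, 4)), treatment_frame=3)
        # last baseline at -2.5 min, first post frame at +2.5 min; t=0 is
        # the treatment instant between them
        np.testing.assert_allclose(st.times_min(), [-7.5, -5.0, -2.5, 2.5, 5.0])
        assert (st.times_min()[:3] < 0).all()


class TestIO:
    def test_single_plane_promoted_to_singletons(self, tmp_path):
        p = tmp_path / "plane.tif"
        tifffile.imwrite(p, np.arange(12, dtype=np.uint16).reshape(3, 4))
        st = imgcore.read_stack(p, pixel_size_xy=0.07)
        assert st.voxels.shape == (1, 1, 1, 3, 4)

    def test_ome_round_trip_preserves_voxels_and_calibration(self, tmp_path):
        vox = np.random.default_rng(0).uniform(0, 100, (3, 2, 2, 8, 9))
        st = make_stack(vox, channel_names=("mTurquoise", "YPet"))
        p = tmp_path / "stack.ome.tif"
        imgcore.write_stack(st, p)
        rt = imgcore.read_stack(p)
        np.testing.assert_array_equal(rt.voxels, st.voxels)
        assert rt.pixel_size_xy == pytest.approx(0.07)
        assert rt.channel_names == ("mTurquoise", "YPet")

    def test_missing_pixel_size_is_an_error(self, tmp_path):
        p = tmp_path / "bare.tif"
        tifffile.imwrite(p, np.zeros((4, 4), dtype=np.uint16))
        with pytest.raises(ValueError, match="pixel size"):
            imgcore.read_stack(p)


class TestBackground:
    def test_mode_of_constant_plane(self):
        st = make_stack(np.full((1, 1, 1, 16, 16), 7.0))
        assert imgcore.estimate_background(st, 0)[0, 0] == pytest.approx(7.0)

    def test_mode_robust_to_sparse_bright_objects(self):
        rng = np.random.default_rng(3)
        plane = np.full((100, 100), 50.0) + rng.normal(0, 1.0, (100, 100))
        idx = rng.choice(10000, 400, replace=False)  # 4% bright pixels
        plane.ravel()[idx] += 500
        st = make_stack(plane[None, None, None])
        assert imgcore.estimate_background(st, 0)[0, 0] == pytest.approx(50, abs=2)

    def test_roi_method_is_roi_mean(self):
        plane = np.zeros((8, 8))
        plane[:4] = 10.0
        roi = np.zeros((8, 8), dtype=bool)
        roi[:4] = True
        st = make_stack(plane[None, None, None])
        lv = imgcore.estimate_background(st, 0, method="roi", roi=roi)
        assert lv[0, 0] == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "level,expected",
        [(100.0, 0.0), (0.0, 100.0)],
        ids=["full-subtraction", "identity"],
    )
    def test_subtract_background(self, level, expected):
        st = make_stack(np.full((1, 1, 1, 4, 4), 100.0))
        out = imgcore.subtract_background(st, level)
        np.testing.assert_allclose(out.voxels, expected)

    def test_negative_level_rejected(self):
        st = make_stack(np.zeros((1, 1, 1, 4, 4)))
        with pytest.raises(ValueError, match="non-negative"):
            imgcore.subtract_background(st, -1.0)

    def test_subtraction_clips_at_zero_and_is_idempotent_at_zero(self):
        st = make_stack(np.full((1, 1, 1, 4, 4), 5.0))
        out = imgcore.subtract_background(st, 10.0)
        assert (out.voxels == 0).all()
        again = imgcore.subtract_background(out, 0.0)
        np.testing.assert_array_equal(again.voxels, out.voxels)


class TestRegistration:
    @staticmethod
    def _scene(T=5, drift=(0, 0)):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 50, (64, 64))
        base[20:30, 40:50] += 300
        vox = np.empty((T, 1, 1, 64, 64))
        for t in range(T):
            vox[t, 0, 0] = np.roll(
                np.roll(base, drift[0] * t, axis=0), drift[1] * t, axis=1
            )
        return make_stack(vox)

    def test_identical_frames_give_zero_shifts(self):
        _, track = imgcore.register_translation(self._scene())
        np.testing.assert_allclose(track.shifts, 0.0)

    def test_integer_drift_recovered_exactly(self):
        # roll-based scene: drift (3, -2) px/frame must be undone exactly
        st = self._scene(T=4, drift=(3, -2))
        reg, track = imgcore.register_translation(st)
        for t in range(4):
            np.testing.assert_allclose(track.shifts[t], [-3 * t, 2 * t])

    def test_registered_stack_is_stable(self):
        st = self._scene(T=4, drift=(3, -2))
        reg, _ = imgcore.register_translation(st)
        _, track2 = imgcore.register_translation(reg)
        assert np.all(np.abs(track2.shifts) < 0.1)

    def test_featureless_frame_flagged_with_zero_shift(self):
        st = self._scene(T=3)
        st.voxels[2] = 42.0
        with pytest.warns(UserWarning, match="featureless"):
            _, track = imgcore.register_translation(st)
        assert track.featureless == (2,)
        np.testing.assert_allclose(track.shifts[2], 0.0)


class TestBlur:
    def test_sigma_zero_is_identity(self):
        vox = np.random.default_rng(1).uniform(0, 10, (1, 1, 1, 16, 16))
        st = make_stack(vox)
        np.testing.assert_array_equal(imgcore.gaussian_blur(st, 0.0).voxels, vox)

    def test_delta_intensity_conserved(self):
        vox = np.zeros((1, 1, 1, 33, 33))
        vox[0, 0, 0, 16, 16] = 1.0
        out = imgcore.gaussian_blur(make_stack(vox), 0.5)
        assert out.voxels.sum() == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_semigroup(self):
        # blurring twice at sigma composes like a single sqrt(2)-wider blur.
        # At sigma >= 1 px the sampled kernel is faithful and the identity
        # holds to ~1e-3; at the default half-pixel sigma discretisation
        # limits it, so only a loose bound applies on band-limited data.
        from scipy import ndimage as ndi

        vox = np.random.default_rng(2).uniform(0, 10, (1, 1, 1, 64, 64))
        st = make_stack(vox)
        twice = imgcore.gaussian_blur(imgcore.gaussian_blur(st, 1.0), 1.0)
        once = imgcore.gaussian_blur(st, np.sqrt(2.0))
        rms = np.sqrt(np.mean((twice.voxels - once.voxels) ** 2))
        assert rms < 1e-3 * vox.std()

        smooth = make_stack(ndi.gaussian_filter(vox, (0, 0, 0, 2, 2)))
        twice = imgcore.gaussian_blur(imgcore.gaussian_blur(smooth, 0.5), 0.5)
        once = imgcore.gaussian_blur(smooth, np.sqrt(0.5))
        rms = np.sqrt(np.mean((twice.voxels - once.voxels) ** 2))
        assert rms < 0.02 * smooth.voxels.std()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            imgcore.gaussian_blur(make_stack(np.zeros((1, 1, 1, 4, 4))), -0.1)


class TestPercentileScaling:
    def test_division_by_control_percentile(self):
        ctrl = make_stack(np.linspace(0, 200, 1000).reshape(1, 1, 1, 25, 40))
        st = make_stack(np.full((1, 1, 1, 4, 4), 100.0))
        out = imgcore.scale_to_percentile(st, ctrl, 100.0)
        np.testing.assert_allclose(out.voxels, 0.5)

    def test_self_scaling_puts_percentile_at_one(self):
        vox = np.random.default_rng(4).uniform(0, 500, (1, 1, 1, 100, 100))
        st = make_stack(vox)
        out = imgcore.scale_to_percentile(st, st, 99.9)
        assert np.percentile(out.voxels, 99.9) == pytest.approx(1.0)

    def test_percentile_matches_sorting_oracle(self):
        vals = np.random.default_rng(5).uniform(0, 1000, 10**5)
        st = make_stack(vals.reshape(1, 1, 1, 250, 400))
        out = imgcore.scale_to_percentile(st, st, 99.9)
        srt = np.sort(vals)
        # linear-interpolation quantile, as numpy defines it
        pos = 0.999 * (vals.size - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        oracle = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
        np.testing.assert_allclose(out.voxels.ravel(), vals / oracle)

    def test_scale_equivariance(self):
        vox = np.random.default_rng(6).uniform(0, 100, (1, 1, 1, 30, 30))
        st = make_stack(vox)
        scaled_in = make_stack(vox * 7.3)
        a = imgcore.scale_to_percentile(st, st, 99.9)
        b = imgcore.scale_to_percentile(scaled_in, scaled_in, 99.9)
        np.testing.assert_allclose(a.voxels, b.voxels)

    def test_zero_control_percentile_rejected(self):
        st = make_stack(np.zeros((1, 1, 1, 4, 4)))
        with pytest.raises(ValueError, match="percentile"):
            imgcore.scale_to_percentile(st, st, 99.9)


class TestZProjection:
    def test_z1_identity_and_pairwise_max(self):
        vox = np.zeros((1, 2, 1, 1, 1))
        vox[0, 0, 0] = 3.0
        vox[0, 1, 0] = 5.0
        out = imgcore.zmax_project(make_stack(vox))
        assert out.voxels.shape == (1, 1, 1, 1, 1)
        assert out.voxels[0, 0, 0, 0, 0] == 5.0

    def test_matches_plane_loop_oracle(self):
        vox = np.random.default_rng(7).uniform(0, 9, (2, 4, 2, 6, 5))
        st = make_stack(vox, channel_names=("a", "b"))
        out = imgcore.zmax_project(st).voxels
        for t in range(2):
            for c in range(2):
                expected = vox[t, 0, c]
                for z in range(1, 4):
                    expected = np.maximum(expected, vox[t, z, c])
                np.testing.assert_array_equal(out[t, 0, c], expected)

    def test_calibration_preserved_through_chain(self):
        vox = np.random.default_rng(8).uniform(1, 9, (2, 2, 1, 8, 8))
        st = make_stack(vox, treatment_frame=1)
        out = imgcore.zmax_project(
            imgcore.gaussian_blur(imgcore.subtract_background(st, 0.5), 0.5)
        )
        assert out.pixel_size_xy == st.pixel_size_xy
        assert out.channel_names == st.channel_names
        assert out.treatment_frame == st.treatment_frame
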