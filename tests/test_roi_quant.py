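"""ROI statistics, mirroring, ROI copying and decay correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mibiquant as mq
from mibiquant.roi_quant import _round_half_away


def _image(counts, t=10.0):
    return mq.PlanarImage(counts=np.asarray(counts), t_acq_min=t, frame_duration_s=600.0)


def _roi(pixels, grid, label=mq.RoiLabel.NODULE):
    return mq.RoiMask(pixels=frozenset(pixels), label=label, source_grid=grid)


class TestRoiMeanCounts:
    def test_uniform_image(self):
        img = _image(np.full((8, 8), 7))
        roi = _roi({(r, 0) for r in range(8)} | {(0, c) for c in range(1, 3)}, (8, 8))
        stats = mq.roi_mean_counts(img, roi)
        assert stats.n_pixels == 10
        assert stats.total_counts == 70
        assert stats.mean_counts_per_pixel == 7.0
        assert stats.t_acq_min == 10.0

    def test_zero_image(self):
        img = _image(np.zeros((4, 4), dtype=int))
        stats = mq.roi_mean_counts(img, _roi({(1, 1), (2, 2)}, (4, 4)))
        assert stats.mean_counts_per_pixel == 0.0

    def test_phantom_nodule_mean_equals_analytic_region_intensity(
        self, noiseless_phantom
    ):
        ph = noiseless_phantom
        stats = mq.roi_mean_counts(
            ph.study.early, ph.study.rois[mq.RoiLabel.NODULE]
        )
        expected = ph.kinetics.a0_nodule * ph.study.early.frame_duration_s
        assert stats.mean_counts_per_pixel == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch_is_an_error(self):
        img = _image(np.ones((4, 4)))
        with pytest.raises(ValueError, match="grid"):
            mq.roi_mean_counts(img, _roi({(0, 0)}, (8, 8)))

    def test_agrees_with_per_pixel_loop_oracle(self, rng):
        # >= 1000 random image/ROI pairs against an explicit loop
        for _ in range(1000):
            shape = (int(rng.integers(2, 12)), int(rng.integers(2, 12)))
            counts = rng.integers(0, 500, size=shape)
            n = int(rng.integers(1, shape[0] * shape[1] + 1))
            flat = rng.choice(shape[0] * shape[1], size=n, replace=False)
            pixels = {(int(i // shape[1]), int(i % shape[1])) for i in flat}
            stats = mq.roi_mean_counts(_image(counts), _roi(pixels, shape))
            total = 0
            for r, c in pixels:
                total += int(counts[r, c])
            assert stats.total_counts == total
            assert stats.mean_counts_per_pixel == pytest.approx(total / len(pixels))
            assert stats.mean_counts_per_pixel * stats.n_pixels == pytest.approx(
                stats.total_counts
            )


class TestMirrorRoi:
    def test_single_pixel_reflection_arithmetic(self):
        roi = _roi({(5, 10)}, (128, 256))
        out = mq.mirror_roi(roi, 64.0, mq.RoiLabel.MIRROR_BACKGROUND)
        assert out.pixels == {(5, 118)}
        assert out.label is mq.RoiLabel.MIRROR_BACKGROUND

    def test_symmetric_mask_is_a_fixed_point(self):
        pixels = {(3, 4), (3, 6), (7, 5)}  # symmetric about col 5
        roi = _roi(pixels, (10, 10))
        out = mq.mirror_roi(roi, 5.0, mq.RoiLabel.NODULE)
        assert out.pixels == pixels
        assert out.warnings == ("mirror_overlaps_source",)

    def test_out_of_grid_reflection_is_an_error(self):
        roi = _roi({(0, 1)}, (4, 4))
        with pytest.raises(ValueError, match="outside"):
            mq.mirror_roi(roi, 3.0, mq.RoiLabel.MIRROR_BACKGROUND)

    def test_disjoint_reflection_carries_no_warning(self):
        roi = _roi({(0, 0), (1, 1)}, (4, 8))
        out = mq.mirror_roi(roi, 3.0, mq.RoiLabel.MIRROR_BACKGROUND)
        assert out.warnings == ()

    @settings(max_examples=200, derandomize=True)
    @given(
        cols=st.integers(8, 64),
        half_axis=st.integers(4, 100),
        data=st.data(),
    )
    def test_involution_property(self, cols, half_axis, data):
        """mirror(mirror(roi)) == roi for any half-integer axis, when in bounds."""
        axis = half_axis / 2.0
        pixels = data.draw(
            st.sets(
                st.tuples(st.integers(0, 7), st.integers(0, cols - 1)),
                min_size=1,
                max_size=10,
            )
        )
        roi = _roi(pixels, (8, cols))
        try:
            once = mq.mirror_roi(roi, axis, mq.RoiLabel.CONTRALATERAL)
            twice = mq.mirror_roi(once, axis, mq.RoiLabel.NODULE)
        except ValueError:
            return  # reflection left the grid; precondition unmet
        assert twice.pixels == roi.pixels

    def test_phantom_mirror_lands_inside_contralateral_lobe(self, noiseless_phantom):
        geom = noiseless_phantom.geometry
        masks = geom.validate()
        contra = noiseless_phantom.study.rois[mq.RoiLabel.CONTRALATERAL]
        lobe = masks["right_lobe"]
        assert all(lobe[r, c] for r, c in contra.pixels)


class TestCopyRoiToLate:
    def test_identical_grids_copy_verbatim(self):
        roi = _roi({(1, 2), (3, 4)}, (8, 8))
        out = mq.copy_roi_to_late(roi, (8, 8), (8, 8))
        assert out.pixels == roi.pixels

    def test_declared_unit_scale_is_identity(self):
        roi = _roi({(0, 0)}, (256, 256))
        out = mq.copy_roi_to_late(roi, (256, 256), (256, 256), scale=1)
        assert out.pixels == roi.pixels

    def test_half_scale_collapses_block(self):
        roi = _roi({(10, 10), (10, 11), (11, 10), (11, 11)}, (256, 256))
        out = mq.copy_roi_to_late(roi, (256, 256), (128, 128), scale=0.5)
        assert out.pixels == {(5, 5)}
        assert out.source_grid == (128, 128)

    def test_undeclared_grid_mismatch_is_an_error(self):
        roi = _roi({(0, 0)}, (256, 256))
        with pytest.raises(ValueError, match="scale"):
            mq.copy_roi_to_late(roi, (256, 256), (128, 128))

    def test_inconsistent_scale_is_an_error(self):
        roi = _roi({(0, 0)}, (256, 256))
        with pytest.raises(ValueError, match="inconsistent"):
            mq.copy_roi_to_late(roi, (256, 256), (128, 128), scale=0.25)


class TestDecayCorrect:
    def _stats(self, mean, n, t):
        return mq.RoiStats(
            mean_counts_per_pixel=mean,
            n_pixels=n,
            total_counts=mean * n,
            t_acq_min=t,
            label=mq.RoiLabel.NODULE,
        )

    def test_reference_time_is_identity(self):
        spec = mq.DecaySpec(enabled=True, reference_time_min=10.0)
        out = mq.decay_correct(self._stats(50.0, 4, 10.0), spec)
        assert out.mean_counts_per_pixel == 50.0

    def test_one_half_life_doubles(self):
        spec = mq.DecaySpec(enabled=True, half_life_min=360.4)
        out = mq.decay_correct(self._stats(50.0, 4, 360.4), spec)
        assert out.mean_counts_per_pixel == pytest.approx(100.0)
        assert out.total_counts == pytest.approx(400.0)

    def test_closed_form_value(self):
        # 100 counts at t=60, reference t=10, T_half 360.4 -> x 2^(50/360.4)
        spec = mq.DecaySpec(enabled=True, reference_time_min=10.0)
        out = mq.decay_correct(self._stats(100.0, 10, 60.0), spec)
        assert out.mean_counts_per_pixel == pytest.approx(110.0939155540424, rel=1e-12)

    def test_preserves_pixel_count_and_mean_total_identity(self, rng):
        for _ in range(200):
            mean = float(rng.uniform(0, 500))
            n = int(rng.integers(1, 1000))
            t = float(rng.uniform(0, 120))
            spec = mq.DecaySpec(
                enabled=True,
                half_life_min=float(rng.uniform(10, 600)),
                reference_time_min=float(rng.uniform(0, 60)),
            )
            out = mq.decay_correct(self._stats(mean, n, t), spec)
            assert out.n_pixels == n
            assert out.mean_counts_per_pixel * n == pytest.approx(
                out.total_counts, rel=1e-12
            )

    def test_disabled_spec_is_rejected(self):
        with pytest.raises(ValueError, match="enabled"):
            mq.decay_correct(self._stats(1.0, 1, 0.0), mq.DecaySpec())


def test_round_half_away_from_zero():
    assert _round_half_away(2.5) == 3
    assert _round_half_away(-2.5) == -3
    assert _round_half_away(2.4) == 2
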