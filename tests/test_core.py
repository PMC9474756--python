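"""Frame-schedule arithmetic, frame combination, SUV and dynamic I/O."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tbmoco as tb
from tbmoco.core import FrameSchedule, SubjectMeta, VoxelGrid, sidecar_path
from tbmoco.errors import (
    FormatError,
    InvalidArgumentError,
    NoReferenceFrameError,
)

CLINICAL_66 = [(5, 24), (10, 6), (30, 6), (60, 6), (120, 24)]
FINE_90 = [(5, 24), (10, 6), (30, 6), (60, 54)]


class TestBuildSchedule:
    @pytest.mark.parametrize(
        "segments,n,total",
        [
            (CLINICAL_66, 66, 3600.0),
            (FINE_90, 90, 3600.0),
            ([(60, 1)], 1, 60.0),
        ],
    )
    def test_counts_and_duration(self, segments, n, total):
        s = tb.build_schedule(segments)
        assert len(s) == n
        assert s.total_duration == total
        assert s.frames[0][0] == 0.0

    def test_contiguity(self):
        s = tb.build_schedule(CLINICAL_66)
        assert np.allclose(s.starts[1:], s.ends[:-1])

    @pytest.mark.parametrize("bad", [[(0, 5)], [(-5, 3)], [(5, 0)], [(5, 1.5)]])
    def test_invalid_segments(self, bad):
        with pytest.raises(InvalidArgumentError):
            tb.build_schedule(bad)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.5, max_value=300.0),
                st.integers(min_value=1, max_value=30),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_total_duration_is_sum_of_segments(self, segments):
        s = tb.build_schedule(segments)
        assert len(s) == sum(c for _, c in segments)
        assert np.isclose(s.total_duration, sum(d * c for d, c in segments))


class TestReferenceFrame:
    def test_90_frame_cut_600_gives_40(self):
        s = tb.build_schedule(FINE_90)
        assert tb.reference_frame_index(s, 600.0) == 40

    def test_66_frame_cut_600_gives_40(self):
        # brute-force oracle over cumulative end times
        s = tb.build_schedule(CLINICAL_66)
        expect = max(k + 1 for k, e in enumerate(s.ends) if e <= 600.0)
        assert expect == 40
        assert tb.reference_frame_index(s, 600.0) == expect

    def test_cut_zero_raises(self):
        s = tb.build_schedule(CLINICAL_66)
        with pytest.raises(NoReferenceFrameError):
            tb.reference_frame_index(s, 0.0)


class TestRebinRegroup:
    def test_rebin_66_to_90(self):
        s66 = tb.build_schedule(CLINICAL_66)
        s90 = tb.rebin_fine(s66, 60.0, 600.0)
        assert len(s90) == 90
        assert s90.total_duration == 3600.0
        n_fine = sum(1 for a, b in s90.frames if a >= 600.0)
        assert n_fine == 50  # fifty 1-min frames over 10-60 min
        assert s90.frames == tb.build_schedule(FINE_90).frames

    def test_rebin_noop_at_total_duration(self):
        s66 = tb.build_schedule(CLINICAL_66)
        assert tb.rebin_fine(s66, 60.0, 3600.0).frames == s66.frames

    def test_rebin_bad_boundary(self):
        s66 = tb.build_schedule(CLINICAL_66)
        with pytest.raises(InvalidArgumentError):
            tb.rebin_fine(s66, 60.0, 601.0)

    def _random_dynamic(self, schedule, shape=(4, 4, 3), seed=0):
        rng = np.random.default_rng(seed)
        grid = VoxelGrid.centered(shape, (4.0, 4.0, 4.0))
        data = rng.random((len(schedule),) + shape)
        return tb.DynamicImage(data, grid, schedule)

    def test_regroup_90_to_66(self):
        s66 = tb.build_schedule(CLINICAL_66)
        s90 = tb.rebin_fine(s66)
        dyn = self._random_dynamic(s90)
        back = tb.regroup(dyn, s66)
        assert back.schedule.frames == s66.frames
        assert back.n_frames == 66
        # early frames (identical schedules) are unchanged
        assert np.allclose(back.data[:40], dyn.data[:40])

    def test_regroup_equal_duration_mean(self):
        s_fine = tb.build_schedule([(60, 2)])
        s_coarse = tb.build_schedule([(120, 1)])
        grid = VoxelGrid.centered((2, 2, 2), (1, 1, 1))
        data = np.stack([np.full((2, 2, 2), 10.0), np.full((2, 2, 2), 20.0)])
        out = tb.regroup(tb.DynamicImage(data, grid, s_fine), s_coarse)
        assert np.allclose(out.data[0], 15.0)

    def test_regroup_conserves_activity_time(self):
        s66 = tb.build_schedule(CLINICAL_66)
        s90 = tb.rebin_fine(s66)
        dyn = self._random_dynamic(s90, seed=3)
        back = tb.regroup(dyn, s66)
        tot_fine = np.tensordot(s90.durations, dyn.data, axes=(0, 0))
        tot_coarse = np.tensordot(s66.durations, back.data, axes=(0, 0))
        assert np.allclose(tot_fine, tot_coarse, rtol=1e-10)

    def test_regroup_non_nesting_raises(self):
        s_fine = tb.build_schedule([(60, 4)])
        s_bad = tb.build_schedule([(90, 2)])  # 90 s is not a union of 60 s frames
        dyn = self._random_dynamic(s_fine)
        with pytest.raises(InvalidArgumentError):
            tb.regroup(dyn, s_bad)


class TestCombineFrames:
    def test_equal_duration_mean(self):
        s = tb.build_schedule([(60, 10)])
        grid = VoxelGrid.centered((2, 2, 2), (1, 1, 1))
        data = np.stack([np.full((2, 2, 2), float(v)) for v in range(1, 11)])
        out = tb.combine_frames(tb.DynamicImage(data, grid, s), 0.0, 600.0)
        assert np.allclose(out, 5.5)

    def test_single_frame_identity(self):
        s = tb.build_schedule([(60, 3)])
        grid = VoxelGrid.centered((3, 3, 3), (1, 1, 1))
        rng = np.random.default_rng(0)
        data = rng.random((3, 3, 3, 3))
        dyn = tb.DynamicImage(data, grid, s)
        assert np.allclose(tb.combine_frames(dyn, 60.0, 120.0), data[1])

    def test_mixed_durations_vs_direct_sum(self):
        s = tb.build_schedule([(30, 2), (60, 2)])
        grid = VoxelGrid.centered((3, 3, 3), (1, 1, 1))
        rng = np.random.default_rng(1)
        data = rng.random((4, 3, 3, 3))
        dyn = tb.DynamicImage(data, grid, s)
        out = tb.combine_frames(dyn, 0.0, 180.0)
        w = np.array([30.0, 30.0, 60.0, 60.0])
        oracle = np.einsum("f,fxyz->xyz", w, data) / w.sum()
        assert np.allclose(out, oracle, atol=1e-12)

    def test_unaligned_window_raises(self):
        s = tb.build_schedule([(60, 3)])
        grid = VoxelGrid.centered((2, 2, 2), (1, 1, 1))
        dyn = tb.DynamicImage(np.zeros((3, 2, 2, 2)), grid, s)
        with pytest.raises(InvalidArgumentError):
            tb.combine_frames(dyn, 30.0, 120.0)


class TestSuv:
    def test_definition(self):
        meta = SubjectMeta(2.2e8, 60000.0, "001")  # 220 MBq, 60 kg
        conc = np.full((3, 3, 3), 2.2e8 / 60000.0)
        assert np.allclose(tb.suv(conc, meta), 1.0)

    def test_subject_001_value(self):
        # 60 kg / 220 MBq subject with 3666.67 Bq/ml -> SUV ~ 1.000
        meta = SubjectMeta(220e6, 60e3)
        assert tb.suv(np.array([3666.67]), meta)[0] == pytest.approx(1.000, abs=1e-3)

    def test_zero_image(self):
        meta = SubjectMeta(1e8, 7e4)
        assert np.all(tb.suv(np.zeros((2, 2, 2)), meta) == 0.0)

    @given(
        st.floats(min_value=1e6, max_value=1e9),
        st.floats(min_value=1e4, max_value=2e5),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_linear_in_concentration_inverse_in_dose(self, dose, weight, a):
        meta = SubjectMeta(dose, weight)
        img = np.array([100.0, 3000.0])
        assert np.allclose(tb.suv(a * img, meta), a * tb.suv(img, meta))
        meta2 = SubjectMeta(a * dose, weight)
        assert np.allclose(tb.suv(img, meta2), tb.suv(img, meta) / a)

    @pytest.mark.parametrize("dose,weight", [(0, 1e4), (1e8, -2.0)])
    def test_invalid_meta(self, dose, weight):
        with pytest.raises(InvalidArgumentError):
            SubjectMeta(dose, weight)


class TestDynamicIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        s = tb.build_schedule([(30, 4)])
        grid = VoxelGrid(
            shape=(6, 5, 7), spacing=(3.125, 3.125, 2.866), origin=(-10.0, 4.0, 2.0)
        )
        dyn = tb.DynamicImage(rng.random((4, 6, 5, 7)).astype(np.float32), grid, s)
        path = tmp_path / "dyn.nii.gz"
        tb.write_dynamic(dyn, path)
        back = tb.read_dynamic(path)
        assert back.schedule.frames == s.frames
        assert back.grid.shape == grid.shape
        assert np.allclose(back.grid.spacing, grid.spacing, atol=1e-5)
        assert np.max(np.abs(back.data - dyn.data)) <= 1e-6 * float(dyn.data.max())

    def test_sidecar_frame_count_mismatch(self, tmp_path):
        s = tb.build_schedule([(30, 4)])
        grid = VoxelGrid.centered((4, 4, 4), (2, 2, 2))
        dyn = tb.DynamicImage(np.zeros((4, 4, 4, 4)), grid, s)
        path = tmp_path / "dyn.nii.gz"
        tb.write_dynamic(dyn, path)
        sidecar_path(path).write_text(json.dumps([[0, 30], [30, 60], [60, 90]]))
        with pytest.raises(FormatError):
            tb.read_dynamic(path)

    def test_3d_image_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.float32), np.eye(4)),
            str(tmp_path / "vol.nii.gz"),
        )
        with pytest.raises(FormatError):
            tb.read_dynamic(tmp_path / "vol.nii.gz")

    def test_schedule_tsv_round_trip(self, tmp_path):
        s = tb.build_schedule(CLINICAL_66)
        s.to_tsv(tmp_path / "frames.tsv")
        assert FrameSchedule.from_tsv(tmp_path / "frames.tsv").frames == s.frames


class TestVoxelGrid:
    def test_world_round_trip(self):
        g = VoxelGrid(shape=(5, 6, 7), spacing=(2.0, 3.0, 1.5), origin=(1.0, -2.0, 0.5))
        idx = np.array([[0, 0, 0], [4, 5, 6], [1.5, 2.25, 3.0]])
        assert np.allclose(g.world_to_voxel(g.voxel_to_world(idx)), idx)

    def test_rejects_bad_spacing_and_direction(self):
        with pytest.raises(InvalidArgumentError):
            VoxelGrid(shape=(4, 4, 4), spacing=(1.0, 0.0, 1.0))
        with pytest.raises(InvalidArgumentError):
            VoxelGrid(
                shape=(4, 4, 4),
                spacing=(1.0, 1.0, 1.0),
                direction=((1, 0, 0), (0, 1, 0), (0, 0, -1)),  # det -1
            )
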