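import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroseg.errors import ShapeMismatchError
from coroseg.metrics import dice
from coroseg.multiview import (
    ProbVolume,
    ThresholdSet,
    calibrate_thresholds,
    fuse_labels,
    integrate_views,
    predict_volume_singleview,
)
from coroseg.volume_io import IntensityVolume, LabelVolume


class EchoModel:
    """Identity 'model': each output channel echoes the input slice."""

    def predict_batch(self, images):
        return np.repeat(images[:, None], 3, axis=1)


def _prob(rng, shape=(8, 8, 8)):
    return ProbVolume(
        aorta=rng.random(shape), coronary=rng.random(shape), background=rng.random(shape)
    )


class TestSingleView:
    @pytest.mark.parametrize("axis", ["axial", "sagittal", "coronal"])
    def test_echo_round_trip_preserves_layout(self, axis, rng):
        vol = IntensityVolume(rng.random((6, 7, 8), dtype=np.float32))
        pv = predict_volume_singleview(EchoModel(), vol, axis)
        for grid in (pv.background, pv.aorta, pv.coronary):
            np.testing.assert_allclose(grid, vol.data, atol=1e-7)
            assert grid.shape == vol.shape

    def test_axial_and_sagittal_echo_agree(self, rng):
        vol = IntensityVolume(rng.random((8, 8, 8), dtype=np.float32))
        a = predict_volume_singleview(EchoModel(), vol, "axial")
        s = predict_volume_singleview(EchoModel(), vol, "sagittal")
        np.testing.assert_allclose(a.aorta, s.aorta, atol=1e-7)

    def test_invalid_axis_rejected(self, rng):
        with pytest.raises(ValueError, match="axis"):
            predict_volume_singleview(EchoModel(), IntensityVolume(np.zeros((4, 4, 4))), "oblique")


class TestIntegrateViews:
    def test_mean_of_identical_volumes_is_identity(self, rng):
        p = _prob(rng)
        out = integrate_views(p, p, p)
        np.testing.assert_allclose(out.aorta, p.aorta)

    def test_simple_arithmetic(self):
        mk = lambda v: ProbVolume(aorta=np.full((2, 2, 2), v), coronary=np.full((2, 2, 2), v))
        out = integrate_views(mk(0.3), mk(0.6), mk(0.9))
        np.testing.assert_allclose(out.aorta, 0.6)

    def test_matches_explicit_three_term_loop(self, rng):
        ps = [_prob(rng, (4, 5, 3)) for _ in range(3)]
        out = integrate_views(*ps)
        for idx in np.ndindex(4, 5, 3):
            expected = (ps[0].coronary[idx] + ps[1].coronary[idx] + ps[2].coronary[idx]) / 3.0
            assert out.coronary[idx] == pytest.approx(expected)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_by_voxelwise_min_max(self, seed):
        r = np.random.default_rng(seed)
        ps = [
            ProbVolume(aorta=r.random((4, 4, 4)), coronary=r.random((4, 4, 4)))
            for _ in range(3)
        ]
        out = integrate_views(*ps)
        stack = np.stack([p.aorta for p in ps])
        assert (out.aorta >= stack.min(axis=0) - 1e-12).all()
        assert (out.aorta <= stack.max(axis=0) + 1e-12).all()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeMismatchError):
            integrate_views(_prob(rng, (4, 4, 4)), _prob(rng, (4, 4, 4)), _prob(rng, (5, 4, 4)))


class TestCalibrateThresholds:
    def test_binary_map_returns_grid_minimum(self):
        truth = np.zeros((6, 6, 6), dtype=np.uint8)
        truth[2:4, 2:4, 2:4] = 1
        truth[0, 0, 0] = 2
        pv = ProbVolume(
            aorta=(truth == 1).astype(float), coronary=(truth == 2).astype(float)
        )
        th = calibrate_thresholds([pv], [LabelVolume(truth)])
        assert th.t_aorta == pytest.approx(0.01)
        assert th.t_coronary == pytest.approx(0.01)

    def test_constructed_interval_returns_smallest_optimal(self):
        truth = np.zeros((6, 6, 6), dtype=np.uint8)
        truth[1:5, 1:5, 1:5] = 1
        truth[0, 5, 5] = 2
        aorta_p = np.where(truth == 1, 0.4, 0.2)
        coronary_p = np.where(truth == 2, 0.4, 0.2)
        pv = ProbVolume(aorta=aorta_p, coronary=coronary_p)
        th = calibrate_thresholds([pv], [LabelVolume(truth)])
        # any threshold in (0.2, 0.4] is optimal; the grid starts at 0.21
        assert th.t_aorta == pytest.approx(0.21)
        assert th.t_coronary == pytest.approx(0.21)

    def test_matches_exhaustive_double_loop_oracle(self, rng):
        grid = [round(0.05 * k, 2) for k in range(1, 20)]
        preds, truths = [], []
        for _ in range(3):
            t = (rng.random((5, 5, 5)) < 0.3).astype(np.uint8)
            t[rng.random((5, 5, 5)) < 0.1] = 2
            preds.append(ProbVolume(aorta=rng.random((5, 5, 5)), coronary=rng.random((5, 5, 5))))
            truths.append(LabelVolume(t))
        th = calibrate_thresholds(preds, truths, grid=grid)
        for key, cls, got in (("aorta", 1, th.t_aorta), ("coronary", 2, th.t_coronary)):
            best_t, best_s = None, -1.0
            for t in grid:
                scores = []
                for p, lv in zip(preds, truths):
                    scores.append(dice(getattr(p, key) >= t, lv.data == cls))
                s = sum(scores) / len(scores)
                if s > best_s:
                    best_t, best_s = t, s
            assert got == pytest.approx(best_t)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([], [])


class TestFuseLabels:
    def test_three_rule_cases_exhaustively(self):
        th = ThresholdSet(t_aorta=0.30, t_coronary=0.15)
        # voxel 0: only aorta above; voxel 1: both above, coronary larger;
        # voxel 2: neither above.
        pv = ProbVolume(
            aorta=np.array([[[0.5, 0.4, 0.1]]]),
            coronary=np.array([[[0.10, 0.6, 0.1]]]),
        )
        out = fuse_labels(pv, th)
        np.testing.assert_array_equal(out.data[0, 0], [1, 2, 0])

    def test_exact_tie_goes_to_aorta(self):
        pv = ProbVolume(aorta=np.full((1, 1, 1), 0.5), coronary=np.full((1, 1, 1), 0.5))
        out = fuse_labels(pv, ThresholdSet(0.3, 0.15))
        assert out.data[0, 0, 0] == 1

    def test_only_coronary_above(self):
        pv = ProbVolume(aorta=np.full((1, 1, 1), 0.1), coronary=np.full((1, 1, 1), 0.2))
        assert fuse_labels(pv, ThresholdSet(0.3, 0.15)).data[0, 0, 0] == 2

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_class_probability(self, seed):
        r = np.random.default_rng(seed)
        th = ThresholdSet(0.3, 0.15)
        pv = ProbVolume(aorta=r.random((3, 3, 3)), coronary=r.random((3, 3, 3)))
        base = fuse_labels(pv, th)
        raised = ProbVolume(
            aorta=pv.aorta, coronary=np.clip(pv.coronary + 0.2, 0, 1)
        )
        out = fuse_labels(raised, th)
        # raising coronary probability never removes a voxel from coronary
        assert ((base.data == 2) <= (out.data == 2)).all()

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ThresholdSet(t_aorta=0.0, t_coronary=0.5)

    def test_threshold_yaml_round_trip(self, tmp_path):
        th = ThresholdSet(0.42, 0.17)
        th.to_yaml(tmp_path / "th.yaml")
        back = ThresholdSet.from_yaml(tmp_path / "th.yaml")
        assert back == th
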