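import numpy as np
import pytest
from _oracles import flood_fill_components

from coroseg.classifier import (
    StumpModel,
    classify_geometry,
    coronary_components,
    detect_ostia,
    filter_small_components,
    fit_decision_stump,
    origin_angle,
)
from coroseg.errors import (
    AllComponentsRemovedError,
    ComponentCountError,
    EmptyCoronaryMaskError,
    StumpFitError,
)
from coroseg.metrics import ANOMALOUS, NORMAL
from coroseg.phantom import PhantomSpec, generate_phantom
from coroseg.volume_io import LabelVolume


def labels_from_mask(coronary_mask, aorta_mask=None):
    data = np.zeros(coronary_mask.shape, dtype=np.uint8)
    if aorta_mask is not None:
        data[aorta_mask] = 1
    data[coronary_mask] = 2
    return LabelVolume(data)


class TestCoronaryComponents:
    def test_single_tube(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 5, 5] = True
        assert coronary_components(labels_from_mask(mask)).count == 1

    def test_two_disjoint_tubes(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2, 2] = True
        mask[2:8, 7, 7] = True
        assert coronary_components(labels_from_mask(mask)).count == 2

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyCoronaryMaskError):
            coronary_components(labels_from_mask(np.zeros((5, 5, 5), bool)))

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        r = np.random.default_rng(17)
        for _ in range(20):
            mask = r.random((12, 12, 12)) < 0.25
            if not mask.any():
                continue
            cc = coronary_components(labels_from_mask(mask), connectivity=connectivity)
            ours = {frozenset(map(tuple, comp)) for comp in cc.components}
            assert ours == flood_fill_components(mask, connectivity)

    def test_component_volumes_use_spacing(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, 0:4] = True
        lv = LabelVolume((mask * 2).astype(np.uint8), spacing=(2.0, 2.0, 2.0))
        cc = coronary_components(lv)
        assert cc.volumes_ml[0] == pytest.approx(4 * 8 / 1000.0)


class TestFilterSmallComponents:
    def _cc(self, sizes_ml):
        # fabricate a components object with given volumes at 1 ml per voxel
        mask = np.zeros((30, 30, 30), bool)
        lv_data = np.zeros((30, 30, 30), dtype=np.uint8)
        start = 0
        for s in sizes_ml:
            n = int(s)
            lv_data[start, 0, :n] = 2
            start += 2
        lv = LabelVolume(lv_data, spacing=(10.0, 10.0, 10.0))  # 1 voxel = 1 ml
        return coronary_components(lv)

    def test_zero_threshold_is_identity(self):
        cc = self._cc([3, 5])
        out, notes = filter_small_components(cc, 0.0)
        assert out is cc and notes == []

    def test_removes_small_components(self):
        cc = self._cc([1, 5, 8])
        out, notes = filter_small_components(cc, 2.0)
        assert out.count == 2
        assert len(notes) == 1

    def test_all_removed_raises(self):
        cc = self._cc([1, 1])
        with pytest.raises(AllComponentsRemovedError):
            filter_small_components(cc, 100.0)


class TestDetectOstia:
    def test_adjacent_voxel_is_detected(self):
        data = np.zeros((12, 12, 12), dtype=np.uint8)
        data[5, 5, 5] = 1
        data[6, 5, 5] = 2  # touches the aorta
        data[5, 9:11, 5] = 2  # second trunk, nearest voxel (5, 9, 5)
        lv = LabelVolume(data)
        cc = coronary_components(lv)
        a, b = detect_ostia(lv, cc)
        assert {(a.i, a.j, a.k), (b.i, b.j, b.k)} == {(6, 5, 5), (5, 9, 5)}

    def test_requires_two_components(self, shared_phantom):
        _, lv, _ = shared_phantom
        cc = coronary_components(lv)
        with pytest.raises(ComponentCountError):
            detect_ostia(lv, cc)

    def test_translation_equivariance(self):
        data = np.zeros((16, 16, 16), dtype=np.uint8)
        data[4:6, 4:6, 4:8] = 1
        data[7, 4, 5] = 2
        data[4, 9:11, 5] = 2
        lv = LabelVolume(data)
        a, b = detect_ostia(lv, coronary_components(lv))
        shifted = LabelVolume(np.roll(data, 3, axis=(0, 1, 2)))
        a2, b2 = detect_ostia(shifted, coronary_components(shifted))
        assert (a2.i - a.i, a2.j - a.j, a2.k - a.k) == (3, 3, 3)
        assert (b2.i - b.i, b2.j - b.j, b2.k - b.k) == (3, 3, 3)

    def test_phantom_ostia_near_truth(self, normal_phantom):
        _, lv, truth = normal_phantom
        cc = coronary_components(lv)
        a, b = detect_ostia(lv, cc)
        for det in (a, b):
            d = min(
                np.linalg.norm(det.as_array() - np.array(t)) for t in truth.true_ostia
            )
            assert d <= 2.0


class TestOriginAngle:
    def _lv_with_ostia(self, a_ij, b_ij):
        data = np.zeros((40, 40, 10), dtype=np.uint8)
        data[19:22, 19:22, :] = 1  # small aorta block around centroid (20, 20)
        return LabelVolume(data)

    def test_antiparallel_gives_180(self):
        from coroseg.classifier import OstiumPoint

        lv = self._lv_with_ostia(None, None)
        res = origin_angle(lv, OstiumPoint(30, 20, 4), OstiumPoint(10, 20, 4))
        assert res.alpha_deg == pytest.approx(180.0)

    def test_orthogonal_gives_90(self):
        from coroseg.classifier import OstiumPoint

        lv = self._lv_with_ostia(None, None)
        res = origin_angle(lv, OstiumPoint(30, 20, 4), OstiumPoint(20, 30, 4))
        assert res.alpha_deg == pytest.approx(90.0)

    def test_z_half_between_ostia(self):
        from coroseg.classifier import OstiumPoint

        lv = self._lv_with_ostia(None, None)
        res = origin_angle(lv, OstiumPoint(30, 20, 2), OstiumPoint(10, 20, 7))
        assert res.z_half == pytest.approx(4.5)

    def test_phantom_separation_recovered(self):
        spec = PhantomSpec(variant="normal", ostium_azimuths_deg=[10.0, 145.0], noise_seed=2)
        _, lv, truth = generate_phantom(spec)
        cc = coronary_components(lv)
        a, b = detect_ostia(lv, cc)
        res = origin_angle(lv, a, b)
        assert res.alpha_deg == pytest.approx(135.0, abs=8.0)

    def test_right_angle_rotation_invariance(self):
        # Each trunk touches the aorta at a unique closest voxel, so the
        # detected ostia rotate rigidly with the volume and alpha is exact.
        data = np.zeros((24, 24, 8), dtype=np.uint8)
        data[10:14, 10:14, :] = 1  # aorta block, centroid (11.5, 11.5)
        data[14:19, 11, 3] = 2  # trunk A: unique closest voxel (14, 11, 3)
        data[11, 14:20, 5] = 2  # trunk B: unique closest voxel (11, 14, 5)
        lv = LabelVolume(data)
        alpha0 = origin_angle(lv, *detect_ostia(lv, coronary_components(lv))).alpha_deg
        for k in (1, 2, 3):
            rot = LabelVolume(np.rot90(lv.data, k=k, axes=(0, 1)).copy())
            alphar = origin_angle(rot, *detect_ostia(rot, coronary_components(rot))).alpha_deg
            assert alphar == pytest.approx(alpha0, abs=1e-9)

    def test_degenerate_vector_raises(self):
        from coroseg.classifier import OstiumPoint
        from coroseg.errors import DegenerateAngleError

        lv = self._lv_with_ostia(None, None)
        with pytest.raises(DegenerateAngleError):
            origin_angle(lv, OstiumPoint(20, 20, 4), OstiumPoint(10, 20, 4))


class TestDecisionStump:
    def test_reference_angles_give_widest_gap_midpoint(self):
        angles = [121.0, 135.0, 154.0, 20.0, 30.0, 46.0]
        labels = [NORMAL] * 3 + [ANOMALOUS] * 3
        stump = fit_decision_stump(angles, labels)
        assert stump.threshold_deg == pytest.approx(83.5)
        assert stump.training_accuracy == 1.0
        # all six training angles classified correctly
        for a, lab in zip(angles, labels):
            assert stump.predict(a) == lab

    def test_matches_exhaustive_midpoint_search(self):
        r = np.random.default_rng(5)
        for _ in range(20):
            n_angles = r.normal(130, 15, size=6)
            a_angles = r.normal(35, 10, size=5)
            angles = np.concatenate([n_angles, a_angles])
            labels = [NORMAL] * 6 + [ANOMALOUS] * 5
            stump = fit_decision_stump(angles, labels)
            uniq = np.unique(angles)
            mids = (uniq[:-1] + uniq[1:]) / 2
            y = np.array([lab == ANOMALOUS for lab in labels])
            accs = [((angles < t) == y).mean() for t in mids]
            assert ((angles < stump.threshold_deg) == y).mean() == max(accs)

    def test_interleaved_classes_warns(self):
        angles = [10.0, 20.0, 30.0, 40.0]
        labels = [ANOMALOUS, NORMAL, ANOMALOUS, NORMAL]
        with pytest.warns(UserWarning, match="not separable"):
            stump = fit_decision_stump(angles, labels)
        assert stump.training_accuracy < 1.0
        assert stump.warnings

    def test_single_class_raises(self):
        with pytest.raises(StumpFitError):
            fit_decision_stump([10.0, 20.0], [ANOMALOUS, ANOMALOUS])


class TestClassifyGeometry:
    def test_shared_ostium_is_anomalous_by_connectivity(self, shared_phantom):
        _, lv, _ = shared_phantom
        res = classify_geometry(lv)
        assert res.label == ANOMALOUS
        assert res.reason == "connectivity"
        assert res.n_components == 1

    def test_three_trunks_anomalous_by_connectivity(self):
        _, lv, _ = generate_phantom(PhantomSpec(variant="anomalous_three", noise_seed=8))
        res = classify_geometry(lv)
        assert res.label == ANOMALOUS and res.reason == "connectivity"
        assert res.n_components == 3

    def test_wide_normal_geometry_is_normal(self):
        spec = PhantomSpec(variant="normal", ostium_azimuths_deg=[0.0, 135.0], noise_seed=9)
        _, lv, _ = generate_phantom(spec)
        res = classify_geometry(lv, StumpModel(threshold_deg=73.0))
        assert res.label == NORMAL and res.reason == "angle"
        assert res.alpha_deg == pytest.approx(135.0, abs=8.0)

    def test_close_ostia_anomalous_by_angle(self):
        spec = PhantomSpec(
            variant="anomalous_close", ostium_azimuths_deg=[50.0, 80.0], noise_seed=10
        )
        _, lv, _ = generate_phantom(spec)
        res = classify_geometry(lv, StumpModel(threshold_deg=73.0))
        assert res.label == ANOMALOUS and res.reason == "angle"

    def test_never_normal_when_count_not_two(self):
        for variant in ("anomalous_shared", "anomalous_three"):
            for seed in (0, 1, 2):
                _, lv, _ = generate_phantom(PhantomSpec(variant=variant, noise_seed=seed))
                assert classify_geometry(lv).label == ANOMALOUS

    def test_size_filter_restores_two_component_reading(self):
        # two tubes plus a small spurious blob -> 3 components -> anomalous;
        # with the filter the blob is dropped and the angle rules
        spec = PhantomSpec(variant="normal", ostium_azimuths_deg=[0.0, 140.0], noise_seed=13)
        _, lv, _ = generate_phantom(spec)
        data = lv.data.copy()
        data[2:4, 2:4, 30:32] = 2  # 8-voxel blob far from the aorta
        lv2 = LabelVolume(data, lv.spacing)
        res_plain = classify_geometry(lv2)
        assert res_plain.label == ANOMALOUS and res_plain.n_components == 3
        res_filtered = classify_geometry(lv2, min_volume_ml=0.05)
        assert res_filtered.n_components == 2
        assert res_filtered.label == NORMAL
        assert res_filtered.warnings
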