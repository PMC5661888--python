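"""Slice classification, component selection, and 3-D propagation rules."""

import numpy as np
import pytest

from cfcnn.errors import GeometryError, SegmentationStartError
from cfcnn.metrics import dice
from cfcnn.segmentation import (
    ConstantVoxelClassifier,
    OracleVoxelClassifier,
    apply_area_stop_rule,
    classify_slice,
    propagate,
    segment,
    select_component,
)
from cfcnn.volumes import BoundingBox2D, CtVolume, NoduleMask


@pytest.fixture()
def flat_volume():
    return CtVolume(np.zeros((9, 40, 40)), (1, 1, 1), "flat")


class TestClassifySlice:
    def test_constant_high_probability_fills_box(self, flat_volume):
        box = BoundingBox2D(4, 10, 20, 12, 22)
        mask, pmap = classify_slice(ConstantVoxelClassifier(0.9), flat_volume, box)
        assert mask.sum() == 100
        assert mask[10:20, 12:22].all()
        assert not mask[:10].any()
        assert pmap.probs.shape == (10, 10)

    def test_threshold_is_inclusive(self, flat_volume):
        box = BoundingBox2D(4, 10, 20, 12, 22)
        mask, _ = classify_slice(ConstantVoxelClassifier(0.5), flat_volume, box, 0.5)
        assert mask[10:20, 12:22].all()  # p == threshold counts as nodule

    def test_oracle_reproduces_ground_truth(self, sphere_phantom):
        oracle = OracleVoxelClassifier(sphere_phantom.mask)
        box = sphere_phantom.start_box
        mask, _ = classify_slice(oracle, sphere_phantom.volume, box)
        gt = sphere_phantom.mask.labels[box.slice_index]
        assert np.array_equal(mask, gt)

    def test_box_outside_volume(self, flat_volume):
        with pytest.raises(GeometryError):
            classify_slice(
                ConstantVoxelClassifier(0.9),
                flat_volume,
                BoundingBox2D(20, 0, 5, 0, 5),
            )


class TestSelectComponent:
    def _two_regions(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[2:5, 2:5] = 1  # centroid (3, 3)
        m[12:17, 12:17] = 1  # centroid (14, 14)
        return m

    def test_keeps_region_nearest_reference(self):
        m = self._two_regions()
        kept = select_component(m, "propagated", reference=(13.0, 13.0))
        assert kept[12:17, 12:17].all() and not kept[2:5, 2:5].any()
        kept = select_component(m, "starting", reference=(4.0, 4.0))
        assert kept[2:5, 2:5].all() and not kept[12:17, 12:17].any()

    def test_single_region_unchanged(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[3:6, 3:6] = 1
        assert np.array_equal(select_component(m, "starting", (0.0, 0.0)), m)

    def test_empty_mask_passes_through(self):
        empty = np.zeros((8, 8), dtype=np.uint8)
        assert not select_component(empty, "propagated", (4.0, 4.0)).any()

    def test_tie_keeps_larger_region(self):
        """Equidistant centroids: the larger region wins, verified against
        exhaustive evaluation of both candidates on a toy grid."""
        m = np.zeros((10, 10), dtype=np.uint8)
        m[4, 1:3] = 1  # centroid (4.0, 1.5), area 2
        m[3:6, 7:9] = 1  # centroid (4.0, 7.5), area 6
        ref = (4.0, 4.5)  # distance 3.0 to both centroids
        areas = {2: m[4, 1:3].sum(), 6: m[3:6, 7:9].sum()}
        assert areas[2] < areas[6]
        kept = select_component(m, "propagated", ref)
        assert kept[3:6, 7:9].all() and not kept[4, 1:3].any()

    def test_eight_connectivity(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[1, 1] = m[2, 2] = 1  # diagonal touch = one component
        kept = select_component(m, "starting", (0.0, 0.0))
        assert kept.sum() == 2


class TestAreaStopRule:
    def test_ten_percent_drop_excluded(self):
        # kept area 40 followed by 4: 4 < 0.3 * 40, slice excluded
        assert apply_area_stop_rule([40, 4]) == 1

    def test_exactly_thirty_percent_continues(self):
        assert apply_area_stop_rule([40, 12]) == 2  # 12 == 0.3 * 40, kept

    def test_empty_slice_stops(self):
        assert apply_area_stop_rule([40, 30, 0, 30]) == 2

    def test_ratio_uses_preceding_kept_slice(self):
        # 100 -> 35 (ok, vs 30) -> 10 (10 < 0.3*35 = 10.5 -> stop)
        assert apply_area_stop_rule([100, 35, 10]) == 2


class TestPropagate:
    def test_oracle_on_sphere_equals_ground_truth(self, sphere_phantom):
        """With a perfect classifier the pipeline reconstructs the phantom
        exactly and stops at the empty slices beyond the poles."""
        oracle = OracleVoxelClassifier(sphere_phantom.mask)
        result = propagate(oracle, sphere_phantom.volume, sphere_phantom.start_box)
        assert np.array_equal(result.mask.labels, sphere_phantom.mask.labels)
        assert result.stop_reason_up == "empty_slice"
        assert result.stop_reason_down == "empty_slice"
        assert dice(sphere_phantom.mask, result.mask) == 1.0

    def test_area_rule_excludes_violating_slice(self, flat_volume):
        """A synthetic probability field whose area collapses from 40 to 4
        voxels stops propagation with the 4-voxel slice excluded."""

        class ShrinkingClassifier:
            def predict_voxels(self, volume, coords):
                out = []
                for s, r, c in coords:
                    if s == 4:
                        on = 10 <= r < 15 and 10 <= c < 18  # 40 voxels
                    elif s == 5:
                        on = 12 <= r < 14 and 12 <= c < 14  # 4 voxels
                    else:
                        on = False
                    out.append(1.0 if on else 0.0)
                return np.array(out)

        box = BoundingBox2D(4, 5, 25, 5, 25)
        result = propagate(ShrinkingClassifier(), flat_volume, box)
        assert result.per_slice_area == {4: 40}
        assert result.stop_reason_down == "area_ratio"
        assert result.stop_reason_up == "empty_slice"
        assert not result.mask.labels[5].any()

    def test_exact_thirty_percent_kept(self, flat_volume):
        class ExactThirty:
            def predict_voxels(self, volume, coords):
                out = []
                for s, r, c in coords:
                    if s == 4:
                        on = 10 <= r < 15 and 10 <= c < 18  # 40
                    elif s == 5:
                        on = 11 <= r < 14 and 11 <= c < 15  # 12 = 30%
                    else:
                        on = False
                    out.append(1.0 if on else 0.0)
                return np.array(out)

        result = propagate(ExactThirty(), flat_volume, BoundingBox2D(4, 5, 25, 5, 25))
        assert result.per_slice_area == {4: 40, 5: 12}

    def test_component_selection_follows_centroid(self, flat_volume):
        """Noise regions on later slices are discarded in favour of the
        component nearest the preceding slice's centroid."""

        class NoisyClassifier:
            def predict_voxels(self, volume, coords):
                out = []
                for s, r, c in coords:
                    on = False
                    if s in (4, 5):
                        on = 10 <= r < 16 and 10 <= c < 16
                        if s == 5 and 20 <= r < 22 and 20 <= c < 22:
                            on = True  # distant 4-voxel noise blob
                    out.append(1.0 if on else 0.0)
                return np.array(out)

        result = propagate(
            NoisyClassifier(), flat_volume, BoundingBox2D(4, 5, 25, 5, 25)
        )
        assert result.per_slice_area[5] == 36
        assert not result.mask.labels[5, 20:22, 20:22].any()

    def test_constant_zero_raises_start_error(self, flat_volume):
        with pytest.raises(SegmentationStartError):
            propagate(
                ConstantVoxelClassifier(0.0), flat_volume, BoundingBox2D(4, 5, 25, 5, 25)
            )

    def test_monotone_stop(self, sphere_phantom):
        """No nonempty slice appears beyond the stopping point."""
        oracle = OracleVoxelClassifier(sphere_phantom.mask)
        result = propagate(oracle, sphere_phantom.volume, sphere_phantom.start_box)
        kept = sorted(result.per_slice_area)
        lo, hi = kept[0], kept[-1]
        assert not result.mask.labels[:lo].any()
        assert not result.mask.labels[hi + 1 :].any()
        assert set(kept) == set(range(lo, hi + 1))


class TestSegment:
    def test_oracle_dice_is_one(self, sphere_phantom):
        oracle = OracleVoxelClassifier(sphere_phantom.mask)
        result = segment(oracle, sphere_phantom.volume, sphere_phantom.start_box)
        assert dice(sphere_phantom.mask, result.mask) == 1.0

    def test_juxtapleural_oracle(self):
        from cfcnn.phantoms import PhantomConfig, generate_phantom

        ph = generate_phantom(
            PhantomConfig(nodule_kind="juxtapleural", radius_vox=6.5, noise_sd=0.0)
        )
        result = segment(OracleVoxelClassifier(ph.mask), ph.volume, ph.start_box)
        assert dice(ph.mask, result.mask) > 0.95

    def test_result_confined_to_box_footprint(self, sphere_phantom):
        oracle = OracleVoxelClassifier(sphere_phantom.mask)
        result = segment(oracle, sphere_phantom.volume, sphere_phantom.start_box)
        box = result.start_box
        outside = np.ones_like(result.mask.labels, dtype=bool)
        outside[:, box.row_start : box.row_stop, box.col_start : box.col_stop] = False
        assert not (result.mask.labels.astype(bool) & outside).any()
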