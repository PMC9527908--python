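import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ttmorph as tm
from ttmorph.errors import MeasurementError
from ttmorph.morphometry import (
    TubuleComponent, equivalent_diameter_from_contours, label_components,
    longest_branch_length, subsample_metrics,
)
from ttmorph.volume import LabelVolume, SliceContour

from conftest import join_truth, single_tubule_scene


def _volume_from_mask(mask, spacing=(10.0, 10.0, 50.0), with_extracellular_at_z0=False):
    vox = np.ones(mask.shape, dtype=np.uint16)  # cell everywhere
    vox[mask] = 3
    if with_extracellular_at_z0:
        vox[0] = 2
        vox[0][mask[0]] = 3  # object may reach the face and touch the slab above
    return LabelVolume(vox, spacing, cell_label=1, extracellular_label=2)


def _single_component(mask, spacing=(10.0, 10.0, 50.0), **kw):
    vol = _volume_from_mask(mask, spacing, **kw)
    comps = label_components(vol, min_voxels=1)
    assert len(comps) == 1
    return comps[0]


class TestComponents:
    def test_disjoint_objects_give_separate_components(self):
        mask = np.zeros((4, 20, 20), dtype=bool)
        mask[:, 2:6, 2:6] = True
        mask[:, 12:16, 12:16] = True
        vol = _volume_from_mask(mask)
        comps = label_components(vol)
        assert len(comps) == 2
        assert all(not c.touches_extracellular for c in comps)

    def test_extracellular_contact_flag(self, control_cell):
        _, _, _, comps, _ = control_cell
        assert all(c.touches_extracellular for c in comps)

    def test_min_voxels_discards_specks(self):
        mask = np.zeros((3, 10, 10), dtype=bool)
        mask[1, 5, 5] = True           # single voxel
        mask[:, 1:3, 1:3] = True       # 12 voxels
        vol = _volume_from_mask(mask)
        assert len(label_components(vol, min_voxels=4)) == 1
        assert len(label_components(vol, min_voxels=1)) == 2

    def test_connectivity_6_splits_diagonal_chain(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        vol = _volume_from_mask(mask)
        assert len(label_components(vol, connectivity=26, min_voxels=1)) == 1
        assert len(label_components(vol, connectivity=6, min_voxels=1)) == 2


class TestVolumeAndArea:
    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((10, 20, 20), dtype=bool)
        mask[:, 5:15, 5:15] = True  # 1000 voxels
        comp = _single_component(mask)
        assert tm.component_volume(comp) == pytest.approx(0.005, rel=1e-12)

    def test_volume_conservation_is_exact(self, control_cell):
        _, _, vol, comps, rec = control_cell
        total = rec["volume_um3"].sum()
        expected = int(vol.object_mask().sum()) * vol.voxel_volume_nm3 / 1e9
        assert total == pytest.approx(expected, rel=1e-12)

    def test_cube_surface_area(self):
        # 1 µm cube at (10,10,50) nm: 20 slices × 100 × 100 voxels
        mask = np.zeros((24, 120, 120), dtype=bool)
        mask[2:22, 10:110, 10:110] = True
        comp = _single_component(mask)
        assert tm.component_surface_area(comp) == pytest.approx(6.0, rel=0.10)

    def test_cylinder_surface_area_oracle(self):
        scene = single_tubule_scene(length=5.0, radius_nm=200.0, mod_amp=0.0)
        vol = tm.voxelize_scene(scene)
        comp = label_components(vol)[0]
        true = 2 * np.pi * 0.2 * 5.0 + 2 * np.pi * 0.2**2  # 6.534 µm²
        assert tm.component_surface_area(comp) == pytest.approx(true, rel=0.10)

    def test_dilation_grows_area_of_boxes(self):
        from scipy import ndimage
        areas = []
        for grow in range(3):
            mask = np.zeros((20, 60, 60), dtype=bool)
            mask[5:12, 20:40, 20:40] = True
            if grow:
                mask = ndimage.binary_dilation(mask, iterations=grow)
            areas.append(tm.component_surface_area(_single_component(mask)))
        assert areas[0] < areas[1] < areas[2]


def _circle_contour(diameter_nm, n=64, slice_index=0):
    r = diameter_nm / 2
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    v = np.column_stack([r * np.cos(th), r * np.sin(th)])
    v = np.vstack([v, v[:1]])
    per = float(np.sqrt((np.diff(v, axis=0) ** 2).sum(1)).sum())
    area = abs(np.dot(v[:-1, 0], v[1:, 1]) - np.dot(v[1:, 0], v[:-1, 1])) / 2
    return SliceContour(slice_index=slice_index, vertices=v, perimeter=per, area=area)


class TestEquivalentDiameter:
    def test_circle_identity(self):
        """Three circular contours of perimeter π·400 give exactly 400 nm."""
        cs = [SliceContour(i, np.zeros((2, 2)), np.pi * 400.0, 1.0) for i in range(3)]
        assert equivalent_diameter_from_contours(cs) == pytest.approx(400.0, rel=1e-12)
        one = [SliceContour(0, np.zeros((2, 2)), 1570.80, 1.0)]
        assert equivalent_diameter_from_contours(one) == pytest.approx(500.0, rel=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=10.0, max_value=5000.0), min_size=1, max_size=30))
    def test_formula_is_mean_perimeter_over_pi(self, perimeters):
        cs = [SliceContour(i, np.zeros((2, 2)), p, 1.0) for i, p in enumerate(perimeters)]
        expected = np.mean(perimeters) / np.pi
        assert equivalent_diameter_from_contours(cs) == pytest.approx(expected, rel=1e-9)

    def test_voxelized_cylinder_diameter(self):
        scene = single_tubule_scene(length=3.0, radius_nm=200.0, mod_amp=0.0)
        vol = tm.voxelize_scene(scene)
        comp = label_components(vol)[0]
        assert tm.equivalent_diameter(comp) == pytest.approx(400.0, rel=0.05)

    def test_area_variant(self):
        cs = [_circle_contour(400.0)]
        d = equivalent_diameter_from_contours(cs, variant="area")
        assert d == pytest.approx(400.0, rel=0.01)

    def test_no_contours_raises(self):
        with pytest.raises(MeasurementError):
            equivalent_diameter_from_contours([])


class TestLongestBranch:
    def test_straight_cylinder_length(self):
        scene = single_tubule_scene(length=4.0, radius_nm=200.0, mod_amp=0.0)
        vol = tm.voxelize_scene(scene)
        comp = label_components(vol)[0]
        L = longest_branch_length(comp)
        assert L == pytest.approx(4.0, abs=max(0.05, 2 * 0.01) + 0.15)

    def test_y_shape_returns_longer_branch(self):
        # main trunk 4 µm along Z from the face; side arm 1.5 µm in X at depth 1 µm
        sp = (50.0, 50.0, 50.0)
        mask = np.zeros((90, 24, 50), dtype=bool)
        zz, yy, xx = np.mgrid[0:90, 0:24, 0:50]
        trunk = ((yy - 12) ** 2 + (xx - 10) ** 2 <= 4**2) & (zz >= 1) & (zz <= 81)
        arm = ((yy - 12) ** 2 + (zz - 21) ** 2 <= 4**2) & (xx >= 10) & (xx <= 40)
        mask = trunk | arm
        comp = _single_component(mask, spacing=sp, with_extracellular_at_z0=True)
        assert comp.touches_extracellular
        L = longest_branch_length(comp)
        assert L == pytest.approx(4.0, abs=0.4)     # not 1.0 + 1.5

    def test_single_voxel_degenerate(self):
        mask = np.zeros((3, 5, 5), dtype=bool)
        mask[1, 2, 2] = True
        comp = _single_component(mask)
        assert longest_branch_length(comp) == 0.0


class TestWidthAndFractions:
    def test_length_fraction_arithmetic(self):
        assert tm.length_fraction(5.0, 12.5) == pytest.approx(0.40)
        assert tm.length_fraction(7.0, 7.0) == 1.0
        with pytest.raises(MeasurementError):
            tm.length_fraction(1.0, 0.0)

    def test_cell_width_perpendicular_box(self, control_cell):
        scene, _, vol, comps, rec = control_cell
        w = rec.loc[rec["class"] == "tubule", "cell_width_um"]
        assert np.allclose(w, scene.spec.cell_width, rtol=0.02)

    def test_cell_width_45_degree_chord(self):
        # 6 µm-wide slab cell along Z; tubule axis at 45° in the X–Z plane
        sp = (50.0, 50.0, 50.0)
        nz, ny, nx = 140, 30, 170
        vox = np.full((nz, ny, nx), 2, dtype=np.uint16)
        vox[4:124] = 1                       # slab faces at z-index 4 and 124 (6 µm)
        p0 = np.array([4.0, 15.0, 20.0])     # entry point on the lower face
        d = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
        rel = np.stack([zz - p0[0], yy - p0[1], xx - p0[2]], axis=-1)
        t = rel @ d
        dist2 = (rel**2).sum(-1) - t**2
        tub = (t >= 0) & (t <= 60) & (dist2 <= 4**2) & (vox == 1)
        vox[tub] = 3
        vol = LabelVolume(vox, sp, cell_label=1, extracellular_label=2)
        comp = label_components(vol, min_voxels=1)[0]
        assert comp.touches_extracellular
        w = tm.cell_width_at(vol, comp)
        assert w == pytest.approx(6.0 * np.sqrt(2), rel=0.05)

    def test_recovered_penetration_fraction(self, control_cell):
        _, gt, _, _, rec = control_cell
        j = join_truth(rec, gt)
        assert np.allclose(j["length_fraction"], j["length_fraction_true"], rtol=0.08)


class TestSummariesAndSubsample:
    def test_density_and_volume_fraction_arithmetic(self):
        rec = pd.DataFrame({
            "class": ["tubule"] * 14, "volume_um3": [3.6 / 14] * 14,
        })
        s = tm.cell_summaries(rec, cell_volume_um3=200.0)
        assert s["tubule_density_per_um3"] == pytest.approx(0.07)
        assert s["tubule_volume_fraction_pct"] == pytest.approx(1.8)

    def test_empty_cell_is_valid(self):
        s = tm.cell_summaries(pd.DataFrame(), cell_volume_um3=100.0)
        assert s["tubule_density_per_um3"] == 0.0
        assert s["tubule_volume_fraction_pct"] == 0.0

    def test_summaries_invariant_to_relabelling(self, control_cell):
        _, _, _, _, rec = control_cell
        base = tm.cell_summaries(rec, 100.0)
        shuffled = rec.sample(frac=1.0, random_state=5).reset_index(drop=True)
        shuffled["component_id"] = np.arange(len(shuffled))[::-1]
        other = tm.cell_summaries(shuffled, 100.0)
        for key, val in base.items():
            if isinstance(val, float):
                assert other[key] == pytest.approx(val, rel=1e-12), key
            else:
                assert other[key] == val, key

    def test_subsample_deterministic_and_distinct_seeds(self):
        rec = pd.DataFrame({"class": ["tubule"] * 20, "volume_um3": np.arange(20.0)})
        a = subsample_metrics(rec, k=15, seed=7)
        b = subsample_metrics(rec, k=15, seed=7)
        assert list(a.index) == list(b.index) and len(a) == 15
        c = subsample_metrics(rec, k=15, seed=8)
        assert list(a.index) != list(c.index)

    def test_subsample_smaller_population_returns_all(self):
        rec = pd.DataFrame({"class": ["tubule"] * 10, "volume_um3": np.arange(10.0)})
        assert len(subsample_metrics(rec, k=15, seed=0)) == 10
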