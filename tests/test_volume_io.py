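import numpy as np
import pytest
import tifffile

import ttmorph as tm
from ttmorph.errors import BoundsError, ConfigurationError, VolumeFormatError
from ttmorph.volume import LabelVolume, contours_from_mask


def _demo_volume(shape=(12, 16, 16), spacing=(10.0, 10.0, 50.0)):
    rng = np.random.default_rng(0)
    vox = rng.integers(0, 5, size=shape).astype(np.uint16)
    return LabelVolume(voxels=vox, spacing=spacing, cell_label=1, extracellular_label=2)


@pytest.mark.parametrize("fmt,ext", [("tiff", ".tif"), ("mrc", ".mrc")])
def test_roundtrip_bit_exact(tmp_path, fmt, ext):
    vol = _demo_volume()
    path = tmp_path / f"vol{ext}"
    tm.write_label_volume(vol, path, format=fmt)
    back = tm.read_label_volume(path)
    assert np.array_equal(back.voxels, vol.voxels)
    assert back.spacing == vol.spacing
    assert back.object_labels == vol.object_labels
    assert back.cell_label == vol.cell_label


def test_mrc_spacing_survives_in_header(tmp_path):
    vol = _demo_volume(spacing=(8.0, 11.0, 50.0))
    path = tmp_path / "vol.mrc"
    tm.write_label_volume(vol, path, format="mrc")
    # drop the sidecar: spacing must still come back from the map header
    (tmp_path / "vol.mrc.json").unlink()
    back = tm.read_label_volume(path)
    assert np.allclose(back.spacing, vol.spacing)


def test_all_zero_volume_roundtrip(tmp_path):
    vol = LabelVolume(np.zeros((5, 6, 7), dtype=np.int32), (10, 10, 50))
    path = tm.write_label_volume(vol, tmp_path / "z.tif")
    back = tm.read_label_volume(path)
    assert back.voxels.sum() == 0 and back.shape == (5, 6, 7)


def test_float_tiff_rejected(tmp_path):
    path = tmp_path / "f.tif"
    tifffile.imwrite(str(path), np.zeros((3, 4, 4), dtype=np.float32))
    with pytest.raises(VolumeFormatError):
        tm.read_label_volume(path, spacing=(10, 10, 50))


def test_missing_file_and_missing_spacing(tmp_path):
    with pytest.raises(FileNotFoundError):
        tm.read_label_volume(tmp_path / "nope.tif")
    path = tmp_path / "bare.tif"
    tifffile.imwrite(str(path), np.zeros((3, 4, 4), dtype=np.uint8))
    with pytest.raises(ConfigurationError):
        tm.read_label_volume(path)  # no sidecar, no spacing argument


def test_overlapping_label_roles_rejected():
    with pytest.raises(ConfigurationError):
        LabelVolume(np.zeros((2, 2, 2), dtype=np.uint8), (10, 10, 50),
                    cell_label=1, extracellular_label=1)
    with pytest.raises(ConfigurationError):
        LabelVolume(np.zeros((2, 2, 2), dtype=np.uint8), (10, 10, 50),
                    cell_label=1, extracellular_label=2, object_labels={2, 3})


def test_crop_stack_portion():
    vol = _demo_volume(shape=(30, 8, 8))
    sub = tm.crop_stack_portion(vol, start_slice=5, n_slices=10)
    assert sub.shape == (10, 8, 8)
    assert np.array_equal(sub.voxels[0], vol.voxels[5])
    assert sub.provenance["crop_window"] == {"start_slice": 5, "n_slices": 10}
    # full-depth crop is the identity
    full = tm.crop_stack_portion(vol, 0, 30)
    assert np.array_equal(full.voxels, vol.voxels)
    with pytest.raises(BoundsError):
        tm.crop_stack_portion(vol, 25, 10)


def _disc_mask(radius_nm, spacing_nm, offset=0.2):
    r = radius_nm / spacing_nm
    n = int(2 * r) + 8
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2 + offset
    return ((xx - c) ** 2 + (yy - c) ** 2) <= r**2


def test_disc_contour_matches_analytic_circle():
    """A digitized 200 nm disc at 10 nm spacing: perimeter and area within 5%."""
    mask = _disc_mask(200.0, 10.0)
    (contour,) = contours_from_mask(mask, (10.0, 10.0))
    assert contour.perimeter == pytest.approx(2 * np.pi * 200.0, rel=0.05)
    assert contour.area == pytest.approx(np.pi * 200.0**2, rel=0.05)
    # perimeter is consistent with its own vertex chain
    d = np.diff(contour.vertices, axis=0)
    assert contour.perimeter == pytest.approx(np.sqrt((d**2).sum(1)).sum(), rel=1e-9)


def test_disc_perimeter_converges_with_spacing():
    """Finer sampling cannot worsen the perimeter error (small numerical slack)."""
    errs = []
    for s in (20.0, 10.0, 5.0):
        mask = _disc_mask(200.0, s)
        (c,) = contours_from_mask(mask, (s, s))
        errs.append(abs(c.perimeter - 2 * np.pi * 200.0) / (2 * np.pi * 200.0))
    assert errs[1] <= errs[0] + 0.003
    assert errs[2] <= errs[1] + 0.003


def test_two_cross_sections_and_empty_slice():
    vox = np.zeros((2, 30, 30), dtype=np.uint8)
    vox[0, 5:10, 5:10] = 3
    vox[0, 20:26, 20:26] = 3
    vol = LabelVolume(vox, (10, 10, 50))
    assert len(tm.extract_slice_contours(vol, 3, 0)) == 2
    assert tm.extract_slice_contours(vol, 3, 1) == []
    with pytest.raises(BoundsError):
        tm.extract_slice_contours(vol, 3, 5)


def test_contour_areas_cross_check_voxel_volume(control_cell):
    """Σ(contour areas)·sz tracks the voxel volume within 10% for tubules."""
    _, _, vol, comps, _ = control_cell
    sz = vol.spacing[2]
    for comp in comps[:3]:
        contour_vol = sum(c.area for c in comp.contour_stack()) * sz / 1e9
        voxel_vol = tm.component_volume(comp)
        assert contour_vol == pytest.approx(voxel_vol, rel=0.10)
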