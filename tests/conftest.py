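import numpy as np
import pytest

import ttmorph as tm
from ttmorph.synthetic import SyntheticScene, SyntheticSpec, TubulePrimitive


def tiny_spec(**overrides):
    """Small, fast control-like scene: 2 z-lines × 1 lane in a 5 µm cell."""
    base = dict(cell_width=5.0, cell_depth=0.9, n_zlines=2,
                tubule_radius_mean=202.5, fragment_count=0)
    base.update(overrides)
    return SyntheticSpec(**base)


def single_tubule_scene(length=5.0, radius_nm=200.0, mod_amp=0.0, phase=0.0,
                        cell_width=6.0, cell_depth=1.2):
    """Hand-built scene holding exactly one straight tubule (analytic oracle)."""
    spec = SyntheticSpec(cell_width=cell_width, cell_depth=cell_depth, n_zlines=1,
                         tubule_radius_mean=radius_nm,
                         radius_modulation_amplitude=mod_amp)
    scene = SyntheticScene(spec=spec, seed=0)
    scene.tubules.append(TubulePrimitive(
        primitive_id=0, label=3, x0=1.0, y0=cell_depth / 2.0, length=length,
        r0=radius_nm / 1000.0, mod_amp=mod_amp, mod_wavelength=1.5, mod_phase=phase))
    return scene


@pytest.fixture(scope="session")
def control_cell():
    """One measured control-like cell shared across tests: (scene, truth, volume, components, records)."""
    scene, gt = tm.build_scene(tm.control_spec(), seed=1)
    vol = tm.voxelize_scene(scene)
    comps = tm.label_components(vol)
    rec = tm.measure_components(vol, comps, animal_id="a0", cell_id="c0", region="control")
    return scene, gt, vol, comps, rec


@pytest.fixture(scope="session")
def border_cell():
    """Border-like cell with fragments and longitudinal elements."""
    scene, gt = tm.build_scene(
        tm.border_spec(n_zlines=3, fragment_count=5, longitudinal_probability=0.4), seed=7)
    vol = tm.voxelize_scene(scene)
    comps = tm.label_components(vol)
    rec = tm.measure_components(vol, comps, animal_id="a0", cell_id="c0", region="border")
    return scene, gt, vol, comps, rec


def join_truth(records, truth):
    """Join measured records to ground truth on the voxelization labels."""
    return records.set_index("source_labels").join(
        truth.set_index("labels"), rsuffix="_true")
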