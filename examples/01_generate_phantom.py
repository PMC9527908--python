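"""Generate a synthetic t-tubule label volume with analytic ground truth.

Builds one control-like cell (regular tubule lattice at ~2 µm z-line
pitch, ~200 nm mean radius with sinusoidal narrowings/dilations), writes
it as a multi-page TIFF with a JSON sidecar, and prints the analytic
per-primitive metrics that any measurement must recover.
"""

import ttmorph as tm

scene, truth = tm.build_scene(tm.control_spec(), seed=1)
volume = tm.voxelize_scene(scene, spacing=(10.0, 10.0, 50.0))
tm.write_label_volume(volume, "phantom_control.tif")

print(f"scene: {len(scene.tubules)} tubules, {len(scene.fragments)} fragments")
print(f"volume shape (Z,Y,X): {volume.shape}, spacing {volume.spacing} nm")
print("\nanalytic ground truth (volume µm³, area µm², diameter nm, length µm):")
cols = ["labels", "class", "volume_um3", "surface_area_um2",
        "diameter_nm", "longest_branch_um", "length_fraction"]
print(truth[cols].round(3).to_string(index=False))
print("\nlength_fraction is the penetration depth divided by the 8 µm cell width;")
print("values near 0.41 mean tubules reach a bit less than half-way across the cell.")
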