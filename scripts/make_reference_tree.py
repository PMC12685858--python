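"""Regenerate the packaged calibrated reference tree.

Provenance of src/emboflow/data/reference_tree.json: a seeded generator
run with the default topology (43 outlets, target branch at depth 5 with
10 target outlets, inlet radius 2.31 mm) followed by stall calibration to
5000 Pa at 5 cm^3/s inlet flow with non-target outlets at 300 Pa. The
committed file is byte-stable; rerun this script only to regenerate it
deliberately.
"""

from pathlib import Path

from emboflow import (
    BoundaryConditions,
    TreeGenConfig,
    calibrate_stall_pressure,
    find_stall_pressure,
    generate_tree,
    write_tree,
)

FIXTURE_SEED = 7
DESIRED_STALL_PA = 5000.0

out = Path(__file__).resolve().parents[1] / "src/emboflow/data/reference_tree.json"
tree = generate_tree(TreeGenConfig(random_seed=FIXTURE_SEED))
bc = BoundaryConditions(inlet_flow=5e-6, non_target_pressure=300.0)
calibrated = calibrate_stall_pressure(tree, bc, DESIRED_STALL_PA)
out.parent.mkdir(parents=True, exist_ok=True)
write_tree(calibrated, out)
print(f"wrote {out}")
print(f"verified stall: {find_stall_pressure(calibrated, bc):.2f} Pa")
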