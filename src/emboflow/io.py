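"""Reading and writing vascular trees and solution tables.

Canonical tree format is JSON::

    {"schema_version": 1,
     "fluid": {"density": 1060.0, "viscosity": 0.0035},
     "inlet_id": "v000",
     "target_branch_id": "v012",
     "segments": [{"id": ..., "parent": ..., "length_m": ..., "radius_m": ...,
                   "label": ...}, ...]}

Depth levels are derived, never stored. A CSV edge-list alternative
(``child_id,parent_id,length_m,radius_m,label`` plus ``#key=value`` metadata
comment lines) round-trips the same information. Floats are serialized with
``repr`` so write-then-read is lossless to full double precision.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path

import pandas as pd

from .errors import TreeValidationError
from .tree import FluidProperties, VascularTree, VesselSegment

__all__ = ["read_tree", "write_tree", "read_tree_json", "tree_to_json",
           "solution_to_frame", "eei_map_to_frame"]

_SCHEMA_VERSION = 1


def tree_to_json(tree: VascularTree) -> str:
    """Serialize a tree to the canonical JSON text (deterministic bytes)."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "fluid": {"density": tree.fluid.density, "viscosity": tree.fluid.viscosity},
        "inlet_id": tree.inlet_id,
        "target_branch_id": tree.target_branch_id,
        "segments": [
            {
                "id": s.segment_id,
                "parent": s.parent_id,
                "length_m": s.length,
                "radius_m": s.radius,
                "label": s.label,
            }
            for s in tree
        ],
    }
    return json.dumps(doc, indent=1) + "\n"


def read_tree_json(text: str) -> VascularTree:
    """Parse the canonical JSON format; all invariants are re-validated."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise TreeValidationError(f"malformed tree JSON: {e}") from e
    for key in ("fluid", "target_branch_id", "segments"):
        if key not in doc:
            raise TreeValidationError(f"tree JSON missing required key {key!r}")
    fluid = FluidProperties(
        density=doc["fluid"]["density"], viscosity=doc["fluid"]["viscosity"]
    )
    segments = []
    for rec in doc["segments"]:
        for key in ("id", "parent", "length_m", "radius_m"):
            if key not in rec:
                raise TreeValidationError(
                    f"segment record {rec.get('id', '<unnamed>')!r} missing "
                    f"required field {key!r}"
                )
        segments.append(
            VesselSegment(
                segment_id=rec["id"],
                parent_id=rec["parent"],
                length=rec["length_m"],
                radius=rec["radius_m"],
                label=rec.get("label"),
            )
        )
    return VascularTree(segments, doc["target_branch_id"], fluid)


def _tree_to_csv(tree: VascularTree) -> str:
    buf = _io.StringIO()
    buf.write("#schema=emboflow-edgelist-v1\n")
    buf.write(f"#fluid_density={tree.fluid.density!r}\n")
    buf.write(f"#fluid_viscosity={tree.fluid.viscosity!r}\n")
    buf.write(f"#target_branch_id={tree.target_branch_id}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["child_id", "parent_id", "length_m", "radius_m", "label"])
    for s in tree:
        w.writerow(
            [s.segment_id, s.parent_id or "", repr(s.length), repr(s.radius),
             s.label or ""]
        )
    return buf.getvalue()


def _tree_from_csv(text: str) -> VascularTree:
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key] = val
        elif line.strip():
            rows.append(line)
    if not rows:
        raise TreeValidationError("edge-list CSV has no data rows")
    reader = csv.DictReader(rows)
    segments = []
    for rec in reader:
        if rec.get("radius_m") in (None, ""):
            raise TreeValidationError(
                f"segment {rec.get('child_id')!r}: missing radius_m"
            )
        segments.append(
            VesselSegment(
                segment_id=rec["child_id"],
                parent_id=rec["parent_id"] or None,
                length=float(rec["length_m"]),
                radius=float(rec["radius_m"]),
                label=rec.get("label") or None,
            )
        )
    target = meta.get("target_branch_id")
    if target is None:
        raise TreeValidationError("edge-list CSV missing #target_branch_id metadata")
    fluid = FluidProperties(
        density=float(meta.get("fluid_density", 1060.0)),
        viscosity=float(meta.get("fluid_viscosity", 0.0035)),
    )
    return VascularTree(segments, target, fluid)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "json"


def write_tree(tree: VascularTree, path, format: str | None = None) -> Path:
    """Write a tree to ``path`` as JSON (default) or CSV edge-list."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(tree_to_json(tree))
    elif fmt == "csv":
        path.write_text(_tree_to_csv(tree))
    else:
        raise ValueError(f"unknown tree format {fmt!r}")
    return path


def read_tree(path, format: str | None = None) -> VascularTree:
    """Read a tree from JSON or CSV edge-list; invariants are re-validated."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        return read_tree_json(text)
    if fmt == "csv":
        return _tree_from_csv(text)
    raise ValueError(f"unknown tree format {fmt!r}")


def solution_to_frame(solution, tree: VascularTree) -> pd.DataFrame:
    """Tidy per-segment table of one flow solution.

    Columns: time, segment_id, flow_cm3s, pressure_Pa_upstream,
    velocity_m_s, reynolds.
    """
    rows = []
    for sid, seg in tree.segments.items():
        up = seg.parent_id if seg.parent_id is not None else "inlet"
        rows.append(
            {
                "time": solution.time,
                "segment_id": sid,
                "flow_cm3s": solution.segment_flows[sid] * 1e6,
                "pressure_Pa_upstream": solution.node_pressures[up],
                "velocity_m_s": solution.segment_velocities[sid],
                "reynolds": solution.segment_reynolds[sid],
            }
        )
    return pd.DataFrame(rows)


def eei_map_to_frame(eei_map, condition_id: str = "") -> pd.DataFrame:
    """EEI map as a table: segment_id, eei_percent, defined_flag, condition_id."""
    rows = [
        {"segment_id": sid, "eei_percent": val, "defined_flag": True,
         "condition_id": condition_id}
        for sid, val in eei_map.values.items()
    ]
    rows += [
        {"segment_id": sid, "eei_percent": float("nan"), "defined_flag": False,
         "condition_id": condition_id}
        for sid in sorted(eei_map.undefined)
    ]
    return pd.DataFrame(rows).sort_values("segment_id", ignore_index=True)
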