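"""File formats: keypoint-trajectory CSV, legacy VTK meshes, case/result JSON.

CSV dialect: comma-separated, header row, UTF-8, ``\\n`` line endings, full
float precision (repr), '.' decimal point, no thousands separators.
Metadata rides in ``#``-prefixed comment lines above the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from softinverse.mesh import Mesh

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_vtk",
    "write_history_csv",
    "write_result_json",
    "read_result_json",
]


def write_tracks_csv(path, D: np.ndarray, node_ids=None, meta: dict | None = None):
    """Write a keypoint trajectory array (steps, keypoints, 3) as CSV.

    Columns: step, node_id, ux, uy, uz; one row per (step, keypoint).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 3 or D.shape[2] != 3:
        raise ValueError("trajectory array must be (steps, keypoints, 3)")
    steps, nk, _ = D.shape
    if node_ids is None:
        node_ids = np.arange(nk)
    node_ids = np.asarray(node_ids, dtype=np.int64)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("step,node_id,ux,uy,uz\n")
        for s in range(steps):
            for k in range(nk):
                ux, uy, uz = (float(v) for v in D[s, k])
                fh.write(f"{s},{node_ids[k]},{ux!r},{uy!r},{uz!r}\n")


def read_tracks_csv(path) -> tuple[np.ndarray, dict]:
    """Read a trajectory CSV back into ((steps, keypoints, 3), metadata)."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    steps = df["step"].nunique()
    order = df["node_id"].unique()
    nk = len(order)
    D = np.empty((steps, nk, 3))
    pos = {nid: j for j, nid in enumerate(order)}
    for (s, nid), grp in df.groupby(["step", "node_id"], sort=False):
        D[int(s), pos[nid]] = grp[["ux", "uy", "uz"]].to_numpy()[0]
    return D, meta


def write_vtk(mesh: Mesh, path, point_data: dict | None = None):
    """Legacy ASCII VTK unstructured grid with the element `region` labels."""
    cell_type = 12 if mesh.element_type == "hex8" else 5  # VTK_HEXAHEDRON / TRIANGLE
    npe = mesh.elements.shape[1]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# vtk DataFile Version 3.0\nsoftinverse mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for pt in mesh.nodes:
            x, y, z = (float(v) for v in pt)
            fh.write(f"{x!r} {y!r} {z!r}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (npe + 1)}\n")
        for conn in mesh.elements:
            fh.write(f"{npe} " + " ".join(str(c) for c in conn) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        for _ in range(mesh.n_elements):
            fh.write(f"{cell_type}\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        for r in mesh.region:
            fh.write(f"{int(r)}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"VECTORS {name} double\n")
                for row in arr:
                    a, b, c = (float(v) for v in row)
                    fh.write(f"{a!r} {b!r} {c!r}\n")


def write_history_csv(path, history, node_ids=None):
    """Full displacement history as CSV (step, node_id, ux, uy, uz)."""
    u = history.displacements
    ids = np.arange(u.shape[1]) if node_ids is None else np.asarray(node_ids)
    write_tracks_csv(path, u[:, ids, :], node_ids=ids)


def write_result_json(path, result) -> None:
    """Persist a RecoveryResult (estimates, errors, compact history)."""
    payload = {
        "case": result.case_name,
        "preset": result.preset,
        "estimates": {k: float(v) for k, v in result.estimates.items()},
        "errors": {k: float(v) for k, v in result.errors.items()},
        "derived": {k: float(v) for k, v in result.derived.items()},
        "final_loss": float(result.final_loss),
        "n_evaluations": int(len(result.history.losses)),
        "best_so_far": [float(v) for v in result.history.best_so_far],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_result_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_case_json(path, case) -> None:
    """Serialize a CaseDefinition (geometry presets, truth, bounds) as JSON."""
    payload = {
        "name": case.name,
        "body": case.body,
        "description": case.description,
        "truth": {k: float(v) for k, v in case.truth.items()},
        "unknowns": list(case.unknowns),
        "bounds": {
            k: [float(d.lower), float(d.upper), d.encoding]
            for k, d in case.bounds.items()
        },
        "presets": {
            p: {k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in cfg.items()}
            for p, cfg in case.presets.items()
        },
        "homogeneous": bool(case.homogeneous),
        "truth_model": case.truth_model,
        "inverse_model": case.inverse_model,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_case_json(path):
    """Load a CaseDefinition from a JSON case configuration."""
    from softinverse.bayesopt import Dimension
    from softinverse.cases import CaseDefinition

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        presets = {
            p: {k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.items()}
            for p, cfg in payload["presets"].items()
        }
        return CaseDefinition(
            name=payload["name"],
            body=payload["body"],
            description=payload.get("description", ""),
            truth=payload["truth"],
            unknowns=payload["unknowns"],
            bounds={
                k: Dimension(k, lo, hi, enc)
                for k, (lo, hi, enc) in payload["bounds"].items()
            },
            presets=presets,
            homogeneous=payload.get("homogeneous", False),
            truth_model=payload.get("truth_model", "neo_hookean"),
            inverse_model=payload.get("inverse_model", "neo_hookean"),
        )
    except KeyError as e:
        raise ValueError(f"case config is missing required field {e}") from None
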