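"""Delimited-text grid files, model/report JSON, mesh export.

Grid files are plain TSV with two header lines carrying the coordinate
vectors, chosen over binary for diffability::

    # lastfit-grid units=mm
    # x<TAB>20 25 ...
    # y<TAB>10 14.5 ...
    z[0,0]<TAB>z[0,1] ...

One text row per x index; values at full (repr) precision so a write/read
round trip is bit-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .adjust import AdjustmentReport
from .bezier import BezierPatchModel
from .grid import SurfaceGrid

MAGIC = "# lastfit-grid"


class GridParseError(ValueError):
    """Malformed grid file; carries the offending line number."""


def write_grid(path, grid: SurfaceGrid) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{MAGIC} units=mm\n")
        fh.write("# x\t" + "\t".join(repr(float(v)) for v in grid.x_coords) + "\n")
        fh.write("# y\t" + "\t".join(repr(float(v)) for v in grid.y_coords) + "\n")
        for row in grid.heights:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_grid(path) -> SurfaceGrid:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(MAGIC):
        raise GridParseError(f"{path}:1: missing '{MAGIC}' header")
    coords = {}
    data_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if line.startswith("# "):
            parts = line[2:].split("\t")
            if parts[0] in ("x", "y"):
                try:
                    coords[parts[0]] = np.array([float(v) for v in parts[1:]])
                except ValueError as e:
                    raise GridParseError(f"{path}:{ln}: bad coordinate value ({e})") from e
        else:
            data_start = ln
            break
    if "x" not in coords or "y" not in coords:
        raise GridParseError(f"{path}: missing x/y coordinate header lines")
    if data_start is None:
        raise GridParseError(f"{path}: no height rows")
    rows = []
    width = None
    for ln, line in enumerate(lines[data_start - 1 :], start=data_start):
        if not line.strip():
            continue
        vals = line.split("\t")
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise GridParseError(f"{path}:{ln}: ragged row ({len(vals)} cells, expected {width})")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as e:
            raise GridParseError(f"{path}:{ln}: non-numeric cell ({e})") from e
    return SurfaceGrid(np.array(rows), coords["x"], coords["y"])


# ---------------------------------------------------------------------------
# mesh export


def export_mesh(grid: SurfaceGrid, path, fmt: str | None = None):
    """Triangulated lattice mesh (PLY or OBJ), mm units.

    Vertex count is n*m and face count 2(n-1)(m-1).  Returns the trimesh
    object for inspection.
    """
    import trimesh

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise ValueError(f"unsupported mesh format {fmt!r}; use 'ply' or 'obj'")
    nx, ny = grid.shape
    xx, yy = np.meshgrid(grid.x_coords, grid.y_coords, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), grid.heights.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + 1
            c = a + ny
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    mesh.export(path, file_type=fmt)
    return mesh


# ---------------------------------------------------------------------------
# model / report serialization


def write_model(path, model: BezierPatchModel) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "patch_layout": list(model.patch_layout),
                "x_coords": model.source_grid.x_coords.tolist(),
                "y_coords": model.source_grid.y_coords.tolist(),
                "source_heights": model.source_grid.heights.tolist(),
                "weights": model.weights.tolist(),
                "control_points": model.control_points.tolist(),
            },
            fh,
        )


def read_model(path) -> BezierPatchModel:
    with open(path) as fh:
        d = json.load(fh)
    grid = SurfaceGrid(
        np.array(d["source_heights"]), np.array(d["x_coords"]), np.array(d["y_coords"])
    )
    return BezierPatchModel(grid, np.array(d["weights"]))


def write_report(path, report: AdjustmentReport, extra: dict | None = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_history_csv(path, history: list[dict]) -> None:
    if not history:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
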