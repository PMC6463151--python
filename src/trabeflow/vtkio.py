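"""Legacy ASCII VTK output for external viewers (VisIt / ParaView).

Only the two structures this package produces are supported: scalar fields
on the uniform periodic grid (STRUCTURED_POINTS) and boundary polylines
(POLYDATA).  The legacy ASCII format is written directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ib_solver import FluidGrid

__all__ = ["write_fields_vtk", "write_polyline_vtk"]


def write_fields_vtk(path: str | Path, grid: FluidGrid, fields: dict[str, np.ndarray]) -> None:
    """Write named scalar fields (shape (nx, ny)) as a legacy VTK file."""
    nx, ny = grid.nx, grid.ny
    lines = [
        "# vtk DataFile Version 3.0",
        "trabeflow fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {grid.h:.10g} {grid.h:.10g} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, f in fields.items():
        if f.shape != (nx, ny):
            raise ValueError(f"field {name!r} has shape {f.shape}, expected {(nx, ny)}")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK iterates x fastest: for each j, all i
        vals = f.T.ravel()
        lines.extend(" ".join(f"{v:.7g}" for v in vals[k : k + 9]) for k in range(0, len(vals), 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_polyline_vtk(path: str | Path, points: np.ndarray, component: np.ndarray) -> None:
    """Write boundary polylines (one per component id) as VTK POLYDATA."""
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        "trabeflow boundary",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines.extend(f"{x:.10g} {y:.10g} 0" for x, y in points)
    comps = [np.flatnonzero(component == c) for c in np.unique(component)]
    total = sum(len(c) + 1 for c in comps)
    lines.append(f"LINES {len(comps)} {total + len(comps)}")
    for idx in comps:
        closed = list(idx) + [idx[0]]
        lines.append(f"{len(closed)} " + " ".join(str(i) for i in closed))
    Path(path).write_text("\n".join(lines) + "\n")
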