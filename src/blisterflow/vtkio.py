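"""Legacy-VTK structured-points output of voxel flow solutions."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .flow_solver import FlowField


def write_vtk_structured_points(path, field: FlowField) -> Path:
    """Write velocity, kinematic pressure and cell labels as ASCII VTK.

    The file uses the ``STRUCTURED_POINTS`` dataset with one point per
    grid cell centre, loadable by ParaView and friends.
    """
    grid = field.grid
    nx, ny, nz = grid.shape
    h = grid.spacing
    vel = field.cell_velocity()
    p = np.where(grid.fluid, field.p, 0.0)
    labels = grid.fluid.astype(np.int8)

    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("blisterflow steady flow solution\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = grid.origin + 0.5 * h
        f.write(f"ORIGIN {o[0]:.9g} {o[1]:.9g} {o[2]:.9g}\n")
        f.write(f"SPACING {h:.9g} {h:.9g} {h:.9g}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")

        f.write("SCALARS pressure_kinematic float 1\nLOOKUP_TABLE default\n")
        _write_values(f, p.transpose(2, 1, 0).ravel())
        f.write("SCALARS cell_label int 1\nLOOKUP_TABLE default\n")
        _write_values(f, labels.transpose(2, 1, 0).ravel(), fmt="%d")
        f.write("VECTORS velocity float\n")
        flat = vel.transpose(2, 1, 0, 3).reshape(-1, 3)
        for row in flat:
            f.write(f"{row[0]:.7g} {row[1]:.7g} {row[2]:.7g}\n")
    return path


def _write_values(f, values, fmt: str = "%.7g", per_line: int = 9) -> None:
    vals = np.asarray(values)
    for i in range(0, len(vals), per_line):
        f.write(" ".join(fmt % v for v in vals[i : i + per_line]) + "\n")
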