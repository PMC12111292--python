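"""Legacy-ASCII VTK export of grid fields.

Writes STRUCTURED_POINTS datasets (cell data on the uniform voxel grid)
readable by ParaView/VisIt.  The writer is deliberately minimal: one
file, any number of scalar cell fields.
"""

from __future__ import annotations

import os

import numpy as np

from .geometry import DomainGrid

__all__ = ["write_vtk"]


def write_vtk(
    path: str | os.PathLike,
    grid: DomainGrid,
    fields: dict[str, np.ndarray],
    title: str = "rdnsim fields",
) -> None:
    """Write scalar cell fields on ``grid`` to a legacy VTK file."""
    nx, ny, nz = grid.shape
    h = grid.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        # point dims = cell dims + 1 so fields attach as CELL_DATA
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {grid.n_cells}",
    ]
    for name, data in fields.items():
        arr = np.asarray(data)
        if arr.shape != grid.shape:
            raise ValueError(
                f"field {name!r} shape {arr.shape} != grid {grid.shape}"
            )
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x varying fastest: transpose to (z, y, x) C-order
        flat = arr.transpose(2, 1, 0).ravel()
        lines.extend(
            " ".join(f"{v:.6g}" for v in flat[i : i + 6])
            for i in range(0, flat.size, 6)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
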