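"""Minimal legacy-VTK (ASCII STRUCTURED_POINTS) writer/reader for voxel fields.

Writes per-voxel (CELL_DATA) scalar fields on a regular grid so results can be
inspected in ParaView.  The reader exists mainly to guarantee lossless
round-trips of integer label fields in tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_structured_points", "read_structured_points"]


def write_structured_points(
    path,
    cell_fields: dict[str, np.ndarray],
    spacing: float,
    origin=(0.0, 0.0, 0.0),
) -> None:
    """Write scalar per-voxel fields to a legacy VTK file.

    ``cell_fields`` maps field name -> (nx, ny, nz) array; all fields must
    share one shape.  Integer arrays are written as ``int``, everything else
    as ``double`` with full precision.
    """
    if not cell_fields:
        raise ValueError("no fields to write")
    shapes = {f.shape for f in cell_fields.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent field shapes: {shapes}")
    (nx, ny, nz) = shapes.pop()

    lines = [
        "# vtk DataFile Version 3.0",
        "scaffopt voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}",
        f"SPACING {spacing:.17g} {spacing:.17g} {spacing:.17g}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in cell_fields.items():
        if np.issubdtype(arr.dtype, np.integer):
            vtype, fmt = "int", "%d"
        else:
            vtype, fmt = "double", "%.17g"
        lines.append(f"SCALARS {name} {vtype} 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest, then y, then z
        flat = np.asarray(arr).transpose(2, 1, 0).ravel()
        lines.extend(fmt % v for v in flat)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_structured_points(path) -> dict[str, np.ndarray]:
    """Read back scalar CELL_DATA fields written by ``write_structured_points``.

    Returns a dict of field name -> (nx, ny, nz) array (ints as int64,
    doubles as float64).
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    dims = None
    ncells = None
    fields: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(x) - 1 for x in line.split()[1:4])
        elif line.startswith("CELL_DATA"):
            ncells = int(line.split()[1])
        elif line.startswith("SCALARS"):
            _, name, vtype = line.split()[:3]
            assert ncells is not None and dims is not None
            dtype = np.int64 if vtype == "int" else np.float64
            vals = np.array(tokens[i + 2 : i + 2 + ncells], dtype=dtype)
            nx, ny, nz = dims
            fields[name] = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
            i += 1 + ncells
        i += 1
    return fields
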