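"""Minimal legacy-VTK (ASCII) writer/reader for triangle meshes with fields.

The legacy unstructured-grid format is plain text and fully sufficient for
the snapshot/mesh exchange needs of this package (ParaView and meshio both
read it).  Point data and cell data are written as scalar fields.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk", "read_vtk"]


def write_vtk(path, points, triangles, point_data=None, cell_data=None, comment="scarsim output"):
    """Write a 2D triangulation with optional scalar fields (legacy VTK ASCII)."""
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    n, m = len(points), len(triangles)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{comment}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for p in points:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} 0\n")
        fh.write(f"CELLS {m} {4 * m}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("5\n" * m)
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, vals in point_data.items():
                _write_scalars(fh, name, np.asarray(vals, dtype=float))
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, vals in cell_data.items():
                _write_scalars(fh, name, np.asarray(vals, dtype=float))


def _write_scalars(fh, name, vals):
    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    for v in vals:
        fh.write(f"{v:.17g}\n")


def read_vtk(path):
    """Read points, triangles and scalar fields back from a legacy VTK file.

    Returns ``(points, triangles, point_data, cell_data)``; only the subset
    of the format produced by :func:`write_vtk` is supported.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    points = triangles = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    target = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            arr = [tokens[i + 1 + k].split() for k in range(n)]
            points = np.array(arr, dtype=float)[:, :2]
            i += n
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            arr = [tokens[i + 1 + k].split()[1:] for k in range(m)]
            triangles = np.array(arr, dtype=int)
            i += m
        elif line.startswith("POINT_DATA"):
            target = point_data
        elif line.startswith("CELL_DATA"):
            target = cell_data
        elif line.startswith("SCALARS") and target is not None:
            name = line.split()[1]
            count = len(points) if target is point_data else len(triangles)
            vals = [float(tokens[i + 2 + k]) for k in range(count)]
            target[name] = np.array(vals)
            i += count + 1
        i += 1
    return points, triangles, point_data, cell_data
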