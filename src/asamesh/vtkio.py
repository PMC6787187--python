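"""Minimal VTK legacy ASCII reader/writer for triangle meshes.

Only the subset the package emits is supported: an unstructured grid of
triangles with optional point vectors and cell scalars.  Values are printed
with 17 significant digits so a write/read round trip reproduces the arrays
bit for bit.
"""

from __future__ import annotations

import numpy as np

_FMT = "%.17g"


def write_vtk(path, nodes: np.ndarray, triangles: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None,
              comment: str = "asamesh mesh") -> None:
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    lines = ["# vtk DataFile Version 3.0", comment[:255], "ASCII",
             "DATASET UNSTRUCTURED_GRID"]
    lines.append(f"POINTS {len(nodes)} double")
    for p in nodes:
        z = p[2] if len(p) > 2 else 0.0
        lines.append(f"{_FMT % p[0]} {_FMT % p[1]} {_FMT % z}")
    lines.append(f"CELLS {len(triangles)} {4 * len(triangles)}")
    for t in triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {len(triangles)}")
    lines.extend(["5"] * len(triangles))
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} double")
                for v in arr:
                    z = v[2] if arr.shape[1] > 2 else 0.0
                    lines.append(f"{_FMT % v[0]} {_FMT % v[1]} {_FMT % z}")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(_FMT % v for v in arr)
    if cell_data:
        lines.append(f"CELL_DATA {len(triangles)}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(_FMT % v for v in arr)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a file written by :func:`write_vtk`.

    Returns (nodes, triangles, point_data, cell_data); vector point data is
    returned as (n, 2) arrays (the z component written as 0 is dropped).
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def next_line():
        nonlocal i
        line = tokens[i]
        i += 1
        return line

    header = [next_line() for _ in range(4)]
    if "UNSTRUCTURED_GRID" not in header[3]:
        raise ValueError("not an unstructured-grid VTK file")
    n_pts = int(next_line().split()[1])
    nodes = np.array([[float(x) for x in next_line().split()] for _ in range(n_pts)])
    n_cells = int(next_line().split()[1])
    triangles = np.array([[int(x) for x in next_line().split()[1:]] for _ in range(n_cells)])
    for _ in range(1 + n_cells):  # CELL_TYPES block
        next_line()
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    current, count = None, 0
    while i < len(tokens):
        line = next_line().strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "POINT_DATA":
            current, count = point_data, int(parts[1])
        elif parts[0] == "CELL_DATA":
            current, count = cell_data, int(parts[1])
        elif parts[0] == "VECTORS":
            arr = np.array([[float(x) for x in next_line().split()] for _ in range(count)])
            current[parts[1]] = arr[:, :2]
        elif parts[0] == "SCALARS":
            next_line()  # LOOKUP_TABLE
            current[parts[1]] = np.array([float(next_line()) for _ in range(count)])
    return nodes[:, :2], triangles, point_data, cell_data
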