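"""Minimal legacy-VTK ASCII writers for visualization output.

Writes fiber axes as polylines (diameter as point data) and the host hex
grid with nodal/cell fields.  Legacy VTK is a plain line-oriented text
format; these writers cover exactly what the package exports.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_fiber_polydata", "write_hex_grid"]


def write_fiber_polydata(path, geometry) -> None:
    """Fiber axis segments of an RveGeometry as VTK polylines."""
    points, lines, diam = [], [], []
    for f in geometry.fibers:
        for a, b in f.segments:
            i = len(points)
            points.extend([a, b])
            lines.append((i, i + 1))
            diam.extend([f.diameter, f.diameter])
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfiber axes\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
        for a, b in lines:
            fh.write(f"2 {a} {b}\n")
        fh.write(f"POINT_DATA {len(points)}\nSCALARS diameter_um float 1\nLOOKUP_TABLE default\n")
        for d in diam:
            fh.write(f"{d:.8g}\n")


def write_hex_grid(path, mesh, point_data=None, cell_data=None) -> None:
    """HexMesh (+ optional nodal vectors / cell scalars) as unstructured grid."""
    nodes, elems = mesh.nodes, mesh.elems
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhost mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} float\n")
        for p in nodes:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        fh.write(f"CELLS {len(elems)} {9 * len(elems)}\n")
        for e in elems:
            fh.write("8 " + " ".join(str(int(i)) for i in e) + "\n")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        fh.write("\n".join(["12"] * len(elems)) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} float\n")
                    for v in arr:
                        fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{float(v):.8g}\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(elems)}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr):
                    fh.write(f"{float(v):.8g}\n")
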