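"""Plain-text mesh export: legacy ASCII VTK, OBJ and STL writers."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_unstructured", "write_vtk_polydata", "write_obj",
           "write_stl_ascii"]


def _write_points(fh, points):
    fh.write(f"POINTS {len(points)} double\n")
    for p in np.asarray(points, float):
        fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def write_vtk_unstructured(path, points, tets, cell_data=None, point_data=None):
    """Legacy ASCII VTK unstructured grid of tetrahedra.

    ``cell_data`` / ``point_data`` map field names to scalar arrays (cell
    vectors of shape (n, 3) are written as VECTORS).
    """
    tets = np.asarray(tets, int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlamsim output\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        _write_points(fh, points)
        fh.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        for t in tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {len(tets)}\n")
        fh.write("10\n" * len(tets))
        for tag, data, count in (("CELL_DATA", cell_data, len(tets)),
                                 ("POINT_DATA", point_data, len(points))):
            if not data:
                continue
            fh.write(f"{tag} {count}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    kind = "int" if arr.dtype.kind in "iu" else "double"
                    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{v:.9g}\n" if kind == "double" else f"{int(v)}\n")


def write_vtk_polydata(path, points, faces):
    """Legacy ASCII VTK triangle polydata (rigid surfaces)."""
    faces = np.asarray(faces, int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlamsim surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        _write_points(fh, points)
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_obj(path, points, faces):
    with open(path, "w") as fh:
        for p in np.asarray(points, float):
            fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for f in np.asarray(faces, int) + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def write_stl_ascii(path, points, faces, name="lamsim"):
    points = np.asarray(points, float)
    faces = np.asarray(faces, int)
    tri = points[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for tr, nn in zip(tri, n):
            fh.write(f"facet normal {nn[0]:.9g} {nn[1]:.9g} {nn[2]:.9g}\n")
            fh.write("  outer loop\n")
            for v in tr:
                fh.write(f"    vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write("  endloop\nendfacet\n")
        fh.write(f"endsolid {name}\n")
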