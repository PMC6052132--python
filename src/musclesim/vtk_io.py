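"""Legacy ASCII VTK writers for meshes, fibers and fields.

Writes VTK DataFile 2.0 unstructured grids: hexahedra for the 3D mesh
(with optional per-cell owner/scalar data) and polylines for the
fibers (with optional per-point scalars such as V_m or γ).  Plain
text, loadable in ParaView and other standard viewers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import MultiScaleGeometry

__all__ = ["write_hex_mesh", "write_fiber_polylines"]

# Q1 lexicographic corner order -> VTK hexahedron order
_VTK_HEX_ORDER = [0, 1, 3, 2, 4, 5, 7, 6]


def _header(f, title: str, points: np.ndarray) -> None:
    f.write("# vtk DataFile Version 2.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    f.write(f"POINTS {len(points)} double\n")
    for p in points:
        f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def _scalars(f, name: str, values: np.ndarray) -> None:
    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    for v in np.asarray(values, dtype=float).ravel():
        f.write(f"{v:.17g}\n")


def write_hex_mesh(
    path: str | Path,
    geom: MultiScaleGeometry,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    point_displacement: np.ndarray | None = None,
) -> Path:
    """Write the 3D hexahedral mesh (Q1 corner nodes) as legacy VTK.

    ``point_displacement`` (n_q1, 3), if given, is written as a VECTORS
    field on the points.  Cell/point data dicts map field name to a
    flat array over cells/points.
    """
    path = Path(path)
    ex, ey, ez = geom.elements3d
    nx, ny = ex + 1, ey + 1
    with open(path, "w") as f:
        _header(f, "musclesim 3D mesh", geom.q1_nodes)
        n_cells = geom.n_elements_3d
        f.write(f"CELLS {n_cells} {n_cells * 9}\n")
        for e in range(n_cells):
            i, j, k = geom.element_multi_index(e)
            corners = [
                (i + a) + nx * ((j + b) + ny * (k + c))
                for c in range(2) for b in range(2) for a in range(2)
            ]
            ordered = [corners[o] for o in _VTK_HEX_ORDER]
            f.write("8 " + " ".join(str(c) for c in ordered) + "\n")
        f.write(f"CELL_TYPES {n_cells}\n")
        f.write("12\n" * n_cells)
        if cell_data:
            f.write(f"CELL_DATA {n_cells}\n")
            for name, values in cell_data.items():
                _scalars(f, name, values)
        if point_data or point_displacement is not None:
            f.write(f"POINT_DATA {len(geom.q1_nodes)}\n")
            if point_displacement is not None:
                f.write("VECTORS displacement double\n")
                for v in point_displacement:
                    f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for name, values in (point_data or {}).items():
                _scalars(f, name, values)
    return path


def write_fiber_polylines(
    path: str | Path,
    geom: MultiScaleGeometry,
    positions: np.ndarray | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the fibers as VTK polylines with optional per-node scalars.

    ``positions`` (n_sarcomere_points, 3) defaults to the reference
    fiber node coordinates.
    """
    path = Path(path)
    n = geom.n_sarcomere_points
    npf = geom.nodes_per_fiber
    pts = (
        geom.fiber_nodes.reshape(n, 3)
        if positions is None
        else np.asarray(positions, dtype=float).reshape(n, 3)
    )
    with open(path, "w") as f:
        _header(f, "musclesim fibers", pts)
        nf = geom.n_fibers
        f.write(f"CELLS {nf} {nf * (npf + 1)}\n")
        for fid in range(nf):
            ids = range(fid * npf, (fid + 1) * npf)
            f.write(f"{npf} " + " ".join(str(i) for i in ids) + "\n")
        f.write(f"CELL_TYPES {nf}\n")
        f.write("4\n" * nf)
        if point_data:
            f.write(f"POINT_DATA {n}\n")
            for name, values in point_data.items():
                _scalars(f, name, values)
    return path
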