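"""Cube muscle geometry with embedded 1D fiber meshes.

The 3D muscle domain is a box discretized into ``e_x × e_y × e_z``
hexahedral elements carrying tri-quadratic (Q2) displacement nodes and
tri-linear (Q1) pressure nodes.  Muscle fibers are straight 1D meshes
aligned with one coordinate axis; each 3D element contains ``f1 × f2``
fibers in its cross-section and ``epf`` 1D elements of each of them, so
every 3D element holds exactly ``f1·f2·epf`` fiber elements.  Each 1D
node is a sarcomere position where one instance of the subcellular model
lives.

Orderings are 0-based and lexicographic with x fastest.  Fibers are
placed at transverse offsets ``(i + 0.5)/f`` of the element width so no
fiber ever lies on an element boundary, which keeps element ownership of
fiber nodes unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiScaleGeometry",
    "EntityCounts",
    "build_cube_geometry",
    "fiber_elements_in_3d_element",
    "count_entities",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class EntityCounts:
    """Structural entity counts of a multi-scale geometry."""

    elements_3d: int
    fibers: int
    elements_1d: int
    sarcomere_points: int


@dataclass
class MultiScaleGeometry:
    """3D hexahedral mesh with embedded 1D fiber meshes.

    Attributes
    ----------
    extent:
        Physical size of the box per axis in cm.
    elements3d:
        ``(e_x, e_y, e_z)`` hexahedral element counts.
    fiber_axis:
        Axis index (0, 1, 2) the fibers run along.
    fibers_per_cross_section_element:
        ``(f1, f2)`` fibers per 3D element along the two transverse axes
        (in ascending axis order).
    elements_per_fiber_per_3d_element:
        Number of 1D elements of one fiber inside one 3D element.
    q2_nodes, q1_nodes:
        Node coordinate arrays, shape ``(n, 3)``, lexicographic with x
        fastest.
    fiber_nodes:
        Array of shape ``(n_fibers, nodes_per_fiber, 3)`` with 1D node
        coordinates; fibers ordered lexicographically in their
        transverse integer coordinates (first transverse axis fastest).
    """

    extent: tuple[float, float, float]
    elements3d: tuple[int, int, int]
    fiber_axis: int
    fibers_per_cross_section_element: tuple[int, int]
    elements_per_fiber_per_3d_element: int
    q2_nodes: np.ndarray = field(repr=False)
    q1_nodes: np.ndarray = field(repr=False)
    fiber_nodes: np.ndarray = field(repr=False)

    # ---- derived sizes -------------------------------------------------
    @property
    def transverse_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.fiber_axis)  # type: ignore[return-value]

    @property
    def n_elements_3d(self) -> int:
        ex, ey, ez = self.elements3d
        return ex * ey * ez

    @property
    def n_fibers(self) -> int:
        t1, t2 = self.transverse_axes
        f1, f2 = self.fibers_per_cross_section_element
        return (f1 * self.elements3d[t1]) * (f2 * self.elements3d[t2])

    @property
    def elements_per_fiber(self) -> int:
        return (
            self.elements_per_fiber_per_3d_element
            * self.elements3d[self.fiber_axis]
        )

    @property
    def nodes_per_fiber(self) -> int:
        return self.elements_per_fiber + 1

    @property
    def n_elements_1d(self) -> int:
        return self.n_fibers * self.elements_per_fiber

    @property
    def n_sarcomere_points(self) -> int:
        return self.n_fibers * self.nodes_per_fiber

    @property
    def element_size(self) -> tuple[float, float, float]:
        return tuple(L / e for L, e in zip(self.extent, self.elements3d))  # type: ignore[return-value]

    # ---- index arithmetic ----------------------------------------------
    def element_index(self, i: int, j: int, k: int) -> int:
        ex, ey, _ = self.elements3d
        return i + ex * (j + ey * k)

    def element_multi_index(self, e: int) -> tuple[int, int, int]:
        ex, ey, ez = self.elements3d
        if not (0 <= e < ex * ey * ez):
            raise IndexError(f"3D element index {e} out of range")
        i = e % ex
        j = (e // ex) % ey
        k = e // (ex * ey)
        return i, j, k

    def fiber_index(self, it1: int, it2: int) -> int:
        """Global fiber id from transverse fiber-lattice coordinates."""
        t1, _ = self.transverse_axes
        f1, _ = self.fibers_per_cross_section_element
        n1 = f1 * self.elements3d[t1]
        return it1 + n1 * it2

    def fiber_multi_index(self, fiber_id: int) -> tuple[int, int]:
        t1, _ = self.transverse_axes
        f1, _ = self.fibers_per_cross_section_element
        n1 = f1 * self.elements3d[t1]
        return fiber_id % n1, fiber_id // n1

    def global_1d_element(self, fiber_id: int, local_el: int) -> int:
        return fiber_id * self.elements_per_fiber + local_el

    def owning_element_of_1d_node(self, fiber_id: int, node: int) -> int:
        """3D element that owns a fiber node (half-open convention).

        Nodes on shared faces normal to the fiber axis belong to the
        lower-index element; transverse ownership is unambiguous because
        fibers never sit on element boundaries.
        """
        it1, it2 = self.fiber_multi_index(fiber_id)
        f1, f2 = self.fibers_per_cross_section_element
        epf = self.elements_per_fiber_per_3d_element
        idx = [0, 0, 0]
        t1, t2 = self.transverse_axes
        idx[t1] = it1 // f1
        idx[t2] = it2 // f2
        ia = min(node // epf, self.elements3d[self.fiber_axis] - 1)
        # end node of the last element stays with the last element
        if node == self.elements_per_fiber:
            ia = self.elements3d[self.fiber_axis] - 1
        idx[self.fiber_axis] = ia
        return self.element_index(*idx)

    def counts(self) -> EntityCounts:
        return EntityCounts(
            elements_3d=self.n_elements_3d,
            fibers=self.n_fibers,
            elements_1d=self.n_elements_1d,
            sarcomere_points=self.n_sarcomere_points,
        )


def build_cube_geometry(
    extent: tuple[float, float, float] = (1.0, 1.0, 1.0),
    elements3d: tuple[int, int, int] = (1, 1, 1),
    fiber_axis: str | int = "x",
    fibers_per_cross_section_element: tuple[int, int] = (2, 2),
    elements_per_fiber_per_3d_element: int = 3,
) -> MultiScaleGeometry:
    """Build a box muscle geometry with embedded, axis-aligned fibers.

    Parameters mirror the structured test scenario: a generic cubic
    muscle of 1 × 1 × 1 cm with fibers parallel to one cube edge,
    ``(f1, f2)`` fibers per element cross-section and ``epf`` 1D
    elements per fiber per 3D element.

    Raises
    ------
    ValueError
        On non-positive counts or extents.
    """
    if isinstance(fiber_axis, str):
        if fiber_axis not in _AXES:
            raise ValueError(
                f"fiber_axis must be x, y or z, got {fiber_axis!r}")
        axis = _AXES[fiber_axis]
    else:
        axis = int(fiber_axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"fiber_axis must be x, y or z, got {fiber_axis!r}")
    extent = tuple(float(L) for L in extent)  # type: ignore[assignment]
    elements3d = tuple(int(e) for e in elements3d)  # type: ignore[assignment]
    f = tuple(int(v) for v in fibers_per_cross_section_element)
    epf = int(elements_per_fiber_per_3d_element)
    if any(L <= 0 for L in extent):
        raise ValueError(f"extent must be positive, got {extent}")
    if any(e < 1 for e in elements3d) or any(v < 1 for v in f) or epf < 1:
        raise ValueError("element and fiber counts must be >= 1")

    ex, ey, ez = elements3d
    # Q2 nodes: (2e+1) per axis; Q1 nodes: (e+1) per axis
    q2_axes = [np.linspace(0.0, extent[a], 2 * elements3d[a] + 1) for a in range(3)]
    q1_axes = [np.linspace(0.0, extent[a], elements3d[a] + 1) for a in range(3)]

    def _grid(axes: list[np.ndarray]) -> np.ndarray:
        Z, Y, X = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    q2_nodes = _grid(q2_axes)
    q1_nodes = _grid(q1_axes)

    t1, t2 = (a for a in (0, 1, 2) if a != axis)
    f1, f2 = f
    h = [extent[a] / elements3d[a] for a in range(3)]
    # transverse fiber lattice: offsets (i+0.5)/f within each element
    pos1 = np.array(
        [(e + (i + 0.5) / f1) * h[t1] for e in range(elements3d[t1]) for i in range(f1)]
    )
    pos2 = np.array(
        [(e + (i + 0.5) / f2) * h[t2] for e in range(elements3d[t2]) for i in range(f2)]
    )
    n_per_fiber = epf * elements3d[axis] + 1
    along = np.linspace(0.0, extent[axis], n_per_fiber)

    n_fibers = len(pos1) * len(pos2)
    fiber_nodes = np.empty((n_fibers, n_per_fiber, 3))
    fid = 0
    for p2 in pos2:
        for p1 in pos1:
            fiber_nodes[fid, :, axis] = along
            fiber_nodes[fid, :, t1] = p1
            fiber_nodes[fid, :, t2] = p2
            fid += 1

    return MultiScaleGeometry(
        extent=extent,  # type: ignore[arg-type]
        elements3d=elements3d,  # type: ignore[arg-type]
        fiber_axis=axis,
        fibers_per_cross_section_element=(f1, f2),
        elements_per_fiber_per_3d_element=epf,
        q2_nodes=q2_nodes,
        q1_nodes=q1_nodes,
        fiber_nodes=fiber_nodes,
    )


def fiber_elements_in_3d_element(
    geom: MultiScaleGeometry, element_index: int
) -> list[int]:
    """1D elements whose midpoints lie inside a 3D element, in constant time.

    Pure index arithmetic: the fiber lattice is structured, so the
    ``f1·f2`` fibers crossing the element and the ``epf`` local fiber
    elements of each are enumerated directly without any search over
    fibers.  Cost is independent of the total fiber count.
    """
    i, j, k = geom.element_multi_index(element_index)
    idx = (i, j, k)
    t1, t2 = geom.transverse_axes
    f1, f2 = geom.fibers_per_cross_section_element
    epf = geom.elements_per_fiber_per_3d_element
    ia = idx[geom.fiber_axis]
    out: list[int] = []
    for b in range(f2):
        it2 = idx[t2] * f2 + b
        for a in range(f1):
            it1 = idx[t1] * f1 + a
            fid = geom.fiber_index(it1, it2)
            base = fid * geom.elements_per_fiber + ia * epf
            out.extend(range(base, base + epf))
    return out


def count_entities(geom: MultiScaleGeometry) -> EntityCounts:
    """Structural counts: 3D elements, fibers, 1D elements, sarcomere points."""
    return geom.counts()
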