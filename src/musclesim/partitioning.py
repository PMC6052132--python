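"""Axis-aligned domain decomposition and communication-surface analysis.

Partitions the structured 3D element grid into ``p_x × p_y × p_z``
axis-aligned boxes and computes the structural quantities a parallel
run's communication cost rests on: shared boundary surface area, ghost
element counts, neighbor sets (26-connectivity, so every cuboid
partition has at most 3³ − 1 = 26 neighbors) and the number of fibers
cut by partition boundaries.

Two named strategies exist:

* ``pillar``: one subdivision along the fiber axis, so every partition
  contains entire fibers and no 0D/1D data crosses a boundary;
* ``cuboid``: near-cubic blocks minimizing surface area, at the price of
  cutting every fiber when the fiber axis is subdivided.

This is a serial structural analyzer; no message passing happens here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .geometry import MultiScaleGeometry

__all__ = [
    "Partitioning",
    "decompose",
    "factorize_process_count",
    "neighbor_sets",
    "average_boundary_area",
    "ghost_element_counts",
    "fibers_cut",
    "partition_report",
]


@dataclass
class Partitioning:
    """Axis-aligned box decomposition of the 3D element grid.

    ``boxes[p] = ((i0, i1), (j0, j1), (k0, k1))`` gives the half-open
    element-index ranges of partition ``p``; partitions are ordered
    lexicographically with the x subdivision fastest.
    """

    subdivisions: tuple[int, int, int]
    strategy: str
    boxes: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]
    elements3d: tuple[int, int, int]

    @property
    def n_partitions(self) -> int:
        return len(self.boxes)

    def owner_map(self) -> np.ndarray:
        """Flat array: 3D element id -> partition id (x fastest)."""
        ex, ey, ez = self.elements3d
        owner = np.full(ex * ey * ez, -1, dtype=np.int64)
        for p, ((i0, i1), (j0, j1), (k0, k1)) in enumerate(self.boxes):
            ii = np.arange(i0, i1)
            jj = np.arange(j0, j1)
            kk = np.arange(k0, k1)
            I, J, K = np.meshgrid(ii, jj, kk, indexing="ij")
            ids = I + ex * (J + ey * K)
            owner[ids.ravel()] = p
        return owner


def _axis_splits(n_elements: int, p: int) -> list[tuple[int, int]]:
    """Split ``n_elements`` into ``p`` contiguous ranges.

    All ranges hold ``n // p`` elements; the remainder is assigned one
    extra element each to the trailing (highest-index) ranges, so
    boundary partitions may be larger but the rule is deterministic.
    """
    base = n_elements // p
    rem = n_elements % p
    sizes = [base] * (p - rem) + [base + 1] * rem
    splits = []
    start = 0
    for s in sizes:
        splits.append((start, start + s))
        start += s
    return splits


def decompose(
    geom: MultiScaleGeometry,
    subdivisions: tuple[int, int, int],
    strategy: str = "general",
) -> Partitioning:
    """Decompose the element grid into an axis-aligned box partitioning.

    Raises
    ------
    ValueError
        If a subdivision exceeds the element count on its axis, or a
        pillar decomposition subdivides the fiber axis.
    """
    px, py, pz = (int(p) for p in subdivisions)
    if min(px, py, pz) < 1:
        raise ValueError(f"subdivisions must be >= 1, got {subdivisions}")
    for p, e, name in zip((px, py, pz), geom.elements3d, "xyz"):
        if p > e:
            raise ValueError(
                f"{p} subdivisions exceed {e} elements along {name}"
            )
    if strategy == "pillar" and (px, py, pz)[geom.fiber_axis] != 1:
        raise ValueError(
            "pillar partitioning requires 1 subdivision along the fiber axis"
        )
    splits = [
        _axis_splits(e, p) for e, p in zip(geom.elements3d, (px, py, pz))
    ]
    boxes = [
        (sx, sy, sz)
        for sz in splits[2]
        for sy in splits[1]
        for sx in splits[0]
    ]
    return Partitioning(
        subdivisions=(px, py, pz),
        strategy=strategy,
        boxes=boxes,
        elements3d=geom.elements3d,
    )


def _ordered_factorizations(n: int) -> list[tuple[int, int, int]]:
    """All ordered triples (a, b, c) with a·b·c = n."""
    divs = [d for d in range(1, n + 1) if n % d == 0]
    out = []
    for a in divs:
        for b in divs:
            if (n // a) % b == 0:
                out.append((a, b, n // (a * b)))
    return out


def _aspect_cost(
    subdiv: tuple[int, int, int], elements3d: tuple[int, int, int]
) -> float:
    """Log-space variance of mean block extents; 0 for perfect cubes."""
    logs = [math.log(e / p) for e, p in zip(elements3d, subdiv)]
    mean = sum(logs) / 3.0
    return sum((v - mean) ** 2 for v in logs)


def factorize_process_count(
    n_proc: int,
    geom: MultiScaleGeometry,
    strategy: str = "cuboid",
    atomic_block: tuple[int, int, int] = (1, 1, 1),
) -> tuple[int, int, int]:
    """Choose subdivisions (p_x, p_y, p_z) for up to ``n_proc`` processes.

    Among all factorizations of every m <= n_proc that are admissible —
    each generated partition at least as large as ``atomic_block`` along
    every axis, and for the pillar strategy exactly one subdivision
    along the fiber axis — the factorization with maximal product
    (most processes used) is returned; ties go to the most cube-like
    blocks in log space, then to larger p_x, then larger p_y.

    Raises
    ------
    ValueError
        If no admissible factorization exists (atomic block too large).
    """
    if n_proc < 1:
        raise ValueError("n_proc must be >= 1")
    atomic = tuple(int(a) for a in atomic_block)
    best: tuple[int, int, int] | None = None
    best_key: tuple | None = None
    for m in range(n_proc, 0, -1):
        for sub in _ordered_factorizations(m):
            if strategy == "pillar" and sub[geom.fiber_axis] != 1:
                continue
            ok = all(
                e // p >= a and p <= e
                for e, p, a in zip(geom.elements3d, sub, atomic)
            )
            if not ok:
                continue
            key = (_aspect_cost(sub, geom.elements3d), -sub[0], -sub[1])
            if best_key is None or key < best_key:
                best, best_key = sub, key
        if best is not None:
            return best
    raise ValueError(
        f"no admissible factorization of <= {n_proc} processes for mesh "
        f"{geom.elements3d} with atomic block {atomic}"
    )


def _boxes_adjacent(
    a: tuple[tuple[int, int], ...], b: tuple[tuple[int, int], ...]
) -> bool:
    """26-connectivity adjacency of two disjoint boxes (touch or share)."""
    for (a0, a1), (b0, b1) in zip(a, b):
        if a1 < b0 or b1 < a0:  # gap of at least one element
            return False
    return True


def neighbor_sets(part: Partitioning) -> list[set[int]]:
    """Per-partition sets of adjacent partitions (face/edge/corner)."""
    n = part.n_partitions
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for p, q in itertools.combinations(range(n), 2):
        if _boxes_adjacent(part.boxes[p], part.boxes[q]):
            nbrs[p].add(q)
            nbrs[q].add(p)
    return nbrs


def average_boundary_area(
    part: Partitioning, geom: MultiScaleGeometry
) -> float:
    """Mean over partitions of element-face area shared with other partitions.

    For a grid of boxes this is exact closed-form face counting: a box
    contributes one full cross-section per interior face it exposes.
    Units follow the geometry extent (cm²).
    """
    h = geom.element_size
    px, py, pz = part.subdivisions
    subs = (px, py, pz)
    total = 0.0
    for p, box in enumerate(part.boxes):
        # grid position of this partition
        gx = p % px
        gy = (p // px) % py
        gz = p // (px * py)
        grid = (gx, gy, gz)
        dims = [b[1] - b[0] for b in box]
        for axis in range(3):
            o1, o2 = (a for a in range(3) if a != axis)
            face_area = dims[o1] * h[o1] * dims[o2] * h[o2]
            exposed = (1 if grid[axis] > 0 else 0) + (
                1 if grid[axis] < subs[axis] - 1 else 0
            )
            total += exposed * face_area
    return total / part.n_partitions


def ghost_element_counts(part: Partitioning) -> list[int]:
    """Per-partition count of one-layer ghost 3D elements.

    Ghosts are elements face/edge/corner-adjacent to the partition box
    but owned elsewhere: the box dilated by one element (clipped to the
    mesh) minus the box itself.
    """
    ex, ey, ez = part.elements3d
    mesh = (ex, ey, ez)
    out = []
    for box in part.boxes:
        vol = 1
        dil = 1
        for (lo, hi), n in zip(box, mesh):
            vol *= hi - lo
            dil *= min(hi + 1, n) - max(lo - 1, 0)
        out.append(dil - vol)
    return out


def fibers_cut(part: Partitioning, geom: MultiScaleGeometry) -> int:
    """Number of fibers whose elements span more than one partition.

    Scans each fiber's element column through the owner grid.  Every
    fiber runs the full fiber axis inside one transverse element cell,
    so a fiber is cut exactly when the fiber-axis subdivision splits
    its column.
    """
    owner = part.owner_map()
    ex, ey, _ = geom.elements3d
    axis = geom.fiber_axis
    f1, f2 = geom.fibers_per_cross_section_element
    t1, t2 = geom.transverse_axes
    cut = 0
    for fid in range(geom.n_fibers):
        it1, it2 = geom.fiber_multi_index(fid)
        idx = [0, 0, 0]
        idx[t1] = it1 // f1
        idx[t2] = it2 // f2
        owners = set()
        for ia in range(geom.elements3d[axis]):
            idx[axis] = ia
            owners.add(owner[idx[0] + ex * (idx[1] + ey * idx[2])])
            if len(owners) > 1:
                cut += 1
                break
    return cut


def partition_report(
    part: Partitioning, geom: MultiScaleGeometry
) -> dict:
    """JSON-serializable structural report of a partitioning."""
    nbrs = neighbor_sets(part)
    ghosts = ghost_element_counts(part)
    return {
        "subdivisions": list(part.subdivisions),
        "strategy": part.strategy,
        "n_partitions": part.n_partitions,
        "average_boundary_area_cm2": average_boundary_area(part, geom),
        "fibers_cut": fibers_cut(part, geom),
        "max_neighbors": max((len(s) for s in nbrs), default=0),
        "partitions": [
            {
                "box": [list(r) for r in box],
                "n_elements": int(np.prod([hi - lo for lo, hi in box])),
                "n_neighbors": len(nbrs[p]),
                "n_ghost_elements": ghosts[p],
            }
            for p, box in enumerate(part.boxes)
        ],
    }
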