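"""Transfer operators between the 1D fiber meshes and the 3D mesh.

Three transfers close the multi-scale loop:

* homogenization γ → γ̄: nodal activation values are averaged onto the
  27 Gauss points of the owning 3D element, each fiber node
  contributing to its nearest Gauss point (nearest in the element's
  reference coordinates; ties to the lowest Gauss index);
* interpolation of the 3D displacement field to fiber node positions
  via the Q2 basis of the owning element;
* half-sarcomere lengths from the local fiber stretch:
  l_hs = l_hs_ref × (deformed / reference length of the adjacent
  segments, averaged; one-sided at fiber ends).

All steps are local to the owning element — no information beyond the
element and its own Gauss points is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MultiScaleGeometry
from .mechanics import _GP_XI, _tensor_shapes, q2_element_nodes

__all__ = [
    "TransferMap",
    "build_transfer_map",
    "homogenize_gamma",
    "interpolate_fiber_positions",
    "half_sarcomere_lengths",
]


@dataclass
class TransferMap:
    """Per-1D-node ownership and Gauss assignment.

    Arrays are flat over all sarcomere points (fiber-major):
    ``owner_element``, ``ref_coords`` (ξ ∈ [-1, 1]³), ``nearest_gauss``
    (index into the owning element's 27 Gauss points) and the cached Q2
    shape values ``q2_values`` at each node's reference coordinates.
    """

    owner_element: np.ndarray
    ref_coords: np.ndarray
    nearest_gauss: np.ndarray
    q2_values: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.owner_element)


def build_transfer_map(geom: MultiScaleGeometry) -> TransferMap:
    """Build the 1D↔3D transfer map in time linear in the 1D node count.

    Element ownership comes from index arithmetic (no search); nodes on
    element faces normal to the fiber axis belong to the lower-index
    element, so every node appears exactly once.
    """
    n = geom.n_sarcomere_points
    npf = geom.nodes_per_fiber
    owner = np.empty(n, dtype=np.int64)
    xi = np.empty((n, 3))
    h = np.array(geom.element_size)
    coords = geom.fiber_nodes.reshape(n, 3)
    for fid in range(geom.n_fibers):
        for node in range(npf):
            g = fid * npf + node
            e = geom.owning_element_of_1d_node(fid, node)
            owner[g] = e
            i, j, k = geom.element_multi_index(e)
            lo = np.array([i, j, k]) * h
            xi[g] = 2.0 * (coords[g] - lo) / h - 1.0
    np.clip(xi, -1.0, 1.0, out=xi)
    # nearest Gauss point in reference coordinates; ties -> lowest index
    d2 = ((xi[:, None, :] - _GP_XI[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1).astype(np.int64)
    q2_vals, _, _ = _tensor_shapes(xi)
    return TransferMap(
        owner_element=owner,
        ref_coords=xi,
        nearest_gauss=nearest,
        q2_values=q2_vals,
    )


def homogenize_gamma(
    gamma: np.ndarray,
    tmap: TransferMap,
    geom: MultiScaleGeometry,
) -> np.ndarray:
    """Average nodal γ onto Gauss points, shape (n_elements, 27).

    Each Gauss point takes the mean of the γ values of the fiber nodes
    nearest to it; a Gauss point with no assigned nodes falls back to
    the mean γ over all fiber nodes of its element.
    """
    gamma = np.asarray(gamma, dtype=float).ravel()
    n_el = geom.n_elements_3d
    sums = np.zeros((n_el, 27))
    counts = np.zeros((n_el, 27))
    np.add.at(sums, (tmap.owner_element, tmap.nearest_gauss), gamma)
    np.add.at(counts, (tmap.owner_element, tmap.nearest_gauss), 1.0)
    el_sum = np.zeros(n_el)
    el_cnt = np.zeros(n_el)
    np.add.at(el_sum, tmap.owner_element, gamma)
    np.add.at(el_cnt, tmap.owner_element, 1.0)
    el_mean = np.divide(
        el_sum, el_cnt, out=np.zeros(n_el), where=el_cnt > 0
    )
    out = np.where(
        counts > 0,
        np.divide(sums, np.maximum(counts, 1.0)),
        el_mean[:, None],
    )
    return out


def interpolate_fiber_positions(
    u: np.ndarray,
    tmap: TransferMap,
    geom: MultiScaleGeometry,
) -> np.ndarray:
    """Deformed 1D node positions x = X + Σ N_a(ξ) u_a, shape (n, 3)."""
    n = tmap.n_nodes
    X = geom.fiber_nodes.reshape(n, 3)
    out = X.copy()
    # group nodes by owning element so each connectivity is built once
    order = np.argsort(tmap.owner_element, kind="stable")
    sorted_owner = tmap.owner_element[order]
    starts = np.searchsorted(
        sorted_owner, np.arange(geom.n_elements_3d)
    )
    ends = np.searchsorted(
        sorted_owner, np.arange(geom.n_elements_3d), side="right"
    )
    for e in range(geom.n_elements_3d):
        ids = order[starts[e]:ends[e]]
        if len(ids) == 0:
            continue
        ue = u[q2_element_nodes(geom, e)]  # (27, 3)
        out[ids] += tmap.q2_values[ids] @ ue
    return out


def half_sarcomere_lengths(
    positions: np.ndarray,
    geom: MultiScaleGeometry,
    l_hs_ref: float = 1.0,
) -> np.ndarray:
    """Half-sarcomere length per 1D node from local fiber stretch.

    Nodal stretch is the mean of the adjacent deformed-to-reference
    segment length ratios (one segment at fiber ends).

    Raises
    ------
    ValueError
        On a zero-length reference segment.
    """
    npf = geom.nodes_per_fiber
    pos = np.asarray(positions, dtype=float).reshape(
        geom.n_fibers, npf, 3
    )
    ref = geom.fiber_nodes
    ref_len = np.linalg.norm(np.diff(ref, axis=1), axis=2)
    if np.any(ref_len <= 0):
        raise ValueError("zero-length reference fiber segment")
    def_len = np.linalg.norm(np.diff(pos, axis=1), axis=2)
    seg_stretch = def_len / ref_len  # (n_fibers, npf-1)
    stretch = np.empty((geom.n_fibers, npf))
    stretch[:, 0] = seg_stretch[:, 0]
    stretch[:, -1] = seg_stretch[:, -1]
    if npf > 2:
        stretch[:, 1:-1] = 0.5 * (seg_stretch[:, :-1] + seg_stretch[:, 1:])
    return (l_hs_ref * stretch).ravel()
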