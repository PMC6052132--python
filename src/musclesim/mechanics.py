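"""Quasi-static incompressible transversely isotropic finite elasticity.

The macroscopic muscle deformation solves the balance of linear
momentum ``div P = 0`` with the incompressibility constraint
``det F = 1`` on the structured hexahedral mesh, discretized with
Taylor–Hood elements: tri-quadratic (Q2) displacements and tri-linear
(Q1) hydrostatic pressure.  The first Piola–Kirchhoff stress is the
additive split

    P = P_passive(F, M) + P_active(F, M, γ̄) − p F^{-T},

with a Mooney–Rivlin isotropic ground matrix, an additive anisotropic
fiber-stiffening term active only under fiber stretch (λ_f > 1), and an
active stress σ_max·γ̄ acting along the fiber direction a0
(M = a0 ⊗ a0).  The force–length dependence enters only through γ̄,
which already carries the force–length factor; no second
multiplication happens here.

Newton's method with an analytically assembled consistent tangent and
a backtracking line search solves the discrete saddle-point system;
linear solves use a direct sparse factorization (desk-scale problems).
Quadrature is 3×3×3 Gauss per hexahedron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MultiScaleGeometry

__all__ = [
    "ConstitutiveParams",
    "MechanicalState",
    "BoundaryConditions",
    "deformation_gradient",
    "pk1_stress",
    "material_tangent",
    "assemble_system",
    "solve_equilibrium",
    "reference_pressure",
    "twitch_boundary_conditions",
    "NewtonDivergenceError",
]

N_GP = 27  # 3×3×3 Gauss points per hexahedron


class NewtonDivergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class ConstitutiveParams:
    """Material constants (kPa) and the reference fiber direction.

    Defaults are desk-scale configuration values giving a stable
    stress-free reference state; they are not asserted to match any
    particular experimental fit.  ``active_normalized`` selects whether
    the active stress is divided by the fiber stretch λ_f.
    """

    c1: float = 3.0
    c2: float = 1.0
    b1: float = 1.5
    d: float = 4.0
    sigma_max: float = 30.0
    a0: tuple[float, float, float] = (1.0, 0.0, 0.0)
    active_normalized: bool = True

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.sigma_max) < 0:
            raise ValueError("c1, c2, sigma_max must be >= 0")
        n = float(np.linalg.norm(self.a0))
        if abs(n - 1.0) > 1e-12:
            object.__setattr__(
                self, "a0", tuple(float(v) / n for v in self.a0)
            )


def reference_pressure(params: ConstitutiveParams) -> float:
    """Pressure that makes the undeformed reference state stress-free.

    At F = I the Mooney–Rivlin stress is (2c1 + 4c2)·I, so
    p_ref = 2c1 + 4c2 cancels it; anisotropic and active parts vanish
    there (λ_f = 1, γ̄ = 0).
    """
    return 2.0 * params.c1 + 4.0 * params.c2


@dataclass
class MechanicalState:
    """Q2 displacements u (cm), Q1 pressure p (kPa), Gauss-point activation."""

    u: np.ndarray  # (n_q2, 3)
    p: np.ndarray  # (n_q1,)
    gamma_bar: np.ndarray  # (n_elements, 27)

    def copy(self) -> "MechanicalState":
        return MechanicalState(self.u.copy(), self.p.copy(),
                               self.gamma_bar.copy())


def initial_mechanical_state(
    geom: MultiScaleGeometry, params: ConstitutiveParams
) -> MechanicalState:
    """Reference state: u = 0, p = p_ref, γ̄ = 0."""
    return MechanicalState(
        u=np.zeros((len(geom.q2_nodes), 3)),
        p=np.full(len(geom.q1_nodes), reference_pressure(params)),
        gamma_bar=np.zeros((geom.n_elements_3d, N_GP)),
    )


# --------------------------------------------------------------------------
# shape functions and quadrature (tensor products on [-1, 1]^3)
# --------------------------------------------------------------------------

def _lag2(x: np.ndarray) -> np.ndarray:
    """Quadratic Lagrange values at nodes ξ = −1, 0, 1; shape (..., 3)."""
    return np.stack(
        [0.5 * x * (x - 1.0), 1.0 - x**2, 0.5 * x * (x + 1.0)], axis=-1
    )


def _dlag2(x: np.ndarray) -> np.ndarray:
    return np.stack([x - 0.5, -2.0 * x, x + 0.5], axis=-1)


def _lag1(x: np.ndarray) -> np.ndarray:
    return np.stack([0.5 * (1.0 - x), 0.5 * (1.0 + x)], axis=-1)


def _tensor_shapes(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Q2 values, Q2 ξ-gradients and Q1 values at points ``xi`` (n, 3).

    Local node ordering is lexicographic with the first (x) index
    fastest: Q2 local node = a + 3b + 9c, Q1 local node = a + 2b + 4c.
    """
    n = len(xi)
    Lx, Ly, Lz = _lag2(xi[:, 0]), _lag2(xi[:, 1]), _lag2(xi[:, 2])
    Dx, Dy, Dz = _dlag2(xi[:, 0]), _dlag2(xi[:, 1]), _dlag2(xi[:, 2])
    # pcba + C-order reshape makes the x-index a the fastest local index
    q2 = np.einsum("pa,pb,pc->pcba", Lx, Ly, Lz).reshape(n, 27)
    dq2 = np.empty((n, 27, 3))
    dq2[:, :, 0] = np.einsum("pa,pb,pc->pcba", Dx, Ly, Lz).reshape(n, 27)
    dq2[:, :, 1] = np.einsum("pa,pb,pc->pcba", Lx, Dy, Lz).reshape(n, 27)
    dq2[:, :, 2] = np.einsum("pa,pb,pc->pcba", Lx, Ly, Dz).reshape(n, 27)
    lx, ly, lz = _lag1(xi[:, 0]), _lag1(xi[:, 1]), _lag1(xi[:, 2])
    q1 = np.einsum("pa,pb,pc->pcba", lx, ly, lz).reshape(n, 8)
    return q2, dq2, q1


def gauss_points() -> tuple[np.ndarray, np.ndarray]:
    """3×3×3 Gauss points and weights on [-1, 1]^3 (x index fastest)."""
    g = np.sqrt(3.0 / 5.0)
    pts1 = np.array([-g, 0.0, g])
    w1 = np.array([5.0, 8.0, 5.0]) / 9.0
    pts = np.array(
        [[pts1[a], pts1[b], pts1[c]]
         for c in range(3) for b in range(3) for a in range(3)]
    )
    w = np.array(
        [w1[a] * w1[b] * w1[c]
         for c in range(3) for b in range(3) for a in range(3)]
    )
    return pts, w


_GP_XI, _GP_W = gauss_points()
_Q2_GP, _DQ2_GP, _Q1_GP = _tensor_shapes(_GP_XI)


def gauss_point_coords(geom: MultiScaleGeometry, element: int) -> np.ndarray:
    """Physical coordinates of the 27 Gauss points of one element."""
    i, j, k = geom.element_multi_index(element)
    h = np.array(geom.element_size)
    lo = np.array([i, j, k]) * h
    return lo + (_GP_XI + 1.0) * 0.5 * h


# --------------------------------------------------------------------------
# connectivity
# --------------------------------------------------------------------------

def q2_element_nodes(geom: MultiScaleGeometry, element: int) -> np.ndarray:
    """Global Q2 node ids of one element, local lexicographic order (27,)."""
    i, j, k = geom.element_multi_index(element)
    ex, ey, ez = geom.elements3d
    nx, ny = 2 * ex + 1, 2 * ey + 1
    out = np.empty(27, dtype=np.int64)
    idx = 0
    for c in range(3):
        for b in range(3):
            for a in range(3):
                out[idx] = (2 * i + a) + nx * ((2 * j + b) + ny * (2 * k + c))
                idx += 1
    return out


def q1_element_nodes(geom: MultiScaleGeometry, element: int) -> np.ndarray:
    i, j, k = geom.element_multi_index(element)
    ex, ey, _ = geom.elements3d
    nx, ny = ex + 1, ey + 1
    out = np.empty(8, dtype=np.int64)
    idx = 0
    for c in range(2):
        for b in range(2):
            for a in range(2):
                out[idx] = (i + a) + nx * ((j + b) + ny * (k + c))
                idx += 1
    return out


# --------------------------------------------------------------------------
# kinematics and constitutive law
# --------------------------------------------------------------------------

def deformation_gradient(
    u: np.ndarray,
    geom: MultiScaleGeometry,
    element: int,
    ref_coords: np.ndarray,
) -> np.ndarray:
    """F = I + ∂u/∂X at local reference coordinates ξ ∈ [-1, 1]^3.

    ``ref_coords`` may be (3,) or (n, 3); returns (3, 3) or (n, 3, 3).
    The structured mesh has a constant diagonal Jacobian, so shape
    gradients with respect to X are the ξ-gradients scaled by 2/h.
    """
    xi = np.atleast_2d(np.asarray(ref_coords, dtype=float))
    _, dq2, _ = _tensor_shapes(xi)
    h = np.array(geom.element_size)
    dNdX = dq2 * (2.0 / h)  # (n, 27, 3)
    ue = u[q2_element_nodes(geom, element)]  # (27, 3)
    G = np.einsum("ai,paJ->piJ", ue, dNdX)
    F = G + np.eye(3)
    if np.asarray(ref_coords).ndim == 1:
        return F[0]
    return F


def _fiber_terms(
    F: np.ndarray, a0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fiber stretch λ_f and the push-forward Fa0, batched over (..., 3, 3)."""
    Fa = F @ a0
    lam = np.sqrt(np.einsum("...i,...i->...", Fa, Fa))
    return lam, Fa


def pk1_stress(
    F: np.ndarray,
    gamma_bar: np.ndarray | float,
    p: np.ndarray | float,
    params: ConstitutiveParams,
    l_hs: np.ndarray | float | None = None,
) -> np.ndarray:
    """First Piola–Kirchhoff stress P(F, γ̄, p); batched over leading dims.

    ``l_hs`` is accepted for interface completeness but unused: the
    force–length factor is already inside γ̄.

    Raises
    ------
    ValueError
        If any det F <= 0 (inverted element).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("inverted element: det F <= 0")
    a0 = np.asarray(params.a0)
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    P = 2.0 * params.c1 * F + 2.0 * params.c2 * (
        I1[..., None, None] * F - F @ C
    )
    lam, Fa = _fiber_terms(F, a0)
    Faa0 = Fa[..., :, None] * a0[None, :]  # (..., 3, 3) = Fa0 ⊗ a0
    # anisotropic fiber stiffening, active only under stretch
    stretch = lam > 1.0
    psi_p = np.where(
        stretch,
        2.0 * params.b1 * (lam**params.d - 1.0) * params.d
        * lam ** (params.d - 1.0),
        0.0,
    )
    P = P + (psi_p / lam)[..., None, None] * Faa0
    # active stress along the fiber
    g = np.asarray(gamma_bar, dtype=float)
    scale = params.sigma_max * g
    if params.active_normalized:
        scale = scale / lam
    P = P + np.asarray(scale)[..., None, None] * Faa0
    # pressure term
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    P = P - np.asarray(p, dtype=float)[..., None, None] * FinvT
    return P


def material_tangent(
    F: np.ndarray,
    gamma_bar: np.ndarray,
    p: np.ndarray,
    params: ConstitutiveParams,
) -> np.ndarray:
    """A_iJkL = ∂P_iJ/∂F_kL at fixed pressure; batched (..., 3, 3, 3, 3)."""
    F = np.asarray(F, dtype=float)
    batch = F.shape[:-2]
    I = np.eye(3)
    C = np.swapaxes(F, -1, -2) @ F
    B = F @ np.swapaxes(F, -1, -2)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    dd = np.einsum("ik,JL->iJkL", I, I)
    A = 2.0 * params.c1 * np.broadcast_to(dd, batch + (3, 3, 3, 3)).copy()
    A += 2.0 * params.c2 * (
        2.0 * np.einsum("...kL,...iJ->...iJkL", F, F)
        + I1[..., None, None, None, None] * dd
        - np.einsum("ik,...JL->...iJkL", I, C)
        - np.einsum("...iL,...kJ->...iJkL", F, F)
        - np.einsum("...ik,JL->...iJkL", B, I)
    )
    a0 = np.asarray(params.a0)
    lam, Fa = _fiber_terms(F, a0)
    Faa0 = Fa[..., :, None] * a0[None, :]
    outer_aa = np.einsum("J,L->JL", a0, a0)
    # g(λ): coefficient of Fa0 ⊗ a0 from the anisotropic + active parts
    stretch = lam > 1.0
    psi_p = np.where(
        stretch,
        2.0 * params.b1 * params.d * (lam**params.d - 1.0)
        * lam ** (params.d - 1.0),
        0.0,
    )
    psi_pp = np.where(
        stretch,
        2.0 * params.b1 * params.d * (
            (2.0 * params.d - 1.0) * lam ** (2.0 * params.d - 2.0)
            - (params.d - 1.0) * lam ** (params.d - 2.0)
        ),
        0.0,
    )
    g_aniso = psi_p / lam
    gp_aniso = (psi_pp * lam - psi_p) / lam**2
    scale = params.sigma_max * np.asarray(gamma_bar, dtype=float)
    if params.active_normalized:
        g_act = scale / lam
        gp_act = -scale / lam**2
    else:
        g_act = scale
        gp_act = np.zeros_like(scale)
    g = g_aniso + g_act
    gp = gp_aniso + gp_act
    dlam = Faa0 / lam[..., None, None]  # ∂λ/∂F
    A += gp[..., None, None, None, None] * np.einsum(
        "...iJ,...kL->...iJkL", Faa0, dlam
    )
    A += g[..., None, None, None, None] * np.einsum(
        "ik,JL->iJkL", I, outer_aa
    )
    # pressure: ∂(−p F^{-T})/∂F = p F^{-T}_iL F^{-T}_kJ
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    A += np.asarray(p, dtype=float)[..., None, None, None, None] * np.einsum(
        "...iL,...kJ->...iJkL", FinvT, FinvT
    )
    return A


# --------------------------------------------------------------------------
# boundary conditions
# --------------------------------------------------------------------------

@dataclass
class BoundaryConditions:
    """Zero-displacement Dirichlet constraints on Q2 dofs.

    ``fixed`` is a boolean array of shape (n_q2, 3); True entries are
    held at zero displacement.
    """

    fixed: np.ndarray

    @property
    def n_fixed(self) -> int:
        return int(self.fixed.sum())


def faces_boundary_conditions(
    geom: MultiScaleGeometry, faces: list[str],
    components: str = "xyz",
) -> BoundaryConditions:
    """Fix displacement components on named box faces.

    ``faces`` entries are among x0, x1, y0, y1, z0, z1 (min/max face
    normal to the axis).
    """
    X = geom.q2_nodes
    fixed = np.zeros((len(X), 3), dtype=bool)
    comp = [c for c, name in enumerate("xyz") if name in components]
    tol = 1e-12
    for f in faces:
        axis = "xyz".index(f[0])
        val = 0.0 if f[1] == "0" else geom.extent[axis]
        mask = np.abs(X[:, axis] - val) < tol
        for c in comp:
            fixed[mask, c] = True
    return BoundaryConditions(fixed=fixed)


def twitch_boundary_conditions(geom: MultiScaleGeometry) -> BoundaryConditions:
    """Isometric single-twitch constraints: both x faces, front y face
    and bottom z face fully fixed; remaining faces free."""
    return faces_boundary_conditions(geom, ["x0", "x1", "y0", "z0"])


def symmetry_boundary_conditions(geom: MultiScaleGeometry) -> BoundaryConditions:
    """Uniaxial symmetry constraints: normal displacement fixed on the
    three minimum faces, everything else free."""
    X = geom.q2_nodes
    fixed = np.zeros((len(X), 3), dtype=bool)
    for axis in range(3):
        fixed[np.abs(X[:, axis]) < 1e-12, axis] = True
    return BoundaryConditions(fixed=fixed)


# --------------------------------------------------------------------------
# assembly and Newton solve
# --------------------------------------------------------------------------

def _element_quantities(
    geom: MultiScaleGeometry,
    state: MechanicalState,
    element: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(F, p, γ̄, dNdX) at the 27 Gauss points of one element."""
    h = np.array(geom.element_size)
    dNdX = _DQ2_GP * (2.0 / h)  # (27, 27, 3) gp × node × axis
    ue = state.u[q2_element_nodes(geom, element)]
    G = np.einsum("ai,paJ->piJ", ue, dNdX)
    F = G + np.eye(3)
    pe = state.p[q1_element_nodes(geom, element)]
    p_gp = _Q1_GP @ pe
    return F, p_gp, state.gamma_bar[element], dNdX


def assemble_system(
    state: MechanicalState,
    geom: MultiScaleGeometry,
    params: ConstitutiveParams,
    bcs: BoundaryConditions | None = None,
) -> tuple[np.ndarray, sp.csr_matrix]:
    """Weak-form residual and consistent tangent of the mixed u–p system.

    Dof ordering: all u dofs (node-major, xyz within node), then p
    dofs.  With ``bcs`` given, constrained rows/columns are eliminated
    (identity rows, zero residual).

    Raises
    ------
    ValueError
        On an inverted element during quadrature (message carries the
        element id).
    """
    n_u = 3 * len(geom.q2_nodes)
    n_p = len(geom.q1_nodes)
    detJ = float(np.prod(geom.element_size)) / 8.0
    w = _GP_W * detJ

    R = np.zeros(n_u + n_p)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    for e in range(geom.n_elements_3d):
        F, p_gp, gamma, dNdX = _element_quantities(geom, state, e)
        Jdet = np.linalg.det(F)
        if np.any(Jdet <= 0):
            raise ValueError(f"inverted element {e} during quadrature")
        P = pk1_stress(F, gamma, p_gp, params)
        A = material_tangent(F, gamma, p_gp, params)
        Finv = np.linalg.inv(F)
        FinvT = np.swapaxes(Finv, -1, -2)

        q2n = q2_element_nodes(geom, e)
        q1n = q1_element_nodes(geom, e)
        udof = (3 * q2n[:, None] + np.arange(3)[None, :]).ravel()  # (81,)
        pdof = n_u + q1n

        r_u = np.einsum("p,piJ,paJ->ai", w, P, dNdX).ravel()
        r_p = np.einsum("p,p,pb->b", w, Jdet - 1.0, _Q1_GP)
        np.add.at(R, udof, r_u)
        np.add.at(R, pdof, r_p)

        k_uu = np.einsum(
            "p,paJ,piJkL,pbL->aibk", w, dNdX, A, dNdX
        ).reshape(81, 81)
        k_up = -np.einsum(
            "p,piJ,paJ,pb->aib", w, FinvT, dNdX, _Q1_GP
        ).reshape(81, 8)
        k_pu = np.einsum(
            "p,p,pkL,paL,pb->bak", w, Jdet, FinvT, dNdX, _Q1_GP
        ).reshape(8, 81)

        rows.append(np.repeat(udof, 81)); cols.append(np.tile(udof, 81))
        vals.append(k_uu.ravel())
        rows.append(np.repeat(udof, 8)); cols.append(np.tile(pdof, 81))
        vals.append(k_up.ravel())
        rows.append(np.repeat(pdof, 81)); cols.append(np.tile(udof, 8))
        vals.append(k_pu.ravel())

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_u + n_p, n_u + n_p),
    ).tocsr()

    if bcs is not None:
        fixed = np.zeros(n_u + n_p, dtype=bool)
        fixed[:n_u] = bcs.fixed.ravel()
        keep = sp.diags((~fixed).astype(float))
        K = keep @ K @ keep + sp.diags(fixed.astype(float))
        R[fixed] = 0.0
    return R, K.tocsr()


def quadrature_det_F(
    state: MechanicalState, geom: MultiScaleGeometry
) -> np.ndarray:
    """det F at every Gauss point, shape (n_elements, 27)."""
    out = np.empty((geom.n_elements_3d, N_GP))
    for e in range(geom.n_elements_3d):
        F, _, _, _ = _element_quantities(geom, state, e)
        out[e] = np.linalg.det(F)
    return out


def solve_equilibrium(
    state0: MechanicalState,
    geom: MultiScaleGeometry,
    params: ConstitutiveParams,
    bcs: BoundaryConditions,
    tol_rel: float = 1e-8,
    tol_abs: float = 1e-8,
    max_newton: int = 50,
    max_linesearch: int = 40,
    n_load_steps: int = 1,
) -> tuple[MechanicalState, int]:
    """Newton solve of the quasi-static equilibrium; returns (state, iters).

    Convergence when the residual norm falls below
    ``max(tol_abs, tol_rel · ‖R₀‖)``.  The backtracking line search
    halves the step up to ``max_linesearch`` times and accepts only
    residual-norm-reducing steps.  If a full-activation solve fails,
    ``n_load_steps`` > 1 ramps γ̄ in equal increments.

    Raises
    ------
    NewtonDivergenceError
        On non-convergence; carries the last residual norm.
    """
    if n_load_steps > 1:
        target = state0.gamma_bar.copy()
        state = state0.copy()
        total = 0
        for s in range(1, n_load_steps + 1):
            state.gamma_bar = target * (s / n_load_steps)
            state, it = solve_equilibrium(
                state, geom, params, bcs, tol_rel, tol_abs,
                max_newton, max_linesearch, n_load_steps=1,
            )
            total += it
        state.gamma_bar = target
        return state, total

    state = state0.copy()
    state.u[bcs.fixed] = 0.0
    R, K = assemble_system(state, geom, params, bcs)
    norm0 = float(np.linalg.norm(R))
    tol = max(tol_abs, tol_rel * norm0)
    norm = norm0
    n_u = 3 * len(geom.q2_nodes)
    for it in range(max_newton):
        if norm <= tol:
            return state, it
        delta = spla.spsolve(K.tocsc(), -R)
        alpha = 1.0
        for _ in range(max_linesearch):
            trial = state.copy()
            trial.u += alpha * delta[:n_u].reshape(-1, 3)
            trial.p += alpha * delta[n_u:]
            try:
                R_t, K_t = assemble_system(trial, geom, params, bcs)
            except ValueError:
                alpha *= 0.5
                continue
            norm_t = float(np.linalg.norm(R_t))
            if norm_t < norm:
                state, R, K, norm = trial, R_t, K_t, norm_t
                break
            alpha *= 0.5
        else:
            raise NewtonDivergenceError(
                f"line search stalled at residual {norm:.3e}", norm
            )
    if norm <= tol:
        return state, max_newton
    raise NewtonDivergenceError(
        f"Newton did not converge in {max_newton} iterations "
        f"(residual {norm:.3e})",
        norm,
    )


def uniaxial_active_stretch_oracle(
    params: ConstitutiveParams, gamma: float
) -> float:
    """Semi-analytic incompressible uniaxial reduction, solved by
    scalar root-finding.

    For a homogeneous deformation F = diag(λ, λ^{-1/2}, λ^{-1/2}) with
    the fiber along x and traction-free transverse faces, the pressure
    follows from P_yy = 0 and the axial stretch λ is the root of
    P_xx(λ) = 0.  Independent of the FEM machinery: works directly on
    the constitutive law.
    """
    from scipy.optimize import brentq

    def axial_stress(lam: float) -> float:
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        # pressure from zero transverse stress, using a p=0 evaluation
        P0 = pk1_stress(F, gamma, 0.0, params)
        FinvT = np.linalg.inv(F).T
        p = P0[1, 1] / FinvT[1, 1]
        P = P0 - p * FinvT
        return float(P[0, 0])

    return float(brentq(axial_stress, 0.4, 2.5, xtol=1e-12))
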