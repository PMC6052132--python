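"""1D monodomain diffusion on fibers: FEM assembly, solvers, stimulus.

The action potential propagates along each fiber by the monodomain
equation

    dV_m/dt = 1/(A_m C_m) [ d/dx ( σ_eff dV_m/dx ) − A_m I_ion ],

whose diffusion part is discretized with linear Lagrange finite
elements and zero-Neumann fiber ends (no current leaves the fiber).
One implicit step (θ = 1 implicit Euler, θ = 1/2 Crank–Nicolson) yields
a symmetric, strictly diagonally dominant tridiagonal system

    (M + θ dt D) V_new = (M − (1−θ) dt D) V_old,

with consistent mass matrix M and D = σ_eff/(A_m C_m) · K the scaled
stiffness.  The system is solved either directly by the Thomas
algorithm (linear operation count, instrumented) or iteratively by CG
or restarted GMRES(30) at relative residual tolerance 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MultiScaleGeometry

__all__ = [
    "FiberConductionParams",
    "StimulusProtocol",
    "TridiagonalSystem",
    "assemble_diffusion_system",
    "solve_linear",
    "thomas_solve",
    "stimulus_current",
    "midpoint_node",
]


@dataclass(frozen=True)
class FiberConductionParams:
    """Conduction constants of the monodomain equation.

    Defaults are literature-typical for skeletal muscle fibers and are
    configuration values: σ_eff in mS/cm, A_m in 1/cm, C_m in μF/cm².
    """

    sigma_eff: float = 3.828
    A_m: float = 500.0
    C_m: float = 1.0

    def __post_init__(self) -> None:
        # σ_eff = 0 is the decoupled (reaction-only) limit and is allowed
        if self.sigma_eff < 0 or self.A_m <= 0 or self.C_m <= 0:
            raise ValueError("conduction parameters must be positive")

    @property
    def diffusivity(self) -> float:
        """Effective diffusion coefficient σ_eff/(A_m C_m) in cm²/ms."""
        return self.sigma_eff / (self.A_m * self.C_m)


@dataclass(frozen=True)
class StimulusProtocol:
    """Applied-current protocol.

    The single-twitch scenario stimulates every fiber at its midpoint
    node with 1200 μA/cm² during the first 0.1 ms; outside the window
    (or off-target) the stimulus is zero.  ``onsets`` optionally shifts
    the window per fiber (motor-unit-like randomized trains; generate
    with :func:`randomized_onsets`).
    """

    amplitude: float = 1200.0
    t_start: float = 0.0
    t_end: float = 0.1
    target: str = "midpoint"  # or "nodes"
    nodes: tuple[int, ...] = ()
    onsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("stimulus window must have t_end >= t_start")
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")


def midpoint_node(n_nodes: int) -> int:
    """Midpoint node index; ties go to the lower index for even counts."""
    return (n_nodes - 1) // 2


def stimulus_current(
    protocol: StimulusProtocol,
    geom: MultiScaleGeometry,
    fiber_id: int,
    node_id: int,
    t: float,
) -> float:
    """I_stim at one fiber node and time (μA/cm²)."""
    if not 0 <= fiber_id < geom.n_fibers:
        raise IndexError(f"fiber {fiber_id} out of range")
    if not 0 <= node_id < geom.nodes_per_fiber:
        raise IndexError(f"node {node_id} out of range")
    if protocol.target == "midpoint":
        on_target = node_id == midpoint_node(geom.nodes_per_fiber)
    else:
        on_target = node_id in protocol.nodes
    if not on_target:
        return 0.0
    shift = protocol.onsets[fiber_id] if protocol.onsets is not None else 0.0
    if protocol.t_start + shift <= t <= protocol.t_end + shift:
        return protocol.amplitude
    return 0.0


def stimulus_field(
    protocol: StimulusProtocol,
    geom: MultiScaleGeometry,
    t: float,
) -> np.ndarray:
    """Vectorized I_stim for all fibers/nodes, shape (n_fibers, nodes_per_fiber)."""
    n_f, n_n = geom.n_fibers, geom.nodes_per_fiber
    out = np.zeros((n_f, n_n))
    if protocol.target == "midpoint":
        cols = [midpoint_node(n_n)]
    else:
        cols = [c for c in protocol.nodes if 0 <= c < n_n]
    if not cols:
        return out
    if protocol.onsets is None:
        if protocol.t_start <= t <= protocol.t_end:
            out[:, cols] = protocol.amplitude
    else:
        on = np.array(
            [
                protocol.t_start + s <= t <= protocol.t_end + s
                for s in protocol.onsets
            ]
        )
        out[np.ix_(on, cols)] = protocol.amplitude
    return out


def randomized_onsets(
    n_fibers: int, max_delay: float, seed: int
) -> tuple[float, ...]:
    """Uniform per-fiber stimulation onset delays in [0, max_delay] ms."""
    rng = np.random.default_rng(seed)
    return tuple(rng.uniform(0.0, max_delay, size=n_fibers))


@dataclass
class TridiagonalSystem:
    """Symmetric tridiagonal linear system sub/main/super + rhs."""

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    rhs: np.ndarray

    @property
    def n(self) -> int:
        return len(self.diag)

    def to_sparse(self) -> sp.csr_matrix:
        return sp.diags(
            [self.lower, self.diag, self.upper], [-1, 0, 1], format="csr"
        )

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.diag * v
        out[:-1] += self.upper * v[1:]
        out[1:] += self.lower * v[:-1]
        return out


def fiber_fem_matrices(
    n_nodes: int, dx: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Consistent mass and stiffness diagonals of a uniform linear-FEM fiber.

    Returns (m_off, m_diag, k_off, k_diag); zero-Neumann ends make the
    stiffness rows sum to zero.
    """
    if n_nodes < 2:
        raise ValueError("a fiber needs at least 2 nodes")
    m_off = np.full(n_nodes - 1, dx / 6.0)
    m_diag = np.full(n_nodes, 2.0 * dx / 3.0)
    m_diag[0] = m_diag[-1] = dx / 3.0
    k_off = np.full(n_nodes - 1, -1.0 / dx)
    k_diag = np.full(n_nodes, 2.0 / dx)
    k_diag[0] = k_diag[-1] = 1.0 / dx
    return m_off, m_diag, k_off, k_diag


def assemble_diffusion_system(
    n_nodes: int,
    dx: float,
    V_m: np.ndarray,
    dt_1d: float,
    scheme: str,
    params: FiberConductionParams,
) -> TridiagonalSystem:
    """Assemble one implicit diffusion step on a uniform fiber.

    ``scheme`` selects θ: "crank_nicolson" (1/2) or "implicit_euler"
    (1).  With dt_1d = 0 the step degenerates to M V_new = M V_old,
    i.e. solving returns V_m unchanged.
    """
    theta = {"crank_nicolson": 0.5, "implicit_euler": 1.0}.get(scheme)
    if theta is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    if dt_1d < 0:
        raise ValueError("dt_1d must be >= 0")
    V = np.asarray(V_m, dtype=float)
    if V.shape[-1] != n_nodes:
        raise ValueError("V_m length does not match node count")
    m_off, m_diag, k_off, k_diag = fiber_fem_matrices(n_nodes, dx)
    kappa = params.diffusivity
    lhs_off = m_off + theta * dt_1d * kappa * k_off
    lhs_diag = m_diag + theta * dt_1d * kappa * k_diag
    # rhs = (M − (1−θ) dt D) V
    r_off = m_off - (1.0 - theta) * dt_1d * kappa * k_off
    r_diag = m_diag - (1.0 - theta) * dt_1d * kappa * k_diag
    rhs = r_diag * V
    rhs[..., :-1] += r_off * V[..., 1:]
    rhs[..., 1:] += r_off * V[..., :-1]
    return TridiagonalSystem(
        lower=lhs_off.copy(), diag=lhs_diag, upper=lhs_off.copy(), rhs=rhs
    )


class _OpCounter:
    """Counts floating-point operations of the Thomas sweeps."""

    def __init__(self) -> None:
        self.ops = 0


def thomas_solve(
    system: TridiagonalSystem,
    rhs: np.ndarray | None = None,
    counter: _OpCounter | None = None,
) -> np.ndarray:
    """Direct tridiagonal (Thomas) solve; O(n) operations.

    ``rhs`` may be 1D or 2D ``(n_systems, n)`` sharing the matrix.  The
    optional counter accumulates an exact arithmetic-operation count
    that is affine in n, reflecting the algorithm's linear complexity.
    """
    b = system.rhs if rhs is None else np.asarray(rhs, dtype=float)
    squeeze = b.ndim == 1
    b = np.atleast_2d(b).copy()
    n = system.n
    c = system.upper.astype(float).copy()
    d = system.diag.astype(float).copy()
    a = system.lower
    # forward elimination
    for i in range(1, n):
        w = a[i - 1] / d[i - 1]
        d[i] -= w * c[i - 1]
        b[:, i] -= w * b[:, i - 1]
    x = np.empty_like(b)
    x[:, -1] = b[:, -1] / d[-1]
    for i in range(n - 2, -1, -1):
        x[:, i] = (b[:, i] - c[i] * x[:, i + 1]) / d[i]
    if counter is not None:
        # per interior row: 1 div + 2 mul + 2 sub (forward), 1 mul + 1 sub
        # + 1 div (backward); last row: 1 div
        counter.ops += 8 * (n - 1) + 1
    return x[0] if squeeze else x


def solve_linear(
    system: TridiagonalSystem,
    method: str = "thomas",
    tol: float = 1e-5,
    counter: _OpCounter | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the assembled tridiagonal system.

    Methods: "thomas" (direct), "cg", "gmres_restart30" (restart length
    30).  Iterative methods stop when the residual has dropped by the
    relative tolerance ``tol`` from the initial residual (initial guess
    ``x0``, zero by default — during time stepping the previous V_m is
    the natural guess), with an iteration cap of 10·n.

    Raises
    ------
    RuntimeError
        If an iterative method fails to converge within the cap; the
        message carries the last residual norm.
    """
    if method == "thomas":
        return thomas_solve(system, counter=counter)
    A = system.to_sparse()
    b = system.rhs
    if b.ndim != 1:
        return np.vstack(
            [
                solve_linear(
                    TridiagonalSystem(system.lower, system.diag,
                                      system.upper, row),
                    method=method, tol=tol,
                    x0=None if x0 is None else x0[i],
                )
                for i, row in enumerate(b)
            ]
        )
    n = system.n
    guess = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    r0 = b - A @ guess
    if method == "cg":
        delta, info = spla.cg(A, r0, rtol=tol, atol=0.0, maxiter=10 * n)
    elif method == "gmres_restart30":
        outer = max(1, -(-10 * n // 30))
        delta, info = spla.gmres(
            A, r0, rtol=tol, atol=0.0, restart=30, maxiter=outer
        )
    else:
        raise ValueError(f"unknown linear solver {method!r}")
    x = guess + delta
    if info != 0:
        res = np.linalg.norm(b - A @ x)
        raise RuntimeError(
            f"{method} failed to converge (info={info}), residual {res:.3e}"
        )
    return x


def lumped_integral(V: np.ndarray, n_nodes: int, dx: float) -> float:
    """1ᵀ M V with the consistent mass matrix (total potential content)."""
    m_off, m_diag, _, _ = fiber_fem_matrices(n_nodes, dx)
    v = np.asarray(V, dtype=float)
    total = float(np.sum(m_diag * v))
    total += float(np.sum(m_off * v[1:]) + np.sum(m_off * v[:-1]))
    return total
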