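"""Multi-rate time hierarchy and Godunov/Strang operator splitting.

Reaction (0D) and diffusion (1D) are advanced on nested time steps
``dt_3D = N·dt_1D`` and ``dt_1D = K·dt_0D``.  One 1D step advances the
fiber state by ``dt_1D`` in one of two ways:

* Godunov (first order): K explicit Euler reaction sub-steps, then one
  implicit Euler diffusion step — the baseline scheme;
* Strang (second order): K/2 Heun reaction sub-steps over the first
  half step, one Crank–Nicolson diffusion step over the full step,
  then K/2 Heun sub-steps over the second half.

The stimulus is evaluated at the left endpoint of each reaction
sub-step.  Instrumented counters record reaction right-hand-side calls
and tridiagonal solves so the bookkeeping of each scheme can be
asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cell_models import CellModel
from .geometry import MultiScaleGeometry
from .monodomain import (
    FiberConductionParams,
    StimulusProtocol,
    assemble_diffusion_system,
    solve_linear,
    stimulus_field,
)

__all__ = [
    "SplittingSchedule",
    "FiberState",
    "Counters",
    "euler_step",
    "heun_step",
    "godunov_step",
    "strang_step",
    "advance",
    "estimate_order",
    "theoretical_speedup",
]


@dataclass(frozen=True)
class SplittingSchedule:
    """Nested time steps: dt_3D = N·dt_1D, dt_1D = K·dt_0D (ms)."""

    dt_3d: float
    N: int
    K: int
    scheme: str = "godunov"  # or "strang"
    reaction_integrator: str = "euler"  # or "heun"

    def __post_init__(self) -> None:
        if self.N < 1 or self.K < 1:
            raise ValueError("N and K must be >= 1")
        if self.dt_3d <= 0:
            raise ValueError("dt_3d must be positive")
        if self.scheme not in ("godunov", "strang"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "strang" and self.K % 2 != 0:
            raise ValueError("Strang splitting requires even K")
        if self.reaction_integrator not in ("euler", "heun"):
            raise ValueError(
                f"unknown reaction integrator {self.reaction_integrator!r}"
            )

    @property
    def dt_1d(self) -> float:
        return self.dt_3d / self.N

    @property
    def dt_0d(self) -> float:
        return self.dt_1d / self.K

    @classmethod
    def baseline(cls, dt_3d: float = 1.0, N: int = 2000, K: int = 5
                 ) -> "SplittingSchedule":
        """Baseline configuration: Godunov + Euler + implicit Euler."""
        return cls(dt_3d, N, K, scheme="godunov", reaction_integrator="euler")

    @classmethod
    def improved(cls, dt_3d: float = 1.0, N: int = 250, K: int = 2
                 ) -> "SplittingSchedule":
        """Improved configuration: Strang + Heun + Crank–Nicolson."""
        return cls(dt_3d, N, K, scheme="strang", reaction_integrator="heun")


@dataclass
class FiberState:
    """Coupled fiber-bundle state: V (n_fibers, n_nodes), y (…, state_dim)."""

    V: np.ndarray
    y: np.ndarray

    def copy(self) -> "FiberState":
        return FiberState(self.V.copy(), self.y.copy())


@dataclass
class Counters:
    """Instrumented operation counters for sub-step bookkeeping."""

    rhs_calls: int = 0
    tridiag_solves: int = 0
    thomas_ops: int = 0

    # duck-typed into monodomain's op counter
    @property
    def ops(self) -> int:
        return self.thomas_ops

    @ops.setter
    def ops(self, value: int) -> None:
        self.thomas_ops = value


def euler_step(state: np.ndarray, rhs: Callable[[np.ndarray], np.ndarray],
               dt: float) -> np.ndarray:
    """One explicit Euler step: state + dt·rhs(state)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    out = state + dt * rhs(state)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state after Euler step")
    return out


def heun_step(state: np.ndarray, rhs: Callable[[np.ndarray], np.ndarray],
              dt: float) -> np.ndarray:
    """One Heun (explicit trapezoidal) step; exactly 2 rhs evaluations.

    Predictor ``s* = s + dt f(s)``, corrector
    ``s_new = s + dt/2 (f(s) + f(s*))``.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    k1 = rhs(state)
    pre = state + dt * k1
    out = state + 0.5 * dt * (k1 + rhs(pre))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state after Heun step")
    return out


def _reaction_rhs(
    model: CellModel,
    V: np.ndarray,
    y: np.ndarray,
    I_stim: np.ndarray,
    t: float,
    counters: Counters | None,
) -> tuple[np.ndarray, np.ndarray]:
    if counters is not None:
        counters.rhs_calls += 1
    dy = model.rates(y, V, I_stim, t)
    dV = -model.current(y, V, I_stim) / model.C_m
    return dV, dy


def _reaction_substeps(
    state: FiberState,
    model: CellModel,
    geom: MultiScaleGeometry,
    protocol: StimulusProtocol,
    t0: float,
    dt: float,
    n_steps: int,
    integrator: str,
    counters: Counters | None,
) -> FiberState:
    V, y = state.V, state.y
    for k in range(n_steps):
        t = t0 + k * dt
        I = stimulus_field(protocol, geom, t)
        dV1, dy1 = _reaction_rhs(model, V, y, I, t, counters)
        if integrator == "euler":
            V = V + dt * dV1
            y = y + dt * dy1
        else:  # heun
            Vp = V + dt * dV1
            yp = y + dt * dy1
            dV2, dy2 = _reaction_rhs(model, Vp, yp, I, t, counters)
            V = V + 0.5 * dt * (dV1 + dV2)
            y = y + 0.5 * dt * (dy1 + dy2)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(y))):
        raise FloatingPointError("non-finite fiber state in reaction sub-steps")
    return FiberState(V, y)


def _diffusion_step(
    V: np.ndarray,
    geom: MultiScaleGeometry,
    params: FiberConductionParams,
    dt: float,
    scheme: str,
    solver: str,
    counters: Counters | None,
) -> np.ndarray:
    n_nodes = geom.nodes_per_fiber
    dx = geom.extent[geom.fiber_axis] / geom.elements_per_fiber
    system = assemble_diffusion_system(n_nodes, dx, V, dt, scheme, params)
    if counters is not None:
        counters.tridiag_solves += 1
    if solver == "thomas":
        from .monodomain import thomas_solve

        return thomas_solve(system, counter=counters)
    # previous potential is the natural iterative initial guess
    return solve_linear(system, method=solver, x0=V)


def godunov_step(
    state: FiberState,
    schedule: SplittingSchedule,
    model: CellModel,
    geom: MultiScaleGeometry,
    conduction: FiberConductionParams,
    protocol: StimulusProtocol,
    t: float,
    solver: str = "thomas",
    counters: Counters | None = None,
) -> FiberState:
    """Advance by dt_1D: K Euler reaction sub-steps, then implicit Euler diffusion."""
    st = _reaction_substeps(
        state, model, geom, protocol, t, schedule.dt_0d, schedule.K,
        schedule.reaction_integrator, counters,
    )
    V = _diffusion_step(
        st.V, geom, conduction, schedule.dt_1d, "implicit_euler", solver,
        counters,
    )
    return FiberState(V, st.y)


def strang_step(
    state: FiberState,
    schedule: SplittingSchedule,
    model: CellModel,
    geom: MultiScaleGeometry,
    conduction: FiberConductionParams,
    protocol: StimulusProtocol,
    t: float,
    solver: str = "thomas",
    counters: Counters | None = None,
) -> FiberState:
    """Advance by dt_1D: K/2 Heun sub-steps, Crank–Nicolson diffusion, K/2 Heun."""
    if schedule.K % 2 != 0:
        raise ValueError("Strang splitting requires even K")
    half = schedule.K // 2
    st = _reaction_substeps(
        state, model, geom, protocol, t, schedule.dt_0d, half,
        "heun", counters,
    )
    V = _diffusion_step(
        st.V, geom, conduction, schedule.dt_1d, "crank_nicolson", solver,
        counters,
    )
    st = FiberState(V, st.y)
    st = _reaction_substeps(
        st, model, geom, protocol, t + half * schedule.dt_0d,
        schedule.dt_0d, schedule.K - half, "heun", counters,
    )
    return st


def advance(
    state: FiberState,
    schedule: SplittingSchedule,
    model: CellModel,
    geom: MultiScaleGeometry,
    conduction: FiberConductionParams,
    protocol: StimulusProtocol,
    t0: float = 0.0,
    n_steps: int | None = None,
    solver: str = "thomas",
    counters: Counters | None = None,
) -> FiberState:
    """Advance the fiber state by ``n_steps`` (default N) 1D steps."""
    step = strang_step if schedule.scheme == "strang" else godunov_step
    n = schedule.N if n_steps is None else n_steps
    for i in range(n):
        state = step(
            state, schedule, model, geom, conduction, protocol,
            t0 + i * schedule.dt_1d, solver=solver, counters=counters,
        )
    return state


def estimate_order(
    errors: np.ndarray, step_sizes: np.ndarray
) -> float:
    """Least-squares slope of log(error) vs log(step size)."""
    e = np.asarray(errors, dtype=float)
    h = np.asarray(step_sizes, dtype=float)
    if e.size < 2 or h.size != e.size:
        raise ValueError("need at least 2 matching (error, step) pairs")
    if np.any(e <= 0) or np.any(h <= 0):
        raise ValueError("errors and step sizes must be positive")
    slope, _ = np.polyfit(np.log(h), np.log(e), 1)
    return float(slope)


def theoretical_speedup(
    K_base: int, evals_base: int, K_new: int, evals_new: int
) -> float:
    """Work ratio (K_base·evals_base)/(K_new·evals_new) of two 0D configurations.

    Fifty Euler steps (1 rhs evaluation each) replaced by two Heun steps
    (2 evaluations each) give 50/4 = 12.5.
    """
    if min(K_base, evals_base, K_new, evals_new) <= 0:
        raise ValueError("counts must be positive")
    return (K_base * evals_base) / (K_new * evals_new)
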