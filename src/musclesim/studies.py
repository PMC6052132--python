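"""Desk-scale study drivers: twitch, convergence, solvers, partitions.

Each driver reproduces the design of one numerical study on problem
sizes a workstation handles in seconds to minutes:

* :func:`run_single_twitch` — the isometric single-twitch scenario on
  the cube muscle: midpoint stimulation of every fiber, the coupled
  0D/1D/3D loop with homogenization and interpolation, and
  per-component wall-time bookkeeping;
* :func:`run_convergence_study` — empirical convergence orders of the
  reaction integrators (Euler vs Heun) and of the splitting schemes
  (Godunov vs Strang) against fine-step references;
* :func:`run_solver_comparison` — Thomas vs CG vs restarted GMRES on
  the 1D diffusion systems over a sweep of fiber resolutions;
* :func:`run_partition_study` — all axis-aligned decompositions of a
  mesh into a fixed partition count, with structural communication
  metrics sorted by average boundary area.

All wall-clock numbers are informational only; nothing here asserts
absolute runtimes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_models import (
    ActivationParams,
    CellModel,
    HodgkinHuxleyFixture,
    activation_gamma,
)
from .coupling import (
    build_transfer_map,
    half_sarcomere_lengths,
    homogenize_gamma,
    interpolate_fiber_positions,
)
from .geometry import MultiScaleGeometry, build_cube_geometry
from .mechanics import (
    ConstitutiveParams,
    initial_mechanical_state,
    solve_equilibrium,
    twitch_boundary_conditions,
)
from .monodomain import (
    FiberConductionParams,
    StimulusProtocol,
    assemble_diffusion_system,
    midpoint_node,
    thomas_solve,
    solve_linear,
)
from .partitioning import (
    _ordered_factorizations,
    average_boundary_area,
    decompose,
    fibers_cut,
    ghost_element_counts,
    neighbor_sets,
)
from .splitting import (
    Counters,
    FiberState,
    SplittingSchedule,
    _diffusion_step,
    _reaction_substeps,
    advance,
)
from .monodomain import lumped_integral  # noqa: F401  (re-export convenience)

__all__ = [
    "TwitchResult",
    "run_single_twitch",
    "run_convergence_study",
    "run_solver_comparison",
    "run_partition_study",
    "write_outputs",
    "single_fiber_state",
]


def single_fiber_state(
    model: CellModel, geom: MultiScaleGeometry
) -> FiberState:
    """All-fibers-at-rest state shaped (n_fibers, nodes_per_fiber, …)."""
    y0, V0 = model.resting_state()
    nf, nn = geom.n_fibers, geom.nodes_per_fiber
    return FiberState(
        V=np.full((nf, nn), V0),
        y=np.tile(y0, (nf, nn, 1)),
    )


@dataclass
class TwitchResult:
    """Bundle of a coupled twitch run."""

    times: np.ndarray  # output times (ms), one per 3D step
    V_m_midpoint: np.ndarray  # (n_outputs, n_fibers)
    V_m_final: np.ndarray  # (n_fibers, nodes_per_fiber)
    gamma_bar_mean: np.ndarray  # mean activation per output
    u_max: np.ndarray  # max |u| per output (cm)
    final_displacement: np.ndarray  # (n_q2, 3)
    timings: dict[str, float]
    config: dict = field(default_factory=dict)

    def timing_fractions(self) -> dict[str, float]:
        total = sum(self.timings.values())
        return {k: v / total for k, v in self.timings.items()} if total else {}


def run_single_twitch(
    geom: MultiScaleGeometry | None = None,
    model: CellModel | None = None,
    schedule: SplittingSchedule | None = None,
    conduction: FiberConductionParams | None = None,
    protocol: StimulusProtocol | None = None,
    mech_params: ConstitutiveParams | None = None,
    act_params: ActivationParams | None = None,
    t_end: float = 1.0,
    solver: str = "thomas",
    solve_mechanics: bool = True,
    seed: int = 0,
) -> TwitchResult:
    """Isometric single-twitch experiment on the cube muscle.

    Defaults follow the serial runtime study: a 2×2×2-element cube with
    6×6 fibers, midpoint stimulation of 1200 μA/cm² for 0.1 ms, the
    improved (Strang) schedule, run to ``t_end`` ms.  Each dt_3D step
    runs N 1D steps (each with K reaction sub-steps and one tridiagonal
    solve), homogenizes γ to the Gauss points, solves the 3D
    equilibrium, interpolates displacements back to the fibers and
    updates half-sarcomere lengths.  Wall time is accounted per
    component (0D, 1D, 3D, homogenization, interpolation).
    """
    geom = geom or build_cube_geometry(
        elements3d=(2, 2, 2),
        fibers_per_cross_section_element=(3, 3),
        elements_per_fiber_per_3d_element=3,
    )
    model = model or HodgkinHuxleyFixture()
    schedule = schedule or SplittingSchedule.improved(dt_3d=min(t_end, 1.0))
    conduction = conduction or FiberConductionParams()
    protocol = protocol or StimulusProtocol()
    mech_params = mech_params or ConstitutiveParams()
    act_params = act_params or ActivationParams()

    tmap = build_transfer_map(geom)
    state = single_fiber_state(model, geom)
    mech = initial_mechanical_state(geom, mech_params)
    bcs = twitch_boundary_conditions(geom)
    l_hs = np.full(geom.n_sarcomere_points, act_params.l_hs_ref)

    timings = {k: 0.0 for k in
               ("0D", "1D", "3D", "homogenization", "interpolation")}
    mid = midpoint_node(geom.nodes_per_fiber)
    n_3d_steps = max(1, round(t_end / schedule.dt_3d))
    times, traces, gb_means, u_maxes = [], [], [], []
    reaction_integrator = (
        "heun" if schedule.scheme == "strang" else schedule.reaction_integrator
    )

    t = 0.0
    for _m in range(n_3d_steps):
        for n in range(schedule.N):
            tn = t + n * schedule.dt_1d
            if schedule.scheme == "strang":
                half = schedule.K // 2
                t0c = time.perf_counter()
                state = _reaction_substeps(
                    state, model, geom, protocol, tn, schedule.dt_0d,
                    half, "heun", None)
                timings["0D"] += time.perf_counter() - t0c
                t0c = time.perf_counter()
                V = _diffusion_step(state.V, geom, conduction,
                                    schedule.dt_1d, "crank_nicolson",
                                    solver, None)
                timings["1D"] += time.perf_counter() - t0c
                state = FiberState(V, state.y)
                t0c = time.perf_counter()
                state = _reaction_substeps(
                    state, model, geom, protocol,
                    tn + half * schedule.dt_0d, schedule.dt_0d,
                    schedule.K - half, "heun", None)
                timings["0D"] += time.perf_counter() - t0c
            else:
                t0c = time.perf_counter()
                state = _reaction_substeps(
                    state, model, geom, protocol, tn, schedule.dt_0d,
                    schedule.K, reaction_integrator, None)
                timings["0D"] += time.perf_counter() - t0c
                t0c = time.perf_counter()
                V = _diffusion_step(state.V, geom, conduction,
                                    schedule.dt_1d, "implicit_euler",
                                    solver, None)
                timings["1D"] += time.perf_counter() - t0c
                state = FiberState(V, state.y)
        t += schedule.dt_3d

        # gamma -> gauss points
        t0c = time.perf_counter()
        A2 = model.a2(state.y.reshape(-1, model.state_dim))
        gamma = activation_gamma(A2, l_hs, model, act_params)
        mech.gamma_bar = homogenize_gamma(gamma, tmap, geom)
        timings["homogenization"] += time.perf_counter() - t0c

        if solve_mechanics:
            t0c = time.perf_counter()
            mech, _ = solve_equilibrium(
                mech, geom, mech_params, bcs, n_load_steps=1)
            timings["3D"] += time.perf_counter() - t0c

        t0c = time.perf_counter()
        positions = interpolate_fiber_positions(mech.u, tmap, geom)
        l_hs = half_sarcomere_lengths(positions, geom, act_params.l_hs_ref)
        timings["interpolation"] += time.perf_counter() - t0c

        times.append(t)
        traces.append(state.V[:, mid].copy())
        gb_means.append(float(mech.gamma_bar.mean()))
        u_maxes.append(float(np.abs(mech.u).max()))

    return TwitchResult(
        times=np.array(times),
        V_m_midpoint=np.array(traces),
        V_m_final=state.V.copy(),
        gamma_bar_mean=np.array(gb_means),
        u_max=np.array(u_maxes),
        final_displacement=mech.u.copy(),
        timings=timings,
        config={
            "elements3d": list(geom.elements3d),
            "n_fibers": geom.n_fibers,
            "scheme": schedule.scheme,
            "N": schedule.N,
            "K": schedule.K,
            "dt_3d_ms": schedule.dt_3d,
            "t_end_ms": t_end,
            "solver": solver,
            "seed": seed,
        },
    )


# --------------------------------------------------------------------------
# convergence studies
# --------------------------------------------------------------------------

def _reaction_trajectory(
    model: CellModel, K: int, integrator: str, dt_total: float,
    I_stim: float,
) -> float:
    """V_m after integrating the pure reaction term over [0, dt_total]."""
    y0, V0 = model.resting_state()
    V = np.array([[V0]])
    y = y0[None, None, :].copy()
    dt = dt_total / K
    for _ in range(K):
        dy1 = model.rates(y, V, I_stim)
        dV1 = -model.current(y, V, I_stim) / model.C_m
        if integrator == "euler":
            y, V = y + dt * dy1, V + dt * dV1
        else:
            yp, Vp = y + dt * dy1, V + dt * dV1
            dy2 = model.rates(yp, Vp, I_stim)
            dV2 = -model.current(yp, Vp, I_stim) / model.C_m
            y = y + 0.5 * dt * (dy1 + dy2)
            V = V + 0.5 * dt * (dV1 + dV2)
    return float(V[0, 0])


def run_convergence_study(
    target: str = "splitting",
    model: CellModel | None = None,
    dt_1d_us: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    euler_K: tuple[int, ...] = (1, 2, 4, 8, 16),
    heun_K: tuple[int, ...] = (1, 2, 4),
    reference_K: int = 1024,
    reference_dt_us: float = 0.25,
    t_end: float = 0.1,
    n_fiber_elements: int = 50,
    stimulus_amplitude: float = 1200.0,
) -> pd.DataFrame:
    """Empirical convergence orders of the 0D integrators or the splitting.

    ``target='reaction'``: pure reaction over one 1D step (0.5 μs) at a
    stimulated point, errors vs a Heun reference with ``reference_K``
    sub-steps; Euler shows first, Heun second order.

    ``target='splitting'``: single stimulated fiber over [0, t_end] ms;
    relative error of V_m at the stimulated midpoint node, Godunov
    (K=5) vs Strang (K=2) across ``dt_1d_us``, against a Strang
    reference at ``reference_dt_us``.

    Returns a table with columns (method, step_size_ms, error,
    fitted_order); a single step size yields NaN order.
    """
    model = model or HodgkinHuxleyFixture()
    from .splitting import estimate_order

    rows = []
    if target == "reaction":
        dt_total = 5e-4  # ms, one 1D step
        ref = _reaction_trajectory(model, reference_K, "heun", dt_total,
                                   stimulus_amplitude)
        for method, Ks in (("euler", euler_K), ("heun", heun_K)):
            errs, hs = [], []
            for K in Ks:
                v = _reaction_trajectory(model, K, method, dt_total,
                                         stimulus_amplitude)
                errs.append(abs(v - ref) / abs(ref))
                hs.append(dt_total / K)
            order = (estimate_order(np.array(errs), np.array(hs))
                     if len(errs) > 1 else np.nan)
            rows += [
                {"method": method, "step_size_ms": h, "error": e,
                 "fitted_order": order}
                for h, e in zip(hs, errs)
            ]
    elif target == "splitting":
        geom = build_cube_geometry(
            elements3d=(1, 1, 1),
            fibers_per_cross_section_element=(1, 1),
            elements_per_fiber_per_3d_element=n_fiber_elements,
        )
        conduction = FiberConductionParams()
        protocol = StimulusProtocol(amplitude=stimulus_amplitude,
                                    t_start=0.0, t_end=t_end)
        mid = midpoint_node(geom.nodes_per_fiber)
        state0 = single_fiber_state(model, geom)

        def final_vm(scheme: str, dt_us: float, K: int) -> float:
            dt = dt_us * 1e-3
            n = round(t_end / dt)
            sch = SplittingSchedule(
                dt_3d=t_end, N=n, K=K, scheme=scheme,
                reaction_integrator="heun" if scheme == "strang" else "euler",
            )
            s = advance(state0.copy(), sch, model, geom, conduction, protocol)
            return float(s.V[0, mid])

        ref = final_vm("strang", reference_dt_us, 2)
        for scheme, K in (("godunov", 5), ("strang", 2)):
            errs, hs = [], []
            for dt_us in dt_1d_us:
                v = final_vm(scheme, dt_us, K)
                errs.append(abs(v - ref) / abs(ref))
                hs.append(dt_us * 1e-3)
            order = (estimate_order(np.array(errs), np.array(hs))
                     if len(errs) > 1 else np.nan)
            rows += [
                {"method": scheme, "step_size_ms": h, "error": e,
                 "fitted_order": order}
                for h, e in zip(hs, errs)
            ]
    else:
        raise ValueError("target must be 'reaction' or 'splitting'")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# solver comparison
# --------------------------------------------------------------------------

def run_solver_comparison(
    element_counts: tuple[int, ...] = (25, 50, 100, 200),
    solvers: tuple[str, ...] = ("thomas", "cg", "gmres_restart30"),
    model: CellModel | None = None,
    t_end: float = 3.0,
    dt_1d: float = 5e-3,
    dt_0d: float = 1e-4,
) -> pd.DataFrame:
    """Compare the 1D linear solvers on a single stimulated fiber.

    One fiber inside one 3D element, Godunov splitting, run to
    ``t_end`` ms per solver and element count.  ``max_diff_vs_thomas``
    is the per-solve agreement on the diffusion system assembled from
    the direct solver's final state; ``final_field_drift`` is the
    accumulated end-of-run field difference over all time steps
    (informational, grows with the step count).  Wall times are
    informational; iterative divergence is recorded, not fatal.
    """
    model = model or HodgkinHuxleyFixture()
    K = round(dt_1d / dt_0d)
    rows = []
    for ne in element_counts:
        geom = build_cube_geometry(
            elements3d=(1, 1, 1),
            fibers_per_cross_section_element=(1, 1),
            elements_per_fiber_per_3d_element=ne,
        )
        conduction = FiberConductionParams()
        protocol = StimulusProtocol()
        sch = SplittingSchedule(dt_3d=t_end, N=round(t_end / dt_1d), K=K,
                                scheme="godunov")
        state0 = single_fiber_state(model, geom)
        dx = geom.extent[geom.fiber_axis] / ne
        finals: dict[str, np.ndarray] = {}
        ref_system = None
        ref_solution = None
        for solver in solvers:
            counters = Counters()
            t0 = time.perf_counter()
            try:
                s = advance(state0.copy(), sch, model, geom, conduction,
                            protocol, solver=solver, counters=counters)
                elapsed = time.perf_counter() - t0
                finals[solver] = s.V[0]
                if solver == "thomas":
                    ref_system = assemble_diffusion_system(
                        geom.nodes_per_fiber, dx, s.V[0], dt_1d,
                        "implicit_euler", conduction)
                    ref_solution = thomas_solve(ref_system)
                    x, per_solve_diff = ref_solution, 0.0
                else:
                    x = solve_linear(ref_system, method=solver,
                                     x0=finals["thomas"])
                    per_solve_diff = float(
                        np.abs(x - ref_solution).max())
                res = float(np.linalg.norm(
                    ref_system.rhs - ref_system.matvec(x)))
                rows.append({
                    "n_1d_elements": ne, "solver": solver,
                    "wall_time_s": elapsed,
                    "residual": res,
                    "thomas_ops_per_solve": (
                        counters.thomas_ops / max(counters.tridiag_solves, 1)
                        if solver == "thomas" else np.nan),
                    "max_diff_vs_thomas": per_solve_diff,
                    "final_field_drift": float(
                        np.abs(s.V[0] - finals["thomas"]).max()),
                    "status": "ok",
                })
            except RuntimeError as exc:  # iterative divergence: record
                rows.append({
                    "n_1d_elements": ne, "solver": solver,
                    "wall_time_s": np.nan, "residual": np.nan,
                    "thomas_ops_per_solve": np.nan,
                    "max_diff_vs_thomas": np.nan,
                    "final_field_drift": np.nan,
                    "status": f"diverged: {exc}",
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# partition study
# --------------------------------------------------------------------------

def run_partition_study(
    elements3d: tuple[int, int, int] = (144, 12, 12),
    n_partitions: int = 144,
    extent: tuple[float, float, float] | None = None,
    fiber_axis: str = "x",
    fibers_per_cross_section_element: tuple[int, int] = (1, 1),
    elements_per_fiber_per_3d_element: int = 2,
    compute_fiber_cuts: bool = True,
) -> pd.DataFrame:
    """Structural metrics of all axis-aligned ``n_partitions`` decompositions.

    Enumerates every ordered factorization p_x·p_y·p_z = n_partitions
    that fits the mesh, decomposes, and reports average boundary area,
    ghost counts, cut fibers and neighbor statistics, sorted ascending
    by average boundary area.  The default extent makes elements cubic
    (cube-like element blocks are then cube-like subdomains).
    """
    if extent is None:
        m = max(elements3d)
        extent = tuple(e / m for e in elements3d)  # type: ignore[assignment]
    geom = build_cube_geometry(
        extent=extent,
        elements3d=elements3d,
        fiber_axis=fiber_axis,
        fibers_per_cross_section_element=fibers_per_cross_section_element,
        elements_per_fiber_per_3d_element=elements_per_fiber_per_3d_element,
    )
    rows = []
    for sub in _ordered_factorizations(n_partitions):
        if any(p > e for p, e in zip(sub, elements3d)):
            continue
        part = decompose(geom, sub)
        ghosts = ghost_element_counts(part)
        nbrs = neighbor_sets(part)
        rows.append({
            "p_x": sub[0], "p_y": sub[1], "p_z": sub[2],
            "block_x": elements3d[0] // sub[0],
            "block_y": elements3d[1] // sub[1],
            "block_z": elements3d[2] // sub[2],
            "avg_boundary_area_cm2": average_boundary_area(part, geom),
            "mean_ghost_elements": float(np.mean(ghosts)),
            "fibers_cut": (fibers_cut(part, geom)
                           if compute_fiber_cuts else -1),
            "max_neighbors": max((len(s) for s in nbrs), default=0),
            "mean_neighbors": float(np.mean([len(s) for s in nbrs])),
        })
    df = pd.DataFrame(rows).sort_values(
        "avg_boundary_area_cm2", kind="stable"
    ).reset_index(drop=True)
    return df


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_outputs(
    bundle: TwitchResult | pd.DataFrame | dict,
    fmt: str,
    path: str | Path,
    geom: MultiScaleGeometry | None = None,
) -> Path:
    """Serialize a result bundle: csv (17 sig digits), json, or vtk.

    CSV/JSON round-trip losslessly as decimal text; VTK expects a
    TwitchResult plus its geometry and writes the final V_m field on
    the fiber polylines.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "vtk":
        from .vtk_io import write_fiber_polylines

        if not isinstance(bundle, TwitchResult) or geom is None:
            raise ValueError("vtk output needs a TwitchResult and geometry")
        return write_fiber_polylines(
            path, geom, point_data={"V_m": bundle.V_m_final.ravel()})
    if fmt == "csv":
        if isinstance(bundle, TwitchResult):
            df = pd.DataFrame(
                bundle.V_m_midpoint,
                columns=[f"fiber_{i}" for i in
                         range(bundle.V_m_midpoint.shape[1])],
            )
            df.insert(0, "t_ms", bundle.times)
        elif isinstance(bundle, pd.DataFrame):
            df = bundle
        else:
            df = pd.DataFrame(bundle)
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        if isinstance(bundle, TwitchResult):
            payload = {
                "config": bundle.config,
                "timings_s": bundle.timings,
                "t_ms": bundle.times.tolist(),
                "gamma_bar_mean": bundle.gamma_bar_mean.tolist(),
                "u_max_cm": bundle.u_max.tolist(),
            }
        elif isinstance(bundle, pd.DataFrame):
            payload = bundle.to_dict(orient="records")
        else:
            payload = bundle
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path
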