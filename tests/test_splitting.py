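"""Time integrators, splitting schemes, bookkeeping and order estimation."""

import numpy as np
import pytest

from musclesim import (
    Counters,
    FiberConductionParams,
    FiberState,
    SplittingSchedule,
    StimulusProtocol,
    build_cube_geometry,
    estimate_order,
    euler_step,
    godunov_step,
    heun_step,
    strang_step,
    theoretical_speedup,
)
from musclesim.studies import single_fiber_state


# ---------------------------------------------------------------- one-step

def test_euler_closed_form():
    lam, dt = -0.7, 0.1
    y = np.array([2.0])
    out = euler_step(y, lambda s: lam * s, dt)
    np.testing.assert_allclose(out, y * (1 + lam * dt), rtol=1e-15)
    np.testing.assert_array_equal(euler_step(y, lambda s: 0 * s, dt), y)


def test_heun_closed_form_and_eval_count():
    lam, dt = -0.7, 0.1
    y = np.array([2.0])
    calls = []

    def f(s):
        calls.append(1)
        return lam * s

    out = heun_step(y, f, dt)
    np.testing.assert_allclose(
        out, y * (1 + lam * dt + (lam * dt) ** 2 / 2), rtol=1e-15)
    assert len(calls) == 2
    np.testing.assert_array_equal(heun_step(y, lambda s: 0 * s, dt), y)


@pytest.mark.parametrize("stepper, order", [(euler_step, 1), (heun_step, 2)])
def test_scalar_decay_convergence_order(stepper, order):
    """Global error on y' = −y over [0, 1] scales as dt^order."""
    def integrate(dt):
        y = np.array([1.0])
        for _ in range(round(1.0 / dt)):
            y = stepper(y, lambda s: -s, dt)
        return y[0]

    exact = np.exp(-1.0)
    errs = np.array([abs(integrate(dt) - exact) for dt in (0.02, 0.01)])
    ratio = errs[0] / errs[1]
    assert ratio == pytest.approx(2.0**order, rel=0.10)


def test_negative_dt_rejected():
    with pytest.raises(ValueError):
        euler_step(np.ones(1), lambda s: s, -0.1)


# ---------------------------------------------------------------- schedule

def test_schedule_nesting_and_validation():
    sch = SplittingSchedule(dt_3d=1.0, N=250, K=2, scheme="strang",
                            reaction_integrator="heun")
    assert sch.dt_1d == pytest.approx(4e-3)
    assert sch.dt_0d == pytest.approx(2e-3)
    with pytest.raises(ValueError):
        SplittingSchedule(dt_3d=1.0, N=10, K=3, scheme="strang")
    with pytest.raises(ValueError):
        SplittingSchedule(dt_3d=1.0, N=0, K=1)
    base = SplittingSchedule.baseline()
    assert (base.N, base.K) == (2000, 5)
    imp = SplittingSchedule.improved()
    assert (imp.N, imp.K) == (250, 2)


# ---------------------------------------------------------------- decoupled

class _NullModel:
    """Reaction-free cell model: G_y = 0, I_ion = −I_stim."""

    state_dim = 1
    state_names = ("s",)
    C_m = 1.0
    A2_min, A2_max = 0.0, 1.0

    def rates(self, y, V, I, t=0.0):
        return np.zeros_like(y)

    def current(self, y, V, I):
        return -np.asarray(I, dtype=float) * np.ones(np.shape(V))

    def a2(self, y):
        return y[..., 0]

    def resting_state(self):
        return np.zeros(1), -65.0


@pytest.fixture
def fiber_setup(cell_model):
    geom = build_cube_geometry(
        elements3d=(1, 1, 1), fibers_per_cross_section_element=(1, 1),
        elements_per_fiber_per_3d_element=20)
    protocol = StimulusProtocol()
    return geom, protocol


def test_zero_conductivity_reduces_to_pure_reaction(cell_model, fiber_setup):
    geom, protocol = fiber_setup
    off = FiberConductionParams(sigma_eff=0.0)
    sch = SplittingSchedule(dt_3d=1e-3, N=1, K=4, scheme="godunov")
    s0 = single_fiber_state(cell_model, geom)
    out = godunov_step(s0.copy(), sch, cell_model, geom, off, protocol, 0.0)
    # oracle: K Euler sub-steps, no diffusion
    from musclesim.splitting import _reaction_substeps
    expected = _reaction_substeps(s0.copy(), cell_model, geom, protocol,
                                  0.0, sch.dt_0d, sch.K, "euler", None)
    np.testing.assert_allclose(out.V, expected.V, atol=1e-12)
    np.testing.assert_allclose(out.y, expected.y, atol=1e-14)

    sch2 = SplittingSchedule(dt_3d=1e-3, N=1, K=4, scheme="strang",
                             reaction_integrator="heun")
    out2 = strang_step(s0.copy(), sch2, cell_model, geom, off, protocol, 0.0)
    exp2 = _reaction_substeps(s0.copy(), cell_model, geom, protocol,
                              0.0, sch2.dt_0d, sch2.K, "heun", None)
    np.testing.assert_allclose(out2.V, exp2.V, atol=1e-12)


def test_zero_reaction_reduces_to_pure_diffusion(conduction, fiber_setup):
    geom, _ = fiber_setup
    protocol = StimulusProtocol(amplitude=0.0)
    model = _NullModel()
    rng = np.random.default_rng(3)
    V0 = rng.standard_normal((1, geom.nodes_per_fiber))
    s0 = FiberState(V=V0.copy(), y=np.zeros((1, geom.nodes_per_fiber, 1)))
    sch = SplittingSchedule(dt_3d=2e-3, N=1, K=2, scheme="strang",
                            reaction_integrator="heun")
    out = strang_step(s0.copy(), sch, model, geom, conduction, protocol, 0.0)
    from musclesim.monodomain import assemble_diffusion_system, thomas_solve
    dx = geom.extent[0] / geom.elements_per_fiber
    sys_ = assemble_diffusion_system(geom.nodes_per_fiber, dx, V0[0],
                                     sch.dt_1d, "crank_nicolson", conduction)
    np.testing.assert_allclose(out.V[0], thomas_solve(sys_), atol=1e-12)
    np.testing.assert_array_equal(out.y, s0.y)


def test_substep_bookkeeping_counters(cell_model, conduction, fiber_setup):
    """Godunov: K rhs calls + 1 solve; Strang: 2K rhs calls + 1 solve."""
    geom, protocol = fiber_setup
    s0 = single_fiber_state(cell_model, geom)
    c = Counters()
    sch = SplittingSchedule(dt_3d=1e-3, N=1, K=5, scheme="godunov")
    godunov_step(s0.copy(), sch, cell_model, geom, conduction, protocol,
                 0.0, counters=c)
    assert c.rhs_calls == 5
    assert c.tridiag_solves == 1
    c2 = Counters()
    sch2 = SplittingSchedule(dt_3d=1e-3, N=1, K=4, scheme="strang",
                             reaction_integrator="heun")
    strang_step(s0.copy(), sch2, cell_model, geom, conduction, protocol,
                0.0, counters=c2)
    assert c2.rhs_calls == 2 * 4
    assert c2.tridiag_solves == 1


def test_godunov_and_strang_converge_to_same_solution(
        cell_model, conduction, fiber_setup):
    """Both schemes approach one fine reference; their gap shrinks with dt."""
    from musclesim import advance
    from musclesim.monodomain import midpoint_node

    geom, protocol = fiber_setup
    mid = midpoint_node(geom.nodes_per_fiber)
    s0 = single_fiber_state(cell_model, geom)
    T = 0.02

    def run(scheme, dt_us, K):
        dt = dt_us * 1e-3
        sch = SplittingSchedule(
            dt_3d=T, N=round(T / dt), K=K, scheme=scheme,
            reaction_integrator="heun" if scheme == "strang" else "euler")
        return advance(s0.copy(), sch, cell_model, geom, conduction,
                       protocol).V[0, mid]

    gaps = [abs(run("godunov", dt, 4) - run("strang", dt, 4))
            for dt in (4.0, 1.0)]
    assert gaps[1] < gaps[0]  # schemes agree to O(dt_1D)


# ---------------------------------------------------------------- estimators

def test_estimate_order_two_point_ratios():
    assert estimate_order([4.0, 1.0], [2.0, 1.0]) == pytest.approx(2.0)
    assert estimate_order([2.0, 1.0], [2.0, 1.0]) == pytest.approx(1.0)


def test_estimate_order_noisy_regression(rng):
    h = np.array([8, 4, 2, 1, 0.5]) * 1e-3
    noise = np.exp(rng.normal(0.0, 0.05, size=h.size))
    errs = 3.0 * h**2 * noise
    assert estimate_order(errs, h) == pytest.approx(2.0, abs=0.15)


def test_estimate_order_validation():
    with pytest.raises(ValueError):
        estimate_order([1.0], [1.0])
    with pytest.raises(ValueError):
        estimate_order([1.0, -1.0], [2.0, 1.0])


def test_theoretical_speedup():
    assert theoretical_speedup(50, 1, 2, 2) == pytest.approx(12.5)
    assert theoretical_speedup(3, 2, 3, 2) == 1.0
    assert theoretical_speedup(2, 1, 1, 2) == 1.0
    with pytest.raises(ValueError):
        theoretical_speedup(1, 1, 0, 1)
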