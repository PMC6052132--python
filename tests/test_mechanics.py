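"""Finite elasticity: kinematics, constitutive law, assembly, Newton solve."""

import numpy as np
import pytest

from musclesim import (
    ConstitutiveParams,
    NewtonDivergenceError,
    assemble_system,
    build_cube_geometry,
    deformation_gradient,
    pk1_stress,
    reference_pressure,
    solve_equilibrium,
    twitch_boundary_conditions,
)
from musclesim.mechanics import (
    initial_mechanical_state,
    material_tangent,
    quadrature_det_F,
    symmetry_boundary_conditions,
    uniaxial_active_stretch_oracle,
)


@pytest.fixture
def one_element():
    return build_cube_geometry(
        elements3d=(1, 1, 1), fibers_per_cross_section_element=(2, 2),
        elements_per_fiber_per_3d_element=3)


# ---------------------------------------------------------------- kinematics

def test_deformation_gradient_identity(one_element):
    u = np.zeros((len(one_element.q2_nodes), 3))
    F = deformation_gradient(u, one_element, 0, np.zeros(3))
    np.testing.assert_allclose(F, np.eye(3), atol=1e-15)


def test_deformation_gradient_reproduces_affine_fields(one_element, rng):
    A = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    X = one_element.q2_nodes
    u = X @ (A - np.eye(3)).T
    xi = rng.uniform(-1, 1, size=(5, 3))
    F = deformation_gradient(u, one_element, 0, xi)
    np.testing.assert_allclose(F, np.broadcast_to(A, (5, 3, 3)), atol=1e-12)


def test_deformation_gradient_matches_finite_differences(one_element, rng):
    u = 0.05 * rng.standard_normal((len(one_element.q2_nodes), 3))
    xi0 = np.array([0.3, -0.2, 0.55])
    F = deformation_gradient(u, one_element, 0, xi0)

    from musclesim.mechanics import _tensor_shapes, q2_element_nodes
    ue = u[q2_element_nodes(one_element, 0)]
    h = np.array(one_element.element_size)

    def mapping(xi):
        N, _, _ = _tensor_shapes(xi[None, :])
        lo = np.zeros(3)
        X = lo + (xi + 1.0) * 0.5 * h
        return X + (N[0] @ ue)

    eps = 1e-6
    F_fd = np.empty((3, 3))
    for J in range(3):
        dxi = np.zeros(3)
        dxi[J] = eps
        # chain rule: dX_J = h_J/2 dξ_J
        F_fd[:, J] = (mapping(xi0 + dxi) - mapping(xi0 - dxi)) / (
            2 * eps * h[J] / 2)
    np.testing.assert_allclose(F, F_fd, atol=1e-6)


# ---------------------------------------------------------------- stress

def test_reference_state_is_stress_free(mech_params):
    P = pk1_stress(np.eye(3), 0.0, reference_pressure(mech_params),
                   mech_params)
    np.testing.assert_allclose(P, 0.0, atol=1e-12)


def test_active_part_vanishes_at_zero_activation(mech_params, rng):
    F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0:
        F = np.eye(3)
    p = 1.3
    P_passive = pk1_stress(F, 0.0, p, mech_params)
    P_active = pk1_stress(F, 0.4, p, mech_params)
    # difference is exactly the active term along a0
    diff = P_active - P_passive
    a0 = np.asarray(mech_params.a0)
    Fa = F @ a0
    lam = np.linalg.norm(Fa)
    expected = mech_params.sigma_max * 0.4 * np.outer(Fa, a0) / lam
    np.testing.assert_allclose(diff, expected, rtol=1e-12)


def test_inverted_deformation_rejected(mech_params):
    F = np.diag([-1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        pk1_stress(F, 0.0, 0.0, mech_params)


def _passive_energy(F, params):
    C = F.T @ F
    I1 = np.trace(C)
    I2 = 0.5 * (I1**2 - np.trace(C @ C))
    psi = params.c1 * (I1 - 3) + params.c2 * (I2 - 3)
    lam = np.linalg.norm(F @ np.asarray(params.a0))
    if lam > 1:
        psi += params.b1 * (lam**params.d - 1) ** 2
    return psi


def test_passive_stress_is_energy_gradient(mech_params, rng):
    """∂Ψ_passive/∂F via central differences vs the closed form."""
    for _ in range(4):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        J = np.linalg.det(F)
        if not 0.8 <= J <= 1.2:
            continue
        P = pk1_stress(F, 0.0, 0.0, mech_params)
        eps = 1e-6
        P_fd = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                dF = np.zeros((3, 3))
                dF[i, j] = eps
                P_fd[i, j] = (
                    _passive_energy(F + dF, mech_params)
                    - _passive_energy(F - dF, mech_params)
                ) / (2 * eps)
        scale = max(np.abs(P).max(), 1.0)
        assert np.abs(P - P_fd).max() / scale <= 1e-6


def test_material_tangent_matches_stress_differences(mech_params, rng):
    F = np.eye(3) + 0.08 * rng.standard_normal((3, 3))
    gamma, p = 0.2, 2.0
    A = material_tangent(F, np.array(gamma), np.array(p), mech_params)
    eps = 1e-6
    for k in range(3):
        for L in range(3):
            dF = np.zeros((3, 3))
            dF[k, L] = eps
            fd = (pk1_stress(F + dF, gamma, p, mech_params)
                  - pk1_stress(F - dF, gamma, p, mech_params)) / (2 * eps)
            np.testing.assert_allclose(A[..., k, L], fd, atol=2e-5)


# ---------------------------------------------------------------- assembly

def test_reference_residual_vanishes(one_element, mech_params):
    st = initial_mechanical_state(one_element, mech_params)
    R, _ = assemble_system(st, one_element, mech_params)
    assert np.linalg.norm(R) <= 1e-12


def test_residual_translation_invariant(one_element, mech_params, rng):
    """Before BC elimination, rigid translations leave the residual unchanged."""
    st = initial_mechanical_state(one_element, mech_params)
    st.u = 0.02 * rng.standard_normal(st.u.shape)
    st.gamma_bar[:] = 0.1
    R1, _ = assemble_system(st, one_element, mech_params)
    st2 = st.copy()
    st2.u = st.u + np.array([0.4, -0.7, 0.25])
    R2, _ = assemble_system(st2, one_element, mech_params)
    np.testing.assert_allclose(R1, R2, atol=1e-12)


def test_tangent_matches_fd_jacobian(one_element, mech_params, rng):
    st = initial_mechanical_state(one_element, mech_params)
    st.u += 0.02 * rng.standard_normal(st.u.shape)
    st.p += 0.5 * rng.standard_normal(st.p.shape)
    st.gamma_bar[:] = 0.1
    R0, K = assemble_system(st, one_element, mech_params)
    n_u = st.u.size
    eps = 1e-6
    cols = rng.choice(n_u + st.p.size, size=30, replace=False)
    scale = max(np.abs(K).max(), 1.0)
    for i in cols:
        plus, minus = st.copy(), st.copy()
        if i < n_u:
            plus.u.ravel()[i] += eps
            minus.u.ravel()[i] -= eps
        else:
            plus.p[i - n_u] += eps
            minus.p[i - n_u] -= eps
        Rp, _ = assemble_system(plus, one_element, mech_params)
        Rm, _ = assemble_system(minus, one_element, mech_params)
        fd = (Rp - Rm) / (2 * eps)
        col = np.asarray(K[:, i].todense()).ravel()
        assert np.abs(fd - col).max() / scale <= 1e-5


def test_reference_tangent_nullspace_is_rigid_modes(one_element, mech_params):
    """Six rigid-body modes and no pressure checkerboard before BCs."""
    st = initial_mechanical_state(one_element, mech_params)
    _, K = assemble_system(st, one_element, mech_params)
    sv = np.linalg.svd(K.toarray(), compute_uv=False)
    null = np.sum(sv < 1e-10 * sv[0])
    assert null == 6


# ---------------------------------------------------------------- solves

def test_reference_equilibrium_converges_immediately(one_element, mech_params):
    st = initial_mechanical_state(one_element, mech_params)
    bcs = twitch_boundary_conditions(one_element)
    sol, iters = solve_equilibrium(st, one_element, mech_params, bcs)
    assert iters <= 1
    np.testing.assert_allclose(sol.u, 0.0, atol=1e-14)
    detF = quadrature_det_F(sol, one_element)
    assert np.abs(detF - 1).max() <= 1e-6


def test_uniaxial_active_contraction_matches_scalar_oracle(
        one_element, mech_params):
    gamma = 0.1
    lam_oracle = uniaxial_active_stretch_oracle(mech_params, gamma)
    st = initial_mechanical_state(one_element, mech_params)
    st.gamma_bar[:] = gamma
    bcs = symmetry_boundary_conditions(one_element)
    sol, _ = solve_equilibrium(st, one_element, mech_params, bcs,
                               n_load_steps=2)
    X = one_element.q2_nodes
    face = np.abs(X[:, 0] - one_element.extent[0]) < 1e-12
    lam_fem = 1.0 + sol.u[face, 0].mean() / one_element.extent[0]
    assert abs(lam_fem - lam_oracle) <= 1e-6
    assert np.abs(quadrature_det_F(sol, one_element) - 1).max() <= 1e-6


def test_axis_permutation_objectivity(mech_params):
    """Fiber along x vs fiber along y (a 90° rotation) gives the same
    axial stretch under rotated symmetry constraints."""
    lams = []
    for axis in (0, 1):
        a0 = [0.0, 0.0, 0.0]
        a0[axis] = 1.0
        params = ConstitutiveParams(
            c1=mech_params.c1, c2=mech_params.c2, b1=mech_params.b1,
            d=mech_params.d, sigma_max=mech_params.sigma_max,
            a0=tuple(a0))
        geom = build_cube_geometry(
            elements3d=(1, 1, 1), fibers_per_cross_section_element=(1, 1),
            elements_per_fiber_per_3d_element=1,
            fiber_axis="x" if axis == 0 else "y")
        st = initial_mechanical_state(geom, params)
        st.gamma_bar[:] = 0.08
        bcs = symmetry_boundary_conditions(geom)
        sol, _ = solve_equilibrium(st, geom, params, bcs, n_load_steps=2)
        X = geom.q2_nodes
        face = np.abs(X[:, axis] - 1.0) < 1e-12
        lams.append(1.0 + sol.u[face, axis].mean())
    assert abs(lams[0] - lams[1]) <= 1e-8


def test_newton_divergence_reports_residual(one_element, mech_params):
    st = initial_mechanical_state(one_element, mech_params)
    st.gamma_bar[:] = 0.3
    bcs = symmetry_boundary_conditions(one_element)
    with pytest.raises(NewtonDivergenceError) as exc:
        solve_equilibrium(st, one_element, mech_params, bcs, max_newton=1)
    assert exc.value.residual_norm > 0
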