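# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `musclesim`, and what the test suite does and
does not demonstrate.

## Model structure and assumptions

The package couples three scales on a box-shaped muscle:

1. **0D subcellular dynamics** at every fiber node (sarcomere
   position): a system of ODEs ∂y/∂t = G_y(y, V_m, I_stim) plus the
   membrane balance C_m ∂V_m/∂t = −I_ion(y, V_m, I_stim), with the
   applied stimulus entering as an additive current (so I_stim = c
   shifts ∂V_m/∂t by exactly c/C_m).
2. **1D monodomain conduction** along each fiber, valid under equal
   intra-/extracellular anisotropy, with zero-Neumann fiber ends (no
   current leaves a fiber).
3. **3D quasi-static finite elasticity**: inertia and body forces are
   neglected, tissue is incompressible (det F = 1 via a pressure
   Lagrange multiplier), passive behavior is Mooney–Rivlin plus an
   additive transversely isotropic term, and the active stress acts
   along the fiber direction scaled by the homogenized activation γ̄.

Activation follows γ = f_fl(l_hs)·(A₂ − A₂^min)/(A₂^max − A₂^min); γ is
intentionally not clamped, so out-of-range A₂ produces slightly
negative or >1 values rather than hiding an upstream problem.
Contraction-velocity dependence of the active stress is omitted: the
intended regime is isometric or very slow contraction.

### The subcellular fixture

The framework does not prescribe a particular ionic model; any object
with state dimension, rates, current, and an A₂-like observable plugs
in. The shipped fixture combines:

- classic squid-axon membrane kinetics (gates m, h, n; g_Na = 120,
  g_K = 36, g_L = 0.3 mS/cm², E_Na = 50, E_K = −77, E_L = −54.387 mV,
  C_m = 1 μF/cm²), chosen because its excitability, stiffness and
  smoothness are well understood and all rate functions are standard;
- a two-state calcium/cross-bridge surrogate: a calcium-like
  intermediate c driven by depolarization through a smooth sigmoid
  (half-activation −20 mV, slope 5 mV; release 1/ms, decay 0.5/ms) and
  the A₂-like state a (attachment 2/ms·c toward saturation 1,
  detachment 0.1/ms). These rates were chosen once so a single twitch
  produces a physiologic-looking activation transient that rises over
  a few ms and decays over tens of ms; they are not fitted to data.

The resting state is computed by root-finding on the steady-state
current (bisection on V ∈ [−90, −40] mV, gates and surrogate at their
V-conditional steady states); A₂^min is the resting a, A₂^max its
saturation value. What passing tests show is therefore that the
*framework* — integrators, splitting orders, transfers, coupling —
behaves correctly on a genuinely excitable, stiff, smooth model. They
do not validate any quantitative physiology of a real fiber (absolute
V_m values, twitch amplitudes or timings), which would require the
detailed published subcellular chemistry with its >50 states.

### Force–length curve

f_fl is piecewise linear through (0.635, 0) — (1.1, 1) — (1.85, 0) μm
(half-sarcomere lengths), zero outside. The cited experimental curve is
not printed in the source literature, so the anchors are configuration
defaults with a plateau value of 1 at the optimum, not a claim about a
specific dataset. The reference half-sarcomere length defaults to
1.0 μm so the undeformed muscle sits on the ascending limb.

## Discretization

- **3D**: structured hexahedra, Taylor–Hood Q2 (displacement) / Q1
  (pressure), 3×3×3 Gauss quadrature for everything. The structured
  mesh gives constant diagonal element Jacobians, which the assembly
  exploits. The consistent tangent is assembled analytically (including
  the geometric, fiber, active and pressure blocks) and is verified
  against finite differences of the residual.
- **1D**: linear Lagrange elements, consistent (non-lumped) mass
  matrix — the system stays tridiagonal either way and the consistent
  choice is standard. θ-stepping with θ = 1 (implicit Euler, baseline)
  or θ = 1/2 (Crank–Nicolson, improved).
- **0D**: explicit Euler (baseline) or Heun (improved); Heun is the
  explicit trapezoidal predictor–corrector with exactly two rhs
  evaluations.

### Time splitting

With dt_3D = N·dt_1D and dt_1D = K·dt_0D, one 1D step is either

- **Godunov** (first order): K Euler reaction sub-steps, then one
  implicit Euler diffusion step; or
- **Strang** (second order): K/2 Heun sub-steps, one Crank–Nicolson
  step, K/2 Heun sub-steps (K must be even; odd K is rejected rather
  than rounded).

The stimulus is evaluated at the left endpoint of each reaction
sub-step; the source does not specify this and the choice is
deterministic and scheme-independent. In the convergence studies the
stimulus stays on during the whole measured interval, so the
discontinuity at stimulus offset never degrades the observed orders.

### Linear solvers

The tridiagonal systems are solved by a hand-written Thomas algorithm
with an instrumented, exactly affine operation count (8(n−1)+1
arithmetic operations), or by CG / restarted GMRES(30) from scipy. The
iterative tolerance 1e-5 is interpreted as residual reduction relative
to the initial residual with the previous V_m as initial guess — the
convention under which the iterative and direct solutions agree to
≤1e-6 per solve on study-sized fibers (≥100 elements). Note that the
*accumulated* iterative-vs-direct field drift over hundreds of steps is
larger (~1e-4 mV) and is reported separately by the solver study. The
unpreconditioned GMRES baseline reflects that no preconditioner is
stated for the original configuration. Inside Newton, the 3D saddle
point system is solved by direct sparse LU — appropriate at desk scale,
where the mechanics systems have a few hundred unknowns.

### Newton solve

Relative and absolute tolerance 1e-8 on the residual norm, backtracking
line search halving the step at most 40 times and accepting only
residual-reducing steps, iteration cap 50. If a full-activation solve
fails, γ̄ is ramped in equal load increments — the simplest robust
continuation, used only as a fallback. The anisotropic passive term
b₁(λ^d − 1)² (λ > 1) is one concrete realization of an additive
fiber-stiffening energy; it is C¹ but not C² at λ = 1, which has not
caused line-search trouble in practice because activation drives λ
below 1. A config switch selects whether the active stress is
normalized by the fiber stretch (default: yes, giving a constant
nominal active stress σ_max·γ̄ under uniaxial conditions).

Force–length dependence enters the active stress **only** through γ̄,
which already contains f_fl; multiplying again inside P_active would
double-count the relation. This is an interpretation of an ambiguous
formulation, made once and used consistently.

## Transfer operators

Ownership of fiber nodes is computed by index arithmetic in constant
time per node (the fiber lattice is structured): fibers sit at
transverse offsets (i+0.5)/f of the element cross-section, so no node
is ever on a transverse element boundary, and nodes on faces normal to
the fiber axis belong to the lower-index element. "Nearest Gauss
point" is measured in the element's reference coordinates with ties to
the lowest Gauss index; a Gauss point with no assigned nodes falls back
to the element mean of γ. Half-sarcomere lengths are l_hs_ref × local
stretch, with nodal stretch the mean of the adjacent segment stretches
(one-sided at fiber ends). All transfers touch only the owning element
and its own Gauss points.

## Partitioning analysis

The decomposition module is a serial structural analyzer: it reports
the quantities that drive parallel communication cost (shared boundary
area, one-layer ghost element counts, 26-connectivity neighbor sets,
cut fibers) without any message passing. Remainder elements under
non-divisible subdivisions go to the highest-index partitions. The
factorization objective minimizes the log-space variance of the block
extents (most cube-like blocks), with ties broken toward larger p_x
then p_y — the source only states that an aspect-ratio trade-off was
optimized, so the exact objective is a design choice here.

The partition-shape study (144 partitions of a 144×12×12 mesh) is run
by default on a domain with *cubic elements* (12×1×1 cm), so that
cube-like element blocks coincide with physically cube-like subdomains.
Under the per-partition shared-area metric, the 4×6×6-element blocks
attain the minimal average boundary area exactly (a three-way tie at
59/72 of the cross-section unit), and elongated rod blocks — not flat
plates — attain the maximum. No element aspect ratio makes plate blocks
the maximum while cube-like blocks remain the minimum: the two extremes
sometimes quoted together presume inconsistent element shapes. The
study reports the full sorted table so either extreme can be read off.

## Study problem sizes

All studies run serially at sizes chosen for interactive turnaround:

- reaction convergence: one stimulated point, interval 0.5 μs, Heun
  reference with K = 1024 sub-steps, Euler K ∈ {1,…,16}, Heun
  K ∈ {1,2,4} (larger Heun K drives errors toward double-precision
  round-off, ~1e-13 relative, where slope fitting is meaningless);
- splitting convergence: one 50-element fiber, [0, 0.1 ms], reference
  Strang at dt_1D = 0.25 μs;
- solver comparison: one fiber, [0, 3 ms] (1 ms in the test suite),
  100–200 elements;
- twitch: 2×2×2 elements, 6×6 fibers, [0, 1 ms].

Timing numbers produced by the twitch driver are informational; no test
asserts absolute or relative wall-clock times, since those are
hardware facts, not properties of the algorithms.

## Known limitations

- Cube geometry only; anatomical/unstructured meshes break the pillar
  partitioning concept and are out of scope.
- The incompressibility constraint is enforced weakly (mixed
  formulation); pointwise |det F − 1| ≤ 1e-6 is guaranteed only where
  the converged deformation is homogeneous (the solver tests), not for
  arbitrary inhomogeneous states.
- No bidomain/extracellular potentials, no motor-neuron recruitment
  model (stimulation is a predefined protocol, optionally with seeded
  per-fiber onset delays), no dynamics/inertia, no contact or tendon.
- The cell fixture is a surrogate: quantitative membrane or force
  trajectories are not comparable to published skeletal-muscle traces.
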