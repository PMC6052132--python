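"""Subcellular (0D) membrane/cross-bridge models and the activation parameter.

The monodomain reaction term and the mechanical activation both come
from a pointwise system of ODEs at every sarcomere position,

    dy/dt  = G_y(y, V_m, I_stim),
    dV_m/dt = -I_ion(y, V_m, I_stim) / C_m,

with the stimulus entering as an additive applied current inside
``I_ion``.  The interface is pluggable: any model exposing state
dimension, rates ``G_y``, current ``I_ion`` and an A2-like
concentration observable can drive the pipeline.

The shipped fixture couples the classic squid-axon membrane kinetics
(gates m, h, n) with a two-state calcium/cross-bridge surrogate whose
second state plays the role of the post-power-stroke cross-bridge
concentration A2.  The mechanical activation is

    gamma(y, l_hs) = f_fl(l_hs) * (A2 - A2_min) / (A2_max - A2_min),

where ``f_fl`` is a piecewise-linear force–length curve with value 1 at
the optimal half-sarcomere length and 0 outside its support.  gamma is
deliberately not clamped.

Units: mV, ms, μA/cm², μF/cm², μm (half-sarcomere lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.optimize import brentq

from .geometry import MultiScaleGeometry

__all__ = [
    "CellModel",
    "CellState",
    "ActivationParams",
    "HodgkinHuxleyFixture",
    "rhs",
    "activation_gamma",
    "force_length",
    "initial_state",
]


class CellModel(Protocol):
    """Pluggable ionic-model interface.

    ``rates`` and ``current`` are vectorized over nodes: ``y`` has shape
    ``(n_nodes, state_dim)``; ``V_m`` and ``I_stim`` shape ``(n_nodes,)``.
    Both must be deterministic in their arguments.
    """

    state_dim: int
    state_names: tuple[str, ...]
    C_m: float
    A2_min: float
    A2_max: float

    def rates(self, y: np.ndarray, V_m: np.ndarray, I_stim: np.ndarray,
              t: float) -> np.ndarray: ...

    def current(self, y: np.ndarray, V_m: np.ndarray,
                I_stim: np.ndarray) -> np.ndarray: ...

    def a2(self, y: np.ndarray) -> np.ndarray: ...

    def resting_state(self) -> tuple[np.ndarray, float]: ...


@dataclass
class CellState:
    """Per-node subcellular state: y (n_nodes, state_dim) and V_m (n_nodes,)."""

    y: np.ndarray
    V_m: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.V_m.copy())


@dataclass(frozen=True)
class ActivationParams:
    """Force–length curve anchors and the reference half-sarcomere length.

    The curve is piecewise linear through
    ``(l_min, 0) — (l_opt, 1) — (l_max, 0)`` and zero outside
    ``[l_min, l_max]``; defaults follow typical mammalian skeletal
    muscle (optimum near 1.1 μm per half sarcomere).
    """

    l_opt: float = 1.1
    l_min: float = 0.635
    l_max: float = 1.85
    l_hs_ref: float = 1.0

    def __post_init__(self) -> None:
        if not (self.l_min < self.l_opt < self.l_max):
            raise ValueError(
                "zero-force bounds must bracket the optimal length: "
                f"{self.l_min} < {self.l_opt} < {self.l_max} fails"
            )


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / (-np.expm1(-safe / y))
    return np.where(small, y * (1.0 + x / (2.0 * y)), out)


@dataclass
class HodgkinHuxleyFixture:
    """Squid-axon-style membrane kinetics plus a cross-bridge surrogate.

    State layout ``y = [m, h, n, c, a]``: three membrane gates, a
    calcium-like intermediate ``c`` driven by depolarization through a
    smooth sigmoid, and the A2-like observable ``a`` that rises with
    ``c`` toward saturation ``a_sat`` and relaxes back to rest.  The
    surrogate stands in for the detailed excitation–contraction
    pathway so every framework stage (reaction integration, gamma,
    homogenization) is exercised by a genuinely excitable model.
    """

    # membrane (classic squid-axon constants; mS/cm², mV, μF/cm²)
    g_Na: float = 120.0
    g_K: float = 36.0
    g_L: float = 0.3
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -54.387
    C_m: float = 1.0
    # calcium / cross-bridge surrogate (1/ms rates)
    k_rel: float = 1.0
    k_dec: float = 0.5
    k_on: float = 2.0
    k_off: float = 0.1
    a_sat: float = 1.0
    V_ca: float = -20.0
    k_ca: float = 5.0

    state_dim: int = field(default=5, init=False)
    state_names: tuple[str, ...] = field(
        default=("m", "h", "n", "c", "a"), init=False
    )

    def __post_init__(self) -> None:
        self._rest: tuple[np.ndarray, float] | None = None
        y0, _ = self.resting_state()
        self.A2_min = float(y0[4])
        self.A2_max = float(self.a_sat)

    # -- gate kinetics ---------------------------------------------------
    @staticmethod
    def _alpha_beta(V: np.ndarray) -> tuple[np.ndarray, ...]:
        a_m = 0.1 * _vtrap(V + 40.0, 10.0)
        b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
        a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
        b_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
        a_n = 0.01 * _vtrap(V + 55.0, 10.0)
        b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
        return a_m, b_m, a_h, b_h, a_n, b_n

    def _sigmoid_ca(self, V: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(V - self.V_ca) / self.k_ca))

    def rates(self, y: np.ndarray, V_m: np.ndarray, I_stim: np.ndarray,
              t: float = 0.0) -> np.ndarray:
        y = np.atleast_2d(y)
        V = np.asarray(V_m, dtype=float)
        m, h, n, c, a = (y[..., i] for i in range(5))
        a_m, b_m, a_h, b_h, a_n, b_n = self._alpha_beta(V)
        s = self._sigmoid_ca(V)
        G = np.empty_like(y)
        G[..., 0] = a_m * (1.0 - m) - b_m * m
        G[..., 1] = a_h * (1.0 - h) - b_h * h
        G[..., 2] = a_n * (1.0 - n) - b_n * n
        G[..., 3] = self.k_rel * s * (1.0 - c) - self.k_dec * c
        G[..., 4] = self.k_on * c * (self.a_sat - a) - self.k_off * a
        return G

    def current(self, y: np.ndarray, V_m: np.ndarray,
                I_stim: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(y)
        V = np.asarray(V_m, dtype=float)
        m, h, n = y[..., 0], y[..., 1], y[..., 2]
        i_ion = (
            self.g_Na * m**3 * h * (V - self.E_Na)
            + self.g_K * n**4 * (V - self.E_K)
            + self.g_L * (V - self.E_L)
        )
        return i_ion - np.asarray(I_stim, dtype=float)

    def a2(self, y: np.ndarray) -> np.ndarray:
        return np.atleast_2d(y)[..., 4]

    def resting_state(self) -> tuple[np.ndarray, float]:
        """Resting fixed point (I_stim = 0), found by root-finding.

        The gates and the surrogate are at their steady states for a
        candidate potential; the rest potential is the root of the
        steady-state ionic current.
        """
        if self._rest is not None:
            return self._rest[0].copy(), self._rest[1]

        def y_inf(V: float) -> np.ndarray:
            V_arr = np.asarray([V])
            a_m, b_m, a_h, b_h, a_n, b_n = self._alpha_beta(V_arr)
            s = float(self._sigmoid_ca(V_arr)[0])
            c = self.k_rel * s / (self.k_rel * s + self.k_dec)
            a = self.k_on * c * self.a_sat / (self.k_on * c + self.k_off)
            return np.array(
                [
                    float((a_m / (a_m + b_m))[0]),
                    float((a_h / (a_h + b_h))[0]),
                    float((a_n / (a_n + b_n))[0]),
                    c,
                    a,
                ]
            )

        def steady_current(V: float) -> float:
            return float(
                self.current(y_inf(V)[None, :], np.asarray([V]),
                             np.asarray([0.0]))[0]
            )

        V_rest = brentq(steady_current, -90.0, -40.0, xtol=1e-14)
        self._rest = (y_inf(V_rest), float(V_rest))
        return self._rest[0].copy(), self._rest[1]


def rhs(
    model: CellModel,
    y: np.ndarray,
    V_m: np.ndarray,
    I_stim: np.ndarray | float,
    t: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reaction right-hand side: (dy/dt, dV_m/dt).

    dV_m/dt = -I_ion(y, V_m, I_stim)/C_m, with the applied stimulus
    contributing +I_stim/C_m through the additive current convention.

    Raises
    ------
    FloatingPointError
        If the state contains non-finite entries (reports node ids).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    V = np.atleast_1d(np.asarray(V_m, dtype=float))
    I = np.broadcast_to(np.asarray(I_stim, dtype=float), V.shape)
    bad = ~(np.isfinite(y).all(axis=-1) & np.isfinite(V))
    if bad.any():
        raise FloatingPointError(
            f"non-finite cell state at node(s) {np.flatnonzero(bad).tolist()}"
        )
    dy = model.rates(y, V, I, t)
    dV = -model.current(y, V, I) / model.C_m
    return dy, dV


def force_length(l_hs: float | np.ndarray, act: ActivationParams) -> np.ndarray:
    """Piecewise-linear force–length factor in [0, 1].

    1 at the optimal half-sarcomere length, 0 at and beyond the
    zero-force bounds, linear in between.

    Raises
    ------
    ValueError
        For non-positive lengths.
    """
    l = np.asarray(l_hs, dtype=float)
    if np.any(l <= 0):
        raise ValueError("half-sarcomere length must be positive")
    rising = (l - act.l_min) / (act.l_opt - act.l_min)
    falling = (act.l_max - l) / (act.l_max - act.l_opt)
    f = np.where(l <= act.l_opt, rising, falling)
    return np.clip(f, 0.0, 1.0)


def activation_gamma(
    A2: float | np.ndarray,
    l_hs: float | np.ndarray,
    model: CellModel,
    act: ActivationParams,
) -> np.ndarray:
    """Activation gamma = f_fl(l_hs) · (A2 − A2_min)/(A2_max − A2_min).

    Not clamped: slightly negative or >1 values are possible for
    out-of-range A2 and are passed through.
    """
    if model.A2_max == model.A2_min:
        raise ZeroDivisionError("A2_max must differ from A2_min")
    A2 = np.asarray(A2, dtype=float)
    return force_length(l_hs, act) * (A2 - model.A2_min) / (
        model.A2_max - model.A2_min
    )


def initial_state(model: CellModel, geom: MultiScaleGeometry) -> CellState:
    """All sarcomere points at the model's resting state and potential."""
    y0, V0 = model.resting_state()
    n = geom.n_sarcomere_points
    return CellState(
        y=np.tile(y0, (n, 1)),
        V_m=np.full(n, V0, dtype=float),
    )
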