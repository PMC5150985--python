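"""Piecewise dimple-depth dynamics of a vertical jump off the water surface.

The jump is governed by a single dimensionless second-order ODE for the
scaled dimple depth H(tau) = h/l_c over the stroke phase tau = omega*t:

    H'' = 2 L cos(2 tau) - (2 / (M Omega^2)) * W(tau, H) * H        (+ 1/Omega^2
                                                           with body weight on)

where L is the scaled maximal leg reach, M the body-mass index, Omega the
scaled stroke rate, and W the wetted-length taper: W = 1 while the legs push
(full tibia+tarsus wetted), and

    W = [(pi/2 - tau) / (pi/2 - tau_m)] * (H / H_m)

after the dimple maximum (tau_m, H_m) while the legs close and gradually
disengage.  The restoring term is the linearized capillary force — the weight
of water displaced by the dimples, F = 2 sigma C l_w h / l_c for a thin
superhydrophobic cylinder — truncated by surface rupture when H reaches the
quasi-static sinking depth sqrt(2).

The dimensionless body velocity follows kinematically from h = l_s - y:

    V(tau) = Omega * (L sin(2 tau) - H'),

identical (for weightless flight) to the impulse integral V = Omega *
int (2 W H / (M Omega^2)) dtau, which is carried as an extra state and used
as a momentum-consistency diagnostic.

A jump terminates in exactly one of four modes:

* ``meniscus_breaking`` — H reaches sqrt(2) and the surface ruptures; thrust
  is assumed lost at that instant.
* ``post_takeoff_closing`` — the leg tips regain zero depth (H = 0) before
  the stroke ends; legs finish rotating in the air.
* ``pre_takeoff_closing`` — the stroke completes (tau = pi/2) with H > 0;
  the body then coasts while the relic dimple relaxes at rate H' = -V/Omega
  until H = 0.
* ``no_takeoff`` — the body cannot leave the surface after the stroke.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp

from .physics import DomainError, FluidProperties

__all__ = [
    "JumpMode",
    "JumpParameters",
    "SolverOptions",
    "JumpResult",
    "SolverError",
    "NoTakeoffError",
    "dimple_ode_rhs",
    "simulate_jump",
    "linear_pushing_oracle",
    "resonant_maximum",
    "takeoff_velocity_physical",
]

SQRT2 = math.sqrt(2.0)
HALF_PI = 0.5 * math.pi


class SolverError(RuntimeError):
    """The ODE integrator failed to converge."""


class NoTakeoffError(RuntimeError):
    """A physical takeoff quantity was requested for a non-takeoff jump."""


class JumpMode(str, Enum):
    POST_TAKEOFF_CLOSING = "post_takeoff_closing"
    PRE_TAKEOFF_CLOSING = "pre_takeoff_closing"
    MENISCUS_BREAKING = "meniscus_breaking"
    NO_TAKEOFF = "no_takeoff"


class Stage(str, Enum):
    PUSHING = "pushing"
    CLOSING = "closing"
    POST_CLOSING = "post_closing"


@dataclass(frozen=True)
class JumpParameters:
    """Dimensionless parameters of one jump.

    ``initial_depth`` is the (negligible) dimple depth pre-formed by the
    resting insect's weight; results are insensitive to it over
    [1e-8, 1e-4].  ``breaking_depth`` is the rupture threshold sqrt(2) in
    units of l_c.  ``include_weight`` adds the body-weight term 1/Omega^2 to
    the dimple equation and gravitational deceleration to post-stroke flight
    (off by default: the weight is an order of magnitude below the capillary
    force).
    """

    Omega: float
    mass_index: float
    reach: float
    include_weight: bool = False
    initial_depth: float = 1.0e-6
    breaking_depth: float = SQRT2

    def __post_init__(self) -> None:
        if not (self.Omega > 0 and self.mass_index > 0 and self.reach > 0):
            raise DomainError("Omega, M and L must all be strictly positive")
        if not 0 <= self.initial_depth < 1e-2:
            raise DomainError("initial depth must satisfy 0 <= eps << 1")

    @property
    def stiffness(self) -> float:
        """k = 2/(M Omega^2), the scaled capillary spring constant."""
        return 2.0 / (self.mass_index * self.Omega**2)


@dataclass(frozen=True)
class SolverOptions:
    """Integrator contract: adaptive, stiff-capable, with event detection."""

    method: str = "LSODA"
    rtol: float = 1.0e-8
    atol: float = 1.0e-10
    max_step: float = 0.05
    n_dense: int = 200  # trajectory samples per stage


@dataclass(frozen=True)
class JumpResult:
    """Outcome of one simulated jump (all quantities dimensionless).

    The trajectory arrays cover the integrated phases with per-sample stage
    labels.  ``V_t`` is the dimensionless takeoff velocity
    v_t/sqrt(g l_c) evaluated at the takeoff (or rupture) instant; ``tau_t``
    the corresponding phase.  ``impulse`` is the accumulated momentum
    integral int F dt / (m sqrt(g l_c)) along the trajectory.
    """

    params: JumpParameters
    mode: JumpMode
    tau: np.ndarray
    H: np.ndarray
    Hprime: np.ndarray
    V: np.ndarray
    impulse: np.ndarray
    stage: np.ndarray
    tau_m: float | None
    H_m: float | None
    tau_b: float | None
    tau_t: float | None
    tau_c: float | None
    V_t: float | None

    @property
    def has_takeoff(self) -> bool:
        return self.mode is not JumpMode.NO_TAKEOFF

    def escape_time(self, omega: float) -> float:
        """Physical escape time t_t = tau_t / omega (s)."""
        if self.tau_t is None:
            raise NoTakeoffError("jump has no takeoff instant")
        return self.tau_t / omega

    def to_frame(self):
        """Trajectory as a pandas DataFrame (tau, H, Hprime, V, stage)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "tau": self.tau,
                "H": self.H,
                "Hprime": self.Hprime,
                "V": self.V,
                "stage": self.stage,
            }
        )

    def summary(self) -> dict:
        """Scalar outcomes as a JSON-serializable dict."""
        return {
            "mode": self.mode.value,
            "Omega": self.params.Omega,
            "mass_index": self.params.mass_index,
            "reach": self.params.reach,
            "tau_m": self.tau_m,
            "H_m": self.H_m,
            "tau_b": self.tau_b,
            "tau_t": self.tau_t,
            "tau_c": self.tau_c,
            "V_t": self.V_t,
        }


def dimple_ode_rhs(
    tau: float,
    state,
    params: JumpParameters,
    stage: Stage,
    stage_context: tuple[float, float] | None = None,
):
    """Right-hand side (H', H'') of the dimple equation in a given stage.

    ``stage_context`` carries (tau_m, H_m) and is required in the closing
    stage, where the wetted-length taper W depends on both.  In the
    post-closing stage the legs are stationary and the body is ballistic, so
    both the drive and the capillary term vanish.
    """
    H, Hp = state[0], state[1]
    if stage is Stage.PUSHING:
        drive = 2.0 * params.reach * math.cos(2.0 * tau)
        W = 1.0
    elif stage is Stage.CLOSING:
        if stage_context is None:
            raise DomainError("closing stage requires (tau_m, H_m) context")
        tau_m, H_m = stage_context
        if H_m <= params.initial_depth:
            raise DomainError("degenerate dimple: closing stage with H_m ~ 0")
        drive = 2.0 * params.reach * math.cos(2.0 * tau)
        W = ((HALF_PI - tau) / (HALF_PI - tau_m)) * (H / H_m)
    elif stage is Stage.POST_CLOSING:
        drive = 0.0
        W = 0.0
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown stage {stage}")
    force = params.stiffness * W * H
    acc = drive - force
    if params.include_weight and stage is not Stage.POST_CLOSING:
        acc += 1.0 / params.Omega**2
    return Hp, acc


def _rhs_with_impulse(tau, y, params: JumpParameters, stage: Stage, ctx):
    """(H, H', J) with J the scaled impulse integral int k W H dtau."""
    Hp, acc = dimple_ode_rhs(tau, y, params, stage, ctx)
    if stage is Stage.CLOSING:
        tau_m, H_m = ctx
        W = ((HALF_PI - tau) / (HALF_PI - tau_m)) * (y[0] / H_m)
    elif stage is Stage.PUSHING:
        W = 1.0
    else:
        W = 0.0
    return [Hp, acc, params.stiffness * W * y[0]]


def _velocity(params: JumpParameters, tau, Hprime):
    """Kinematic body velocity V = Omega (L sin 2tau - H') during the stroke."""
    return params.Omega * (params.reach * np.sin(2.0 * np.asarray(tau)) - np.asarray(Hprime))


def simulate_jump(
    params: JumpParameters,
    options: SolverOptions | None = None,
) -> JumpResult:
    """Integrate one jump through its stages and classify its mode.

    Pushing starts from (H, H') = (eps, 0) at tau = 0.  Events, in order of
    occurrence: surface rupture (H = breaking depth, rising), the first
    interior dimple maximum (H' = 0 falling, switching to the closing
    stage), leg-tip takeoff (H = 0, falling) and stroke completion
    (tau = pi/2), after which a relic dimple relaxes kinematically under the
    coasting body.
    """
    opts = options or SolverOptions()
    p = params
    ivp_kw = dict(method=opts.method, rtol=opts.rtol, atol=opts.atol,
                  max_step=opts.max_step, dense_output=True)

    def ev_break(tau, y, *a):
        return y[0] - p.breaking_depth

    ev_break.terminal, ev_break.direction = True, 1.0

    def ev_max(tau, y, *a):
        return y[1]

    ev_max.terminal, ev_max.direction = True, -1.0

    def ev_zero(tau, y, *a):
        return y[0]

    ev_zero.terminal, ev_zero.direction = True, -1.0

    segments: list[tuple[np.ndarray, np.ndarray, Stage]] = []

    # --- pushing stage -----------------------------------------------------
    sol = solve_ivp(
        _rhs_with_impulse, (0.0, HALF_PI), [p.initial_depth, 0.0, 0.0],
        args=(p, Stage.PUSHING, None), events=[ev_break, ev_max], **ivp_kw,
    )
    if sol.status == -1:
        raise SolverError(f"pushing stage failed: {sol.message} (params={p})")
    tau_end = sol.t[-1]
    grid = np.linspace(0.0, tau_end, opts.n_dense)
    segments.append((grid, sol.sol(grid), Stage.PUSHING))

    if sol.t_events[0].size:  # surface rupture while pushing
        tau_b = float(sol.t_events[0][0])
        yb = sol.y_events[0][0]
        return _finish_breaking(p, segments, tau_b, yb)

    if sol.t_events[1].size:
        tau_m = float(sol.t_events[1][0])
        ym = sol.y_events[1][0]
        H_m = float(ym[0])
    else:
        # Capillary spring too weak to reverse the dimple before the stroke
        # ends (k -> 0 limit): treat the stroke end as the maximum.
        tau_m = HALF_PI
        ym = sol.y[:, -1]
        H_m = float(ym[0])
        return _finish_post_closing(p, segments, tau_m, H_m, float(ym[1]),
                                    float(ym[2]), tau_m=None)

    # --- closing stage -----------------------------------------------------
    ctx = (tau_m, H_m)
    sol2 = solve_ivp(
        _rhs_with_impulse, (tau_m, HALF_PI), [H_m, 0.0, float(ym[2])],
        args=(p, Stage.CLOSING, ctx), events=[ev_break, ev_zero], **ivp_kw,
    )
    if sol2.status == -1:
        raise SolverError(f"closing stage failed: {sol2.message} (params={p})")
    tau_end2 = sol2.t[-1]
    if tau_end2 > tau_m:
        grid2 = np.linspace(tau_m, tau_end2, opts.n_dense)
        segments.append((grid2, sol2.sol(grid2), Stage.CLOSING))

    if sol2.t_events[0].size:  # rupture during closing (rare)
        tau_b = float(sol2.t_events[0][0])
        return _finish_breaking(p, segments, tau_b, sol2.y_events[0][0],
                                tau_m=tau_m, H_m=H_m)

    if sol2.t_events[1].size:  # leg tips reach zero depth before stroke end
        tau_t = float(sol2.t_events[1][0])
        yt = sol2.y_events[1][0]
        V_t = float(_velocity(p, tau_t, yt[1]))
        if p.include_weight:
            V_t = V_t  # weight already inside the integrated dynamics
        tau_arr, H, Hp, V, J, stg = _assemble(p, segments)
        return JumpResult(p, JumpMode.POST_TAKEOFF_CLOSING, tau_arr, H, Hp, V, J,
                          stg, tau_m, H_m, None, tau_t, None, V_t)

    yc = sol2.y[:, -1]
    return _finish_post_closing(p, segments, HALF_PI, float(yc[0]),
                                float(yc[1]), float(yc[2]), tau_m=tau_m, H_m=H_m)


def _finish_breaking(p, segments, tau_b, yb, tau_m=None, H_m=None) -> JumpResult:
    """Rupture ends thrust instantly; takeoff velocity is V at rupture."""
    V_t = float(_velocity(p, tau_b, yb[1]))
    tau, H, Hp, V, J, stg = _assemble(p, segments)
    return JumpResult(p, JumpMode.MENISCUS_BREAKING, tau, H, Hp, V, J, stg,
                      tau_m, H_m, tau_b, tau_b, None, V_t)


def _finish_post_closing(p, segments, tau_c, H_c, Hp_c, J_c, tau_m, H_m=None) -> JumpResult:
    """Stroke completed with a relic dimple: coast until H = 0 (or fail).

    With weight off the body coasts at constant V and the dimple relaxes
    linearly, H' = -V/Omega; with weight on V decreases at rate 1/Omega and
    H(tau) is quadratic, which may never reach zero (no takeoff).
    """
    V_c = float(_velocity(p, tau_c, Hp_c))
    if H_m is None:
        H_m = H_c
    if V_c <= 0.0:
        tau, H, Hp, V, J, stg = _assemble(p, segments)
        return JumpResult(p, JumpMode.NO_TAKEOFF, tau, H, Hp, V, J, stg,
                          tau_m, H_m, None, None, tau_c, None)
    if p.include_weight:
        disc = V_c**2 - 2.0 * H_c
        if disc < 0.0:
            tau, H, Hp, V, J, stg = _assemble(p, segments)
            return JumpResult(p, JumpMode.NO_TAKEOFF, tau, H, Hp, V, J, stg,
                              tau_m, H_m, None, None, tau_c, None)
        dtau = p.Omega * (V_c - math.sqrt(disc))
        V_t = V_c - dtau / p.Omega
    else:
        dtau = p.Omega * H_c / V_c
        V_t = V_c
    tau_t = tau_c + dtau
    # analytic coast segment for the trajectory arrays
    n = 50
    g = np.linspace(tau_c, tau_t, n)
    d = g - tau_c
    if p.include_weight:
        Vseg = V_c - d / p.Omega
        Hseg = H_c - (V_c * d - d**2 / (2.0 * p.Omega)) / p.Omega
    else:
        Vseg = np.full(n, V_c)
        Hseg = H_c - V_c * d / p.Omega
    coast = np.vstack([np.clip(Hseg, 0.0, None), -Vseg / p.Omega, np.full(n, J_c)])
    segments.append((g, coast, Stage.POST_CLOSING))
    tau, H, Hp, V, J, stg = _assemble(p, segments, coast_V=(tau_c, V_c))
    return JumpResult(p, JumpMode.PRE_TAKEOFF_CLOSING, tau, H, Hp, V, J, stg,
                      tau_m, H_m, None, tau_t, tau_c, float(V_t))


def _assemble(p, segments, coast_V=None):
    """Concatenate stage segments into trajectory arrays with V attached."""
    taus, Hs, Hps, Js, Vs, stages = [], [], [], [], [], []
    for grid, y, stage in segments:
        taus.append(grid)
        Hs.append(y[0])
        Hps.append(y[1])
        Js.append(y[2])
        if stage is Stage.POST_CLOSING:
            tau_c, V_c = coast_V
            if p.include_weight:
                Vs.append(V_c - (grid - tau_c) / p.Omega)
            else:
                Vs.append(np.full(grid.size, V_c))
        else:
            Vs.append(_velocity(p, grid, y[1]))
        stages.append(np.full(grid.size, stage.value, dtype=object))
    return (np.concatenate(taus), np.concatenate(Hs), np.concatenate(Hps),
            np.concatenate(Vs), np.concatenate(Js),
            np.concatenate(stages))


def linear_pushing_oracle(params: JumpParameters, tau) -> np.ndarray:
    """Closed-form pushing-stage solution with W = 1 and weight off.

    The pushing stage is a driven linear oscillator H'' + k H = 2L cos 2tau
    with k = 2/(M Omega^2) and H(0) = H'(0) = 0, whose solution is

        H = 2L (cos 2tau - cos(sqrt(k) tau)) / (k - 4)      for k != 4,
        H = (L/2) tau sin 2tau                               at resonance.

    Used as an independent cross-check of the numerical integration; not on
    the simulation path.
    """
    tau = np.asarray(tau, dtype=float)
    k = params.stiffness
    L = params.reach
    if abs(k - 4.0) < 1.0e-6:
        return 0.5 * L * tau * np.sin(2.0 * tau)
    return 2.0 * L * (np.cos(2.0 * tau) - np.cos(math.sqrt(k) * tau)) / (k - 4.0)


def resonant_maximum() -> tuple[float, float]:
    """(tau_m, H_m / L) of the resonant (k = 4) pushing solution.

    The first interior maximum of H = (L/2) tau sin 2tau solves
    tan x = -x with x = 2 tau_m in (pi/2, pi).
    """
    from scipy.optimize import brentq

    x = brentq(lambda x: math.sin(x) + x * math.cos(x), math.pi / 2 + 1e-9, math.pi - 1e-9,
               xtol=1e-14)
    tau_m = x / 2.0
    return tau_m, 0.5 * tau_m * math.sin(x)


def takeoff_velocity_physical(result: JumpResult, fluid: FluidProperties) -> float:
    """Physical takeoff velocity v_t = V_t * sqrt(g l_c) (m s^-1)."""
    if result.V_t is None:
        raise NoTakeoffError("jump did not take off; no takeoff velocity")
    return result.V_t * fluid.velocity_scale
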