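"""Stroke-rate optimization: sweeps, ridges, thresholds and the phase diagram.

For a fixed body-mass index M, sweeping the scaled reach L and stroke rate
Omega maps the takeoff velocity V_t and escape phase tau_t, and classifies
each cell's jump mode.  Along each L-column, V_t rises with Omega up to the
meniscus-breaking threshold and collapses beyond it, so the optimal stroke
for long-legged insects sits just below rupture.  The breaking threshold
collapses as Omega_crit * M^(1/2) ~ 1/L, giving a three-mode phase diagram in
(Omega M^(1/2), L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    SQRT2,
    JumpMode,
    JumpParameters,
    JumpResult,
    SolverError,
    SolverOptions,
    simulate_jump,
)
from .physics import DomainError, FluidProperties, InsectMorphology, dimensionless_groups

__all__ = [
    "SweepGrid",
    "RidgePoint",
    "PhasePoint",
    "default_L_grid",
    "default_Omega_grid",
    "golden_section_max",
    "sweep_takeoff_map",
    "optimal_ridge",
    "optimal_omega_at",
    "breaking_threshold",
    "regime_boundary_L",
    "place_jumps_on_phase_diagram",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def golden_section_max(f, a: float, b: float, rel_tol: float = 1.0e-4) -> float:
    """Derivative-free maximizer of f on [a, b] (golden-section search).

    Used to refine ridge optima off the sweep grid; derivative-free because
    V_t(Omega) is kinked at the meniscus-breaking threshold.
    """
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > rel_tol * max(abs(b), 1.0):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)

#: Default grids matching the visual ranges of the published sweeps.
def default_L_grid() -> np.ndarray:
    return np.linspace(1.0, 7.0, 61)


def default_Omega_grid() -> np.ndarray:
    return np.linspace(0.2, 6.0, 117)


@dataclass(frozen=True)
class SweepGrid:
    """Per-cell jump summaries over an (L, Omega) grid at fixed M.

    ``V_t`` and ``tau_t`` are NaN where the jump does not take off or where
    the solver failed; ``mode`` carries the per-cell label (``"failed"`` for
    solver failures, which never abort a sweep).
    """

    mass_index: float
    L_grid: np.ndarray
    Omega_grid: np.ndarray
    V_t: np.ndarray  # shape (nL, nOmega)
    tau_t: np.ndarray
    mode: np.ndarray  # object array of str

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (M, L, Omega, V_t, tau_t, mode)."""
        LL, OO = np.meshgrid(self.L_grid, self.Omega_grid, indexing="ij")
        return pd.DataFrame(
            {
                "M": self.mass_index,
                "L": LL.ravel(),
                "Omega": OO.ravel(),
                "V_t": self.V_t.ravel(),
                "tau_t": self.tau_t.ravel(),
                "mode": self.mode.ravel(),
            }
        )


@dataclass(frozen=True)
class RidgePoint:
    """Optimal stroke rate at one L: argmax of V_t over Omega."""

    L: float
    Omega_opt: float
    V_t_opt: float
    mode: str
    tau_t: float


@dataclass(frozen=True)
class PhasePoint:
    """One jump placed on the (Omega M^(1/2), L) phase diagram."""

    x: float  # Omega * sqrt(M)
    y: float  # L
    mode: str
    tag: str = ""


def _cell(M: float, L: float, Omega: float, options: SolverOptions | None,
          include_weight: bool = False) -> JumpResult | None:
    try:
        return simulate_jump(
            JumpParameters(Omega=Omega, mass_index=M, reach=L,
                           include_weight=include_weight),
            options,
        )
    except SolverError:
        return None


def sweep_takeoff_map(
    M: float,
    L_grid: np.ndarray | None = None,
    Omega_grid: np.ndarray | None = None,
    options: SolverOptions | None = None,
    include_weight: bool = False,
) -> SweepGrid:
    """Simulate every (L, Omega) cell at fixed M.

    Deterministic given solver settings; per-cell solver failures are
    recorded as ``"failed"`` cells rather than aborting the sweep.
    """
    Ls = default_L_grid() if L_grid is None else np.asarray(L_grid, dtype=float)
    Os = default_Omega_grid() if Omega_grid is None else np.asarray(Omega_grid, dtype=float)
    for g, name in ((Ls, "L"), (Os, "Omega")):
        if g.size < 2 or np.any(np.diff(g) <= 0) or np.any(g <= 0):
            raise DomainError(f"{name} grid must be ascending, positive, size >= 2")
    V = np.full((Ls.size, Os.size), np.nan)
    T = np.full_like(V, np.nan)
    mode = np.full(V.shape, "failed", dtype=object)
    for i, L in enumerate(Ls):
        for j, Om in enumerate(Os):
            res = _cell(M, L, Om, options, include_weight)
            if res is None:
                continue
            mode[i, j] = res.mode.value
            if res.V_t is not None:
                V[i, j] = res.V_t
                T[i, j] = res.tau_t
    return SweepGrid(M, Ls, Os, V, T, mode)


def optimal_omega_at(
    M: float,
    L: float,
    Omega_grid: np.ndarray | None = None,
    options: SolverOptions | None = None,
    refine_rel: float = 1.0e-4,
) -> RidgePoint:
    """Takeoff-velocity-maximizing Omega at a single L.

    Coarse argmax over the Omega grid (ties broken toward the smallest
    Omega), then golden-section refinement between the neighbouring grid
    points to the requested relative width.  Golden section is
    derivative-free, which matters because V_t(Omega) is kinked/discontinuous
    at the meniscus-breaking threshold.
    """
    Os = default_Omega_grid() if Omega_grid is None else np.asarray(Omega_grid, dtype=float)

    def vt(Om: float) -> float:
        res = _cell(M, L, Om, options)
        if res is None or res.V_t is None:
            return -np.inf
        return res.V_t

    vals = np.array([vt(Om) for Om in Os])
    if not np.any(np.isfinite(vals)):
        raise SolverError(f"all cells failed along L={L}, M={M}")
    i = int(np.argmax(vals))  # argmax returns the first (smallest-Omega) tie
    a = Os[max(i - 1, 0)]
    b = Os[min(i + 1, Os.size - 1)]
    Om_opt = golden_section_max(vt, a, b, refine_rel)
    res = _cell(M, L, Om_opt, options)
    if res is None:
        raise SolverError(f"refined optimum failed at L={L}, M={M}")
    return RidgePoint(L=float(L), Omega_opt=float(Om_opt),
                      V_t_opt=float(res.V_t) if res.V_t is not None else np.nan,
                      mode=res.mode.value,
                      tau_t=float(res.tau_t) if res.tau_t is not None else np.nan)


def optimal_ridge(
    grid: SweepGrid,
    options: SolverOptions | None = None,
    refine_rel: float = 1.0e-4,
) -> list[RidgePoint | None]:
    """Per-L optimum Omega*(L) and V_t*(L) refined off the sweep grid.

    Returns one :class:`RidgePoint` per L in the sweep (None for all-failed
    columns).  The optimal Omega is non-increasing in L: longer legs must
    rotate slower to stay below the rupture threshold.
    """
    out: list[RidgePoint | None] = []
    for i, L in enumerate(grid.L_grid):
        if not np.any(np.isfinite(grid.V_t[i])):
            out.append(None)
            continue
        out.append(optimal_omega_at(grid.mass_index, L, grid.Omega_grid,
                                    options, refine_rel))
    return out


def breaking_threshold(
    L: float,
    M: float,
    Omega_bracket: tuple[float, float] = (0.05, 20.0),
    options: SolverOptions | None = None,
    rel_tol: float = 1.0e-4,
) -> float | None:
    """Critical stroke rate Omega_crit(L, M) for meniscus breaking.

    Bisection between a non-breaking and a breaking simulation.  Below
    L = sqrt(2) breaking is impossible (even an unopposed stroke only reaches
    dimple depth L), so ``None`` is returned.
    """
    if L <= SQRT2:
        return None
    lo, hi = Omega_bracket

    def breaks(Om: float) -> bool:
        res = _cell(M, L, Om, options)
        return res is not None and res.mode is JumpMode.MENISCUS_BREAKING

    if breaks(lo):
        raise DomainError("lower Omega bracket already breaks the surface")
    while not breaks(hi):
        hi *= 2.0
        if hi > 1.0e4:
            return None
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if breaks(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def regime_boundary_L(
    M: float,
    L_range: tuple[float, float] = (2.0, 6.0),
    Omega_grid: np.ndarray | None = None,
    options: SolverOptions | None = None,
    tol: float = 0.02,
) -> float | None:
    """Reach L* separating pre- and post-takeoff-closing optimal jumps.

    Bisects L, probing the mode of the refined optimal-ridge jump at each
    L; the boundary is the largest L whose optimum is a pre-takeoff-closing
    jump.  Returns ``None`` when the whole range lies on one side.
    """
    lo, hi = L_range

    def pre(L: float) -> bool:
        return optimal_omega_at(M, L, Omega_grid, options).mode == JumpMode.PRE_TAKEOFF_CLOSING.value

    pre_lo, pre_hi = pre(lo), pre(hi)
    if pre_lo == pre_hi:
        return None
    while (hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if pre(mid) == pre_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def place_jumps_on_phase_diagram(
    observations: list[tuple[InsectMorphology, float, FluidProperties]],
    options: SolverOptions | None = None,
    tags: list[str] | None = None,
    flexibility: float = 1.0,
) -> list[PhasePoint]:
    """Place observed/synthetic jumps on the (Omega M^(1/2), L) diagram.

    Each observation is a (morphology, omega, fluid) triple; the point's mode
    label comes from simulating the jump at its own dimensionless
    parameters.
    """
    pts: list[PhasePoint] = []
    for idx, (morph, omega, fluid) in enumerate(observations):
        g = dimensionless_groups(morph, fluid, omega, flexibility=flexibility)
        res = _cell(g.mass_index, g.reach, g.Omega, options)
        mode = res.mode.value if res is not None else "failed"
        tag = tags[idx] if tags else (morph.name or "")
        pts.append(PhasePoint(x=g.Omega * math.sqrt(g.mass_index),
                              y=g.reach, mode=mode, tag=tag))
    return pts
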