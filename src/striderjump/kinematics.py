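"""Sinusoidal leg-stroke model and stroke-rate estimators.

During a vertical jump the four propelling legs rotate synchronously at an
(assumed constant) angular velocity omega, sweeping the stroke phase
omega*t from 0 to pi/2.  The vertical distance from leg tips to the body
centre follows

    l_s(t) = y_i + (Delta_l / 2) * (1 - cos 2*omega*t),

which rises from the resting height y_i to the full leg length l_l, and its
derivative is the bell-shaped downward leg speed v_s = omega*Delta_l*sin(2
omega t) peaking at phase pi/4.  Two estimators recover omega from measured
traces: the peak estimator omega = v_s,max / Delta_l and the time-averaged
angular-rate estimator from a leg-angle series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physics import DomainError

__all__ = [
    "StrokeModel",
    "leg_reach",
    "leg_speed",
    "leg_angle",
    "sample_stroke",
    "estimate_omega_from_peak",
    "estimate_omega_from_angle_series",
]


@dataclass(frozen=True)
class StrokeModel:
    """Constant-rate sinusoidal leg stroke.

    Attributes
    ----------
    omega : float
        Angular velocity of leg rotation (rad s^-1), constant during a jump.
    max_reach : float
        Delta_l = l_l - y_i (m), maximal downward reach of the legs.
    rest_height : float
        y_i (m), body-centre height at stroke start.
    """

    omega: float
    max_reach: float
    rest_height: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise DomainError("omega must be strictly positive")
        if not self.max_reach > 0:
            raise DomainError("max_reach must be strictly positive")
        if self.rest_height < 0:
            raise DomainError("rest_height must be non-negative")

    @property
    def stroke_duration(self) -> float:
        """Time (s) for the phase to sweep [0, pi/2]."""
        return 0.5 * math.pi / self.omega


def _check_phase(phase: np.ndarray) -> None:
    if np.any(phase < -1e-12) or np.any(phase > math.pi / 2 + 1e-12):
        raise DomainError("stroke phase omega*t must lie in [0, pi/2]")


def leg_reach(t, model: StrokeModel):
    """Vertical leg-tip distance l_s(t) below the body centre (m).

    Defined on stroke phases omega*t in [0, pi/2]; rises monotonically from
    the resting height to the full leg length.
    """
    t = np.asarray(t, dtype=float)
    phase = model.omega * t
    _check_phase(phase)
    out = model.rest_height + 0.5 * model.max_reach * (1.0 - np.cos(2.0 * phase))
    return out if out.ndim else float(out)


def leg_speed(t, model: StrokeModel):
    """Downward leg speed v_s(t) = omega * Delta_l * sin(2 omega t) (m s^-1).

    Exact time derivative of :func:`leg_reach`; zero at both stroke ends and
    maximal (omega*Delta_l) at phase pi/4.
    """
    t = np.asarray(t, dtype=float)
    phase = model.omega * t
    _check_phase(phase)
    out = model.omega * model.max_reach * np.sin(2.0 * phase)
    return out if out.ndim else float(out)


def leg_angle(t, model: StrokeModel):
    """Leg angle theta(t) (rad) from the initial leg attitude.

    Derived output for trace emulation only: theta = arcsin of the fractional
    leg extension, clamped to [0, 1], so theta sweeps 0 to pi/2 over the
    stroke.  Not part of the dimple dynamics.
    """
    t = np.asarray(t, dtype=float)
    ls = np.asarray(leg_reach(t, model), dtype=float)
    frac = np.clip((ls - model.rest_height) / model.max_reach, 0.0, 1.0)
    out = np.arcsin(frac)
    return out if out.ndim else float(out)


def sample_stroke(model: StrokeModel, times: np.ndarray) -> "np.recarray":
    """Sample (t, l_s, v_s, theta) at the given times (record array)."""
    times = np.asarray(times, dtype=float)
    rec = np.recarray(times.shape, dtype=[("t", float), ("l_s", float), ("v_s", float), ("theta", float)])
    rec.t = times
    rec.l_s = leg_reach(times, model)
    rec.v_s = leg_speed(times, model)
    rec.theta = leg_angle(times, model)
    return rec


def estimate_omega_from_peak(v_s_max: float, delta_l: float) -> float:
    """Stroke rate from the peak leg speed: omega = v_s,max / Delta_l.

    The sinusoidal stroke peaks at v_s,max = omega*Delta_l, so the quotient
    recovers omega exactly on noiseless data.  On noisy data the maximum of a
    noisy series is biased upward; smooth before taking the peak.
    """
    if delta_l <= 0:
        raise DomainError("degenerate morphology: Delta_l must be positive")
    if v_s_max <= 0:
        raise DomainError("peak leg speed must be positive")
    return v_s_max / delta_l


def estimate_omega_from_angle_series(times, angles) -> float:
    """Time-averaged angular rate from a leg-angle series (rad s^-1).

    Averages the finite-difference derivative of theta(t) over the sampled
    stroke, weighting each interval by its duration (which telescopes to the
    secant slope (theta_N - theta_0)/(t_N - t_0)).  For a noiseless model
    trace covering the full stroke this equals omega exactly, since theta
    sweeps pi/2 in time (pi/2)/omega.

    Requires at least 3 samples with strictly increasing time stamps.
    """
    t = np.asarray(times, dtype=float)
    th = np.asarray(angles, dtype=float)
    if t.size < 3:
        raise DomainError("need at least 3 samples to estimate an angular rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DomainError("time stamps must be strictly increasing")
    dtheta = np.diff(th)
    # dt-weighted mean of dtheta/dt == secant slope over the record
    return float(np.sum(dtheta) / np.sum(dt))
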