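"""Luenberger-type state observers for the circadian oscillator.

An observer is a copy of the plant driven by an output-injection term:
``dz/dt = f(z, u) + K (y - C z)`` with ``y = C x`` measured from the plant.
Only a few states are monitored — the graphical observability analysis
(:mod:`circobs.observability`) shows that any single one of the five
suffices.  The shipped configurations cover the single-sensor observer on
the mRNA (gain ``k``, output scaling ``c``) and the dual-sensor observer on
mRNA plus unphosphorylated protein (gains ``alpha, beta``, scalings
``c1, c2``).

The error ``e = x - z`` obeys ``de/dt = (A - KC) e + [f(x,u) - f(z,u)]``;
its convergence to zero is what the Lyapunov analysis in
:mod:`circobs.stability` certifies and what :func:`coupled_simulate`
measures numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (DEFAULT_ATOL, DEFAULT_DT, DEFAULT_METHOD, DEFAULT_RTOL,
                    N_STATES, InputSignal, IntegrationError, ModelParameters,
                    Trajectory, _integrate_piecewise, vector_field)

__all__ = [
    "ObserverConfig",
    "ErrorTrajectory",
    "observer_rhs",
    "coupled_simulate",
    "convergence_time",
]

#: Observer states may go negative; evaluating x/(K+x) near x = -K is a pole.
POLE_GUARD = 1e-6


class MichaelisPoleError(FloatingPointError):
    """An observer state came within ``POLE_GUARD`` of a Michaelis pole -K."""


@dataclass(frozen=True)
class ObserverConfig:
    """Sensor selection, output scalings and injection gains.

    ``sensors`` are 1-based state indices (``1`` = mRNA ... ``5`` = nuclear
    protein), matching the ``x1..x5`` naming used throughout.  ``scalings``
    are the nonzero entries of the output matrix C, ``gains`` the nonzero
    entries of the injection matrix K; sensor ``i`` contributes
    ``gain * (y - scaling * z_i)`` to equation ``i`` of the observer only.
    """

    sensors: tuple[int, ...]
    gains: tuple[float, ...]
    scalings: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensors", tuple(int(s) for s in self.sensors))
        object.__setattr__(self, "gains", tuple(float(g) for g in self.gains))
        object.__setattr__(self, "scalings", tuple(float(c) for c in self.scalings))
        if len(set(self.sensors)) != len(self.sensors):
            raise ValueError("sensor indices must be distinct")
        if any(not 1 <= s <= N_STATES for s in self.sensors):
            raise ValueError(f"sensor indices must lie in 1..{N_STATES}")
        if not len(self.sensors) == len(self.gains) == len(self.scalings):
            raise ValueError("sensors, gains and scalings must have equal length")

    @classmethod
    def single(cls, sensor: int = 1, gain: float = 5.0, scaling: float = 1.0) -> "ObserverConfig":
        return cls((sensor,), (gain,), (scaling,))

    @classmethod
    def dual(cls, alpha: float, beta: float, c1: float, c2: float,
             sensors: tuple[int, int] = (1, 2)) -> "ObserverConfig":
        return cls(tuple(sensors), (alpha, beta), (c1, c2))

    def measure(self, x: np.ndarray) -> np.ndarray:
        """Plant output y = C x for this sensor set."""
        x = np.asarray(x, dtype=float)
        return np.array([c * x[s - 1] for s, c in zip(self.sensors, self.scalings)])


@dataclass
class ErrorTrajectory:
    """Estimation error e(t) = x(t) - z(t) on a shared time grid."""

    times: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.errors.shape != (self.times.size, N_STATES):
            raise ValueError("errors must have shape (len(times), 5)")

    def max_abs(self) -> np.ndarray:
        return np.abs(self.errors).max(axis=1)

    def euclidean(self) -> np.ndarray:
        return np.linalg.norm(self.errors, axis=1)

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "ErrorTrajectory":
        if traj.errors is None:
            raise ValueError("trajectory carries no observer errors")
        return cls(traj.times, traj.errors)


def _guard_poles(z: np.ndarray, p: ModelParameters) -> None:
    # only the Michaelis constants paired with each state matter
    pairs = ((p.Km, z[0]), (p.K1, z[1]), (p.K2, z[2]), (p.K3, z[2]),
             (p.K4, z[3]), (p.Kd, z[3]))
    for K, zi in pairs:
        if abs(K + zi) < POLE_GUARD:
            raise MichaelisPoleError(
                f"observer state {zi:g} within {POLE_GUARD:g} of Michaelis pole -{K:g}")


def observer_rhs(t: float,
                 z: Sequence[float],
                 p: ModelParameters,
                 u: InputSignal,
                 cfg: ObserverConfig,
                 y: Sequence[float]) -> np.ndarray:
    """Observer time derivatives: plant field at ``z`` plus output injection.

    ``y`` is the measured plant output (one entry per sensor, already
    scaled).  With all gains zero this reduces exactly to the plant field.
    The observer state is *not* restricted to the nonnegative cone; a guard
    raises :class:`MichaelisPoleError` if a Michaelis denominator vanishes.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    _guard_poles(z, p)
    dz = vector_field(z, p, float(u(t)))
    for (s, k, c, yi) in zip(cfg.sensors, cfg.gains, cfg.scalings, y):
        dz[s - 1] += k * (yi - c * z[s - 1])
    return dz


def coupled_simulate(p: ModelParameters,
                     u: InputSignal,
                     x0: Sequence[float],
                     z0: Sequence[float],
                     cfg: ObserverConfig,
                     t_span: tuple[float, float],
                     dt: float = DEFAULT_DT,
                     method: str = DEFAULT_METHOD,
                     rtol: float = DEFAULT_RTOL,
                     atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate plant and observer as one 10-dimensional system.

    The plant is measured continuously (``y = C x(t)`` from the concurrently
    integrated plant state), so the stored error ``e = x - z`` is exactly
    the solution of the error dynamics.  Returns a :class:`Trajectory`
    carrying plant states, observer states and errors on one grid.
    """
    x0 = np.asarray(x0, dtype=float)
    z0 = np.asarray(z0, dtype=float)
    if x0.shape != (N_STATES,) or z0.shape != (N_STATES,):
        raise ValueError("x0 and z0 must each have 5 components")
    if np.any(x0 < 0):
        raise ValueError("plant initial state must be nonnegative")
    if not t_span[1] > t_span[0]:
        raise ValueError("t_span must be increasing")
    t_grid = np.arange(t_span[0], t_span[1] + 0.5 * dt, dt)

    def fun(t, w):
        x, z = w[:N_STATES], w[N_STATES:]
        u_val = float(u(t))
        _guard_poles(z, p)
        dx = vector_field(x, p, u_val)
        dz = vector_field(z, p, u_val)
        for s, k, c in zip(cfg.sensors, cfg.gains, cfg.scalings):
            dz[s - 1] += k * c * (x[s - 1] - z[s - 1])
        return np.concatenate([dx, dz])

    w = _integrate_piecewise(fun, np.concatenate([x0, z0]), t_grid,
                             u.breakpoints(), method, rtol, atol)
    xs, zs = w[:, :N_STATES], w[:, N_STATES:]
    if u.nonnegative and np.any(xs < -1e-7):
        raise IntegrationError(f"plant state reached {xs.min():g} nM")
    xs[(xs < 0.0) & (xs > -1e-7)] = 0.0  # round-off only
    return Trajectory(t_grid, xs, observer_states=zs, errors=xs - zs)


def convergence_time(err: ErrorTrajectory | Trajectory, tol: float = 1e-3) -> float:
    """Earliest sampled time after which max_i |e_i| stays below ``tol``
    through the end of the trajectory.

    Returns ``math.inf`` if the error never settles below ``tol`` (including
    a final sample at or above it).  An error that re-crosses ``tol`` late
    is timed from after its *last* crossing.
    """
    if isinstance(err, Trajectory):
        err = ErrorTrajectory.from_trajectory(err)
    if not tol > 0:
        raise ValueError("tol must be positive")
    if err.times.size == 0:
        raise ValueError("empty error trajectory")
    above = err.max_abs() >= tol
    if above[-1]:
        return math.inf
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return float(err.times[0])
    return float(err.times[idx[-1] + 1])
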