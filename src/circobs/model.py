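"""Core circadian oscillator model.

A five-variable negative-feedback oscillator for the *Drosophila* per /
*Neurospora* frq circuit: mRNA (``x1``) is translated into a cytosolic
protein (``x2``) that is reversibly phosphorylated twice (``x3``, ``x4``);
the doubly phosphorylated form is degraded or shuttled into the nucleus
(``x5``), where it represses transcription of its own gene through a Hill
function.  All degradation/(de)phosphorylation steps follow Michaelis-Menten
kinetics.  An additive external input ``u(t)`` acts on the mRNA equation and
models environmental forcing (light).  With the default parameter set and
``u = 0`` the model settles onto a stable limit cycle with a near-circadian
period.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

__all__ = [
    "ModelParameters",
    "InputSignal",
    "Trajectory",
    "IntegrationError",
    "NoOscillationError",
    "michaelis_term",
    "hill_repression",
    "rhs",
    "vector_field",
    "simulate",
    "estimate_period",
    "random_initial_state",
]

# Numerical policy: sharp Michaelis kinetics (Kd = 0.1 nM) call for a
# stiff-capable adaptive integrator at tight tolerances.
DEFAULT_METHOD = "LSODA"
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: Output sampling step (h) for dense trajectories.
DEFAULT_DT = 0.05
#: Integrator round-off may produce negligible negative concentrations.
#: Values in (-TOL_NEG, 0) are clamped to 0 on output; anything more
#: negative raises :class:`IntegrationError`.
TOL_NEG = 1e-7
#: Transient discarded before period estimation (h).
DEFAULT_TRANSIENT_CUT = 48.0

STATE_LABELS = ("x1", "x2", "x3", "x4", "x5")
N_STATES = 5


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced non-physical states."""


class NoOscillationError(ValueError):
    """Raised when a signal has too few maxima to define a period."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the oscillator.

    Defaults are the standard reference set for this model.  ``vs``..``vd``
    are maximum
    rates (nM/h), ``ks``/``k1``/``k2`` first-order rate constants (1/h),
    ``KI``..``Kd`` Michaelis/inhibition constants (nM) and ``n`` the Hill
    coefficient of the transcriptional repression (dimensionless).
    """

    vs: float = 0.5
    vm: float = 0.3
    v1: float = 6.0
    v2: float = 3.0
    v3: float = 6.0
    v4: float = 3.0
    vd: float = 1.5
    ks: float = 2.0
    k1: float = 2.0
    k2: float = 1.0
    KI: float = 2.0
    Km: float = 0.2
    K1: float = 1.5
    K2: float = 2.0
    K3: float = 1.5
    K4: float = 2.0
    Kd: float = 0.1
    n: int = 4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "n":
                if not float(value).is_integer() or value < 1:
                    raise ValueError(f"Hill coefficient n must be a positive integer, got {value}")
            elif not value > 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {value}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# input signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputSignal:
    """External forcing ``u(t)`` on the mRNA equation (nM/h).

    Kinds
    -----
    ``zero``
        ``u = 0`` for all t (the autonomous oscillator).
    ``sinusoid``
        ``u = amplitude * sin(t)`` with t in hours — period 2*pi h, not 24 h.
    ``step``
        0 for ``t <= onset``, ``level`` afterwards.
    ``pulse``
        ``level`` on the open window ``onset < t < offset``, 0 outside.
    """

    kind: str = "zero"
    amplitude: float = 0.0
    onset: float = 0.0
    offset: float = 0.0
    level: float = 0.0

    _KINDS = ("zero", "sinusoid", "step", "pulse")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown input kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "pulse" and not self.offset > self.onset:
            raise ValueError("pulse requires offset > onset")

    def __call__(self, t: float) -> float:
        if self.kind == "zero":
            return 0.0
        if self.kind == "sinusoid":
            return self.amplitude * math.sin(t)
        if self.kind == "step":
            return self.level if t > self.onset else 0.0
        # pulse: open on both sides
        return self.level if self.onset < t < self.offset else 0.0

    @property
    def nonnegative(self) -> bool:
        """True when u(t) >= 0 for all t.

        With nonnegative forcing the closed positive orthant is forward
        invariant (each derivative is nonnegative on its zero face), so any
        material negativity indicates solver failure.  A negative-going
        input (e.g. the sinusoid) can push the mRNA genuinely below zero
        when nuclear repression has throttled production — the model is
        still well defined there and is integrated as written.
        """
        if self.kind == "zero":
            return True
        if self.kind == "sinusoid":
            return self.amplitude == 0.0
        return self.level >= 0.0

    def breakpoints(self) -> tuple[float, ...]:
        """Times where u is discontinuous; integration is split there."""
        if self.kind == "step":
            return (self.onset,)
        if self.kind == "pulse":
            return (self.onset, self.offset)
        return ()

    @classmethod
    def zero(cls) -> "InputSignal":
        return cls("zero")

    @classmethod
    def sinusoid(cls, amplitude: float) -> "InputSignal":
        return cls("sinusoid", amplitude=amplitude)

    @classmethod
    def step(cls, onset: float, level: float) -> "InputSignal":
        return cls("step", onset=onset, level=level)

    @classmethod
    def pulse(cls, onset: float, offset: float, level: float) -> "InputSignal":
        return cls("pulse", onset=onset, offset=offset, level=level)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled solution on a strictly increasing time grid (hours).

    ``states`` holds the plant (shape ``(len(times), 5)``); coupled
    plant-observer runs additionally carry ``observer_states`` and
    ``errors = states - observer_states`` on the same grid.
    """

    times: np.ndarray
    states: np.ndarray
    observer_states: np.ndarray | None = None
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d grid")
        if self.states.shape != (self.times.size, N_STATES):
            raise ValueError("states must have shape (len(times), 5)")
        for name in ("observer_states", "errors"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.states.shape:
                    raise ValueError(f"{name} must match states' shape")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.times.size

    @property
    def has_observer(self) -> bool:
        return self.observer_states is not None

    def max_abs_error(self) -> np.ndarray:
        """max_i |e_i(t)| per sample."""
        if self.errors is None:
            raise ValueError("trajectory carries no observer errors")
        return np.abs(self.errors).max(axis=1)

    def euclidean_error(self) -> np.ndarray:
        if self.errors is None:
            raise ValueError("trajectory carries no observer errors")
        return np.linalg.norm(self.errors, axis=1)

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.times}
        for i, lbl in enumerate(STATE_LABELS):
            data[lbl] = self.states[:, i]
        if self.observer_states is not None:
            for i in range(N_STATES):
                data[f"z{i + 1}"] = self.observer_states[:, i]
        if self.errors is not None:
            for i in range(N_STATES):
                data[f"e{i + 1}"] = self.errors[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        # full double precision round-trip
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        states = df[list(STATE_LABELS)].to_numpy()
        obs = err = None
        if "z1" in df.columns:
            obs = df[[f"z{i}" for i in range(1, 6)]].to_numpy()
        if "e1" in df.columns:
            err = df[[f"e{i}" for i in range(1, 6)]].to_numpy()
        return cls(df["t"].to_numpy(), states, obs, err)


# ---------------------------------------------------------------------------
# kinetic primitives
# ---------------------------------------------------------------------------

def michaelis_term(K: float, x: float) -> float:
    """Saturating occupancy factor ``x / (K + x)`` in [0, 1).

    Requires K > 0 and x >= 0; monotone increasing in x.
    """
    if not K > 0:
        raise ValueError(f"Michaelis constant must be positive, got {K}")
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"concentration must be nonnegative, got {x}")
    return x / (K + x)


def hill_repression(vs: float, KI: float, n: int, x5: float) -> float:
    """Repressed transcription rate ``vs * KI^n / (KI^n + x5^n)``.

    Decreasing sigmoid in the nuclear-protein concentration ``x5``;
    algebraically ``vs * (1 - michaelis_term(KI**n, x5**n))``.
    """
    if not (vs > 0 and KI > 0):
        raise ValueError("vs and KI must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    if np.any(np.asarray(x5) < 0):
        raise ValueError(f"concentration must be nonnegative, got {x5}")
    KIn = KI ** n
    return vs * KIn / (KIn + x5 ** n)


def vector_field(x: np.ndarray, p: ModelParameters, u_value: float) -> np.ndarray:
    """The raw five-component right-hand side at state ``x``, input value
    ``u_value``, with no domain checks (used by the observer, whose state
    may transiently leave the nonnegative cone)."""
    x1, x2, x3, x4, x5 = x
    KIn = p.KI ** p.n
    dx1 = p.vs * KIn / (KIn + x5 ** p.n) - p.vm * x1 / (p.Km + x1) + u_value
    dx2 = p.ks * x1 - p.v1 * x2 / (p.K1 + x2) + p.v2 * x3 / (p.K2 + x3)
    dx3 = (p.v1 * x2 / (p.K1 + x2) - p.v2 * x3 / (p.K2 + x3)
           - p.v3 * x3 / (p.K3 + x3) + p.v4 * x4 / (p.K4 + x4))
    dx4 = (p.v3 * x3 / (p.K3 + x3) - p.v4 * x4 / (p.K4 + x4)
           - p.vd * x4 / (p.Kd + x4) - p.k1 * x4 + p.k2 * x5)
    dx5 = p.k1 * x4 - p.k2 * x5
    return np.array([dx1, dx2, dx3, dx4, dx5])


def rhs(t: float, x: Sequence[float], p: ModelParameters, u: InputSignal) -> np.ndarray:
    """Time derivatives of the five concentrations (nM/h).

    States must be nonnegative up to solver round-off: components below
    ``-TOL_NEG`` raise, tiny negatives are tolerated (the adaptive solver
    may overshoot zero by less than its absolute tolerance).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -TOL_NEG):
        raise ValueError(f"negative state outside solver tolerance: {x}")
    return vector_field(x, p, float(u(t)))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _integrate_piecewise(fun, y0, t_grid, breakpoints, method, rtol, atol):
    """Integrate ``fun`` over ``t_grid`` splitting at input discontinuities
    so the solver never steps across a jump.  Returns samples at t_grid."""
    t0, t1 = t_grid[0], t_grid[-1]
    cuts = sorted({float(b) for b in breakpoints if t0 < b < t1})
    edges = [t0, *cuts, t1]
    out = np.empty((len(t_grid), len(y0)))
    y = np.asarray(y0, dtype=float)
    pos = 0
    for a, b in zip(edges[:-1], edges[1:]):
        # grid points inside (a, b]; the very first point is y0 itself
        sel = (t_grid > a) & (t_grid <= b)
        t_eval = t_grid[sel]
        if a == t0:
            out[0] = y
            pos = 1
        sol = solve_ivp(fun, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval if t_eval.size else None, dense_output=False)
        if not sol.success:
            raise IntegrationError(f"solver failed on [{a}, {b}]: {sol.message}")
        if t_eval.size:
            out[pos:pos + t_eval.size] = sol.y.T
            pos += t_eval.size
        y = sol.y[:, -1] if sol.y.size else y
    return out


def simulate(p: ModelParameters,
             u: InputSignal,
             x0: Sequence[float],
             t_span: tuple[float, float],
             dt: float = DEFAULT_DT,
             method: str = DEFAULT_METHOD,
             rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate the oscillator over ``t_span`` and sample on a uniform grid.

    Parameters
    ----------
    p, u, x0
        Kinetic constants, forcing signal and nonnegative initial state.
    t_span
        ``(t_start, t_end)`` in hours, increasing.
    dt
        Output grid step (hours).  The trajectory stores this grid, not the
        solver's internal steps.

    Raises
    ------
    IntegrationError
        On solver failure or if any sampled state drops below ``-TOL_NEG``.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (N_STATES,):
        raise ValueError("x0 must have 5 components")
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    if not t_span[1] > t_span[0]:
        raise ValueError("t_span must be increasing")
    t_grid = np.arange(t_span[0], t_span[1] + 0.5 * dt, dt)

    def fun(t, x):
        return vector_field(x, p, float(u(t)))

    ys = _integrate_piecewise(fun, x0, t_grid, u.breakpoints(), method, rtol, atol)
    if u.nonnegative and np.any(ys < -TOL_NEG):
        worst = ys.min()
        raise IntegrationError(f"state reached {worst:g} nM, below -{TOL_NEG:g}")
    ys[(ys < 0.0) & (ys > -TOL_NEG)] = 0.0  # round-off only
    return Trajectory(t_grid, ys)


def estimate_period(traj: Trajectory,
                    variable_index: int = 0,
                    transient_cut: float = DEFAULT_TRANSIENT_CUT) -> float:
    """Mean spacing (h) of successive maxima of one variable after a
    transient cut.

    Raises :class:`NoOscillationError` when fewer than 3 maxima remain — a
    constant or decaying signal has no period.
    """
    mask = traj.times >= transient_cut
    signal = traj.states[mask, variable_index]
    times = traj.times[mask]
    if signal.size < 3:
        raise NoOscillationError("trajectory too short after transient cut")
    peaks, _ = find_peaks(signal)
    if peaks.size < 3:
        raise NoOscillationError(
            f"no oscillation detected: {peaks.size} maxima after t={transient_cut} h")
    return float(np.diff(times[peaks]).mean())


def random_initial_state(seed: int, low: float = 0.0, high: float = 2.5) -> np.ndarray:
    """Componentwise-uniform random nonnegative state in [low, high] nM.

    Deterministic in ``seed``.  The default range covers the unforced limit
    cycle's excursion.
    """
    if not (0 <= low < high):
        raise ValueError(f"require 0 <= low < high, got ({low}, {high})")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, N_STATES)
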