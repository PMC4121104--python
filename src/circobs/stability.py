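"""Lyapunov machinery for observer-error convergence.

The error dynamics of the single-sensor observer are linearized exactly via
the mean value theorem: for each Michaelis term there is a point ``xi``
between plant and observer coordinates with
``g(K,x) - g(K,z) = K/(K+xi)^2 * (x - z)``, and similarly for the Hill
repression.  Substituting these slopes into the derivative of
``V(e) = 1/2 sum e_i^2`` yields the quadratic form ``V̇ = eᵀ Q e`` with a
symmetric 5x5 matrix Q whose entries depend on the mean-value points and,
through its (1,1) entry only, on the injection gain ``k`` and scaling ``c``.
``Q < 0`` (negative definite) for all admissible mean-value points is a
sufficient condition for global asymptotic convergence of the observer.

Because the mean-value points are unknown a priori (they lie between the
plant and observer trajectories), certification scans Q over a box of
candidate points.  This is a *grid certificate*, not a rigorous interval
proof.  Note that the cross terms (2,3) and (3,4) of Q do not shrink with
``k``: on realistic state boxes the sufficient condition can fail even
though simulations converge — the certifiers report that honestly instead
of asserting success.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters

__all__ = [
    "MeanValuePoints",
    "QEvaluation",
    "StateBox",
    "BoxCertificate",
    "mvt_slope",
    "hill_slope",
    "build_Q",
    "is_negative_definite",
    "certify_over_box",
    "minimal_certifying_gain",
]

#: "negative" for eigenvalues means < -EIG_TOL * max(1, ||Q||_2).
EIG_TOL = 1e-12


@dataclass(frozen=True)
class MeanValuePoints:
    """The seven mean-value points the Q matrix is evaluated at.

    ``xi3``/``xi3p`` are both proxies for the second protein form (they
    belong to Michaelis terms with constants K2 and K3 respectively), and
    ``xi4``/``xi4p`` both proxy the third form (constants K4 and Kd); they
    need not coincide, so they are treated as independent coordinates.
    """

    xi1: float
    xi2: float
    xi3: float
    xi3p: float
    xi4: float
    xi4p: float
    xi5: float

    def __post_init__(self) -> None:
        for name in ("xi1", "xi2", "xi3", "xi3p", "xi4", "xi4p", "xi5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def constant(cls, value: float) -> "MeanValuePoints":
        return cls(*([value] * 7))


@dataclass
class QEvaluation:
    """A concrete Q matrix with its spectrum and definiteness verdict."""

    Q: np.ndarray
    eigenvalues: np.ndarray  # sorted descending
    negative_definite: bool


@dataclass(frozen=True)
class StateBox:
    """Per-variable concentration bounds (nM), lower >= 0."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        lo = tuple(float(v) for v in self.lower)
        hi = tuple(float(v) for v in self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if len(lo) != 5 or len(hi) != 5:
            raise ValueError("box needs 5 lower and 5 upper bounds")
        if any(l < 0 for l in lo):
            raise ValueError("lower bounds must be nonnegative")
        if any(h < l for l, h in zip(lo, hi)):
            raise ValueError("upper bounds must dominate lower bounds")

    @classmethod
    def from_trajectory(cls, traj, pad: float = 0.0) -> "StateBox":
        """Componentwise min/max of a simulated trajectory, optionally
        padded outward (lower bound floored at 0)."""
        lo = np.clip(traj.states.min(axis=0) - pad, 0.0, None)
        hi = traj.states.max(axis=0) + pad
        return cls(tuple(lo), tuple(hi))


def mvt_slope(K: float, xi: float) -> float:
    """Mean-value-theorem slope ``K / (K + xi)^2`` of a Michaelis term.

    Positive, decreasing in xi, equal to 1/K at xi = 0.
    """
    if not K > 0:
        raise ValueError(f"Michaelis constant must be positive, got {K}")
    if np.any(np.asarray(xi) < 0):
        raise ValueError(f"mean-value point must be nonnegative, got {xi}")
    return K / (K + xi) ** 2


def hill_slope(vs: float, KI: float, n: int, xi5: float) -> float:
    """Magnitude of the Hill-repression slope at ``xi5``:
    ``n vs KI^n xi5^(n-1) / (KI^n + xi5^n)^2``.  Zero at xi5 = 0 for n >= 2.
    """
    if not (vs > 0 and KI > 0):
        raise ValueError("vs and KI must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    if np.any(np.asarray(xi5) < 0):
        raise ValueError(f"mean-value point must be nonnegative, got {xi5}")
    KIn = KI ** n
    return n * vs * KIn * xi5 ** (n - 1) / (KIn + xi5 ** n) ** 2


def _assemble_Q(p: ModelParameters, gain: float, scaling: float,
                a, b, c, d, e, f, h):
    """Build Q from precomputed slope terms (scalars or broadcastable
    arrays): a=vm*s(Km,xi1), b=v1*s(K1,xi2), c=v2*s(K2,xi3),
    d=v3*s(K3,xi3p), e=v4*s(K4,xi4), f=vd*s(Kd,xi4p), h=hill slope(xi5)."""
    shape = np.broadcast(a, b, c, d, e, f, h).shape
    Q = np.zeros(shape + (5, 5))
    Q[..., 0, 0] = -a - gain * scaling
    Q[..., 1, 1] = -b
    Q[..., 2, 2] = -(c + d)
    Q[..., 3, 3] = -(e + f) - p.k1
    Q[..., 4, 4] = -p.k2
    Q[..., 0, 1] = Q[..., 1, 0] = p.ks / 2
    Q[..., 0, 4] = Q[..., 4, 0] = -h / 2
    Q[..., 1, 2] = Q[..., 2, 1] = (c + b) / 2
    Q[..., 2, 3] = Q[..., 3, 2] = (e + d) / 2
    Q[..., 3, 4] = Q[..., 4, 3] = (p.k1 + p.k2) / 2
    return Q


def build_Q(p: ModelParameters, gain: float, scaling: float,
            mv: MeanValuePoints) -> QEvaluation:
    """The symmetric matrix of the quadratic form ``V̇ = eᵀ Q e`` at given
    mean-value points.

    Only entry (1,1) depends on the injection gain (it carries the extra
    ``-gain*scaling``); entry (5,5) is the constant ``-k2``.  The (1,5)
    entry carries the Hill cross term with its minus sign.
    """
    Q = _assemble_Q(
        p, gain, scaling,
        p.vm * mvt_slope(p.Km, mv.xi1),
        p.v1 * mvt_slope(p.K1, mv.xi2),
        p.v2 * mvt_slope(p.K2, mv.xi3),
        p.v3 * mvt_slope(p.K3, mv.xi3p),
        p.v4 * mvt_slope(p.K4, mv.xi4),
        p.vd * mvt_slope(p.Kd, mv.xi4p),
        hill_slope(p.vs, p.KI, p.n, mv.xi5),
    )
    eigs = np.sort(np.linalg.eigvalsh(Q))[::-1]
    tol = EIG_TOL * max(1.0, float(np.abs(eigs).max()))
    return QEvaluation(Q=Q, eigenvalues=eigs, negative_definite=bool(eigs[0] < -tol))


def _leading_minor_test(Q: np.ndarray, tol: float) -> bool:
    """Sylvester: Q < 0 iff leading principal minors alternate, starting
    negative: sign(det Q_k) = (-1)^k."""
    for k in range(1, Q.shape[0] + 1):
        det = np.linalg.det(Q[:k, :k])
        if det * (-1) ** k <= tol:
            return False
    return True


def is_negative_definite(q: QEvaluation | np.ndarray) -> bool:
    """True iff all eigenvalues are strictly negative.

    Cross-checks the eigenvalue criterion against Sylvester's leading
    principal minor test and raises if the two disagree outside the
    floating-point tolerance band (which would indicate a numerically
    borderline matrix, not a definable answer).
    """
    Q = q.Q if isinstance(q, QEvaluation) else np.asarray(q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be a square matrix")
    if not np.allclose(Q, Q.T, rtol=0, atol=1e-12 * max(1.0, np.abs(Q).max())):
        raise ValueError("Q must be symmetric")
    eigs = np.linalg.eigvalsh(Q)
    scale = max(1.0, float(np.abs(eigs).max()))
    by_eigs = bool(eigs.max() < -EIG_TOL * scale)
    borderline = abs(eigs.max()) <= 1e-9 * scale
    by_minors = _leading_minor_test(Q, 0.0)
    if by_eigs != by_minors and not borderline:
        raise ArithmeticError(
            f"definiteness criteria disagree (max eig {eigs.max():g})")
    return by_eigs


@dataclass
class BoxCertificate:
    """Result of a grid scan of Q over a box of mean-value points."""

    worst_eigenvalue: float
    argmax: MeanValuePoints
    certified: bool  # worst eigenvalue < 0 on the grid (grid certificate only)
    grid_density: int
    gain: float
    scaling: float


def certify_over_box(p: ModelParameters,
                     gain: float,
                     scaling: float,
                     box: StateBox,
                     grid_density: int = 9,
                     chunk: int = 200_000) -> BoxCertificate:
    """Scan Q over a regular grid of mean-value points and report the
    worst (largest) eigenvalue found and where.

    Each of the seven mean-value coordinates is scanned over its state
    variable's interval (``xi3``/``xi3p`` over the x3 interval,
    ``xi4``/``xi4p`` over x4's).  A nonpositive worst eigenvalue certifies
    the sufficient condition *on the grid* — this is not an interval-
    arithmetic proof over the continuous box.
    """
    if grid_density < 1:
        raise ValueError("grid_density must be >= 1")
    lo, hi = np.array(box.lower), np.array(box.upper)

    def axis(i):
        if hi[i] == lo[i]:
            return np.array([lo[i]])
        return np.linspace(lo[i], hi[i], grid_density)

    xi1, xi2, xi3, xi4, xi5 = (axis(i) for i in range(5))
    # precompute the slope terms each entry depends on (one axis each)
    terms = [p.vm * mvt_slope(p.Km, xi1),
             p.v1 * mvt_slope(p.K1, xi2),
             p.v2 * mvt_slope(p.K2, xi3),
             p.v3 * mvt_slope(p.K3, xi3),   # xi3p scans the same interval
             p.v4 * mvt_slope(p.K4, xi4),
             p.vd * mvt_slope(p.Kd, xi4),   # xi4p likewise
             hill_slope(p.vs, p.KI, p.n, xi5)]
    axes = [xi1, xi2, xi3, xi3, xi4, xi4, xi5]
    sizes = [t.size for t in terms]
    total = int(np.prod(sizes))

    worst = -np.inf
    worst_idx = None
    flat = np.arange(total)
    for start in range(0, total, chunk):
        sel = flat[start:start + chunk]
        idx = np.array(np.unravel_index(sel, sizes)).T  # (m, 7)
        vals = [terms[j][idx[:, j]] for j in range(7)]
        Q = _assemble_Q(p, gain, scaling, *vals)
        eig_max = np.linalg.eigvalsh(Q)[:, -1]
        k = int(np.argmax(eig_max))
        if eig_max[k] > worst:
            worst = float(eig_max[k])
            worst_idx = idx[k]
    mv = MeanValuePoints(*(float(axes[j][worst_idx[j]]) for j in range(7)))
    return BoxCertificate(worst_eigenvalue=worst, argmax=mv,
                          certified=worst < 0.0, grid_density=grid_density,
                          gain=gain, scaling=scaling)


def minimal_certifying_gain(p: ModelParameters,
                            scaling: float,
                            box: StateBox,
                            k_max: float,
                            grid_density: int = 5,
                            rel_tol: float = 1e-3) -> float | None:
    """Smallest gain k in (0, k_max] whose grid certificate over ``box`` is
    negative, found by bisection; ``None`` if no gain up to k_max works.

    Only Q's (1,1) entry depends on k, so the worst eigenvalue over the grid
    is non-increasing in k and bisection is sound.  Because the trailing
    4x4 block is k-independent, certification can be structurally impossible
    on a given box — in that case no k_max helps and ``None`` is returned.
    """
    if not k_max > 0:
        raise ValueError("k_max must be positive")

    def worst(k):
        return certify_over_box(p, k, scaling, box, grid_density).worst_eigenvalue

    if worst(k_max) >= 0.0:
        return None
    lo, hi = 0.0, k_max
    while hi - lo > rel_tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if worst(mid) < 0.0:
            hi = mid
        else:
            lo = mid
    return hi
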