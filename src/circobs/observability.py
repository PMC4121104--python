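"""Graphical and differential observability analysis.

Two complementary tests of whether a sensor set can reconstruct the full
state:

* the **inference diagram** — a directed graph with an edge ``x_j -> x_i``
  whenever variable i appears in equation j.  Its condensation into
  strongly connected components (SCCs) identifies the *root SCCs* (no
  incoming edges from other components); picking one sensor per root SCC
  is necessary, and for many nonlinear systems sufficient, for
  observability.  For the circadian model all five variables form a single
  root SCC, so any one of them suffices.

* the **Lie-derivative rank test** — stack the gradients of the output and
  its repeated Lie derivatives along the vector field; full numerical rank
  at a point indicates local observability there.  The model is rational,
  so the stacked Jacobian is formed symbolically (sympy) and evaluated
  exactly; a nested finite-difference route is available as an independent
  cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import sympy as sp

from .model import N_STATES, STATE_LABELS, ModelParameters

__all__ = [
    "InferenceDiagram",
    "SCCDecomposition",
    "LieRankResult",
    "circadian_dependency",
    "build_inference_diagram",
    "scc_decompose",
    "root_sccs",
    "propose_sensors",
    "circadian_field_sympy",
    "lie_rank",
    "lie_rank_general",
]

#: Structural dependency of the circadian equations: entry [j][i] is True
#: when variable i+1 appears in equation j+1.
_CIRCADIAN_DEPENDENCY = np.array([
    [1, 0, 0, 0, 1],   # eq 1: x1, x5
    [1, 1, 1, 0, 0],   # eq 2: x1, x2, x3
    [0, 1, 1, 1, 0],   # eq 3: x2, x3, x4
    [0, 0, 1, 1, 1],   # eq 4: x3, x4, x5
    [0, 0, 0, 1, 1],   # eq 5: x4, x5
], dtype=bool)


def circadian_dependency() -> np.ndarray:
    """The declared 5x5 boolean dependency structure of the oscillator."""
    return _CIRCADIAN_DEPENDENCY.copy()


@dataclass
class InferenceDiagram:
    """Directed dependency graph over state variables.

    Edge ``j -> i`` means variable i appears in variable j's differential
    equation (so information about i flows *to* an observer of j).
    """

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


@dataclass
class SCCDecomposition:
    """Partition of a diagram into strongly connected components."""

    components: list[frozenset]
    is_root: list[bool]

    def roots(self) -> list[frozenset]:
        return [c for c, r in zip(self.components, self.is_root) if r]


def build_inference_diagram(dependency: np.ndarray | Sequence[Sequence[bool]],
                            labels: Sequence[str] | None = None) -> InferenceDiagram:
    """Build the inference diagram from a boolean dependency matrix.

    ``dependency[j][i]`` truthy means variable i appears in equation j and
    contributes edge ``label_j -> label_i``.  Diagonal entries give
    self-loops (recorded, but irrelevant to SCC structure).
    """
    dep = np.asarray(dependency, dtype=bool)
    if dep.ndim != 2 or dep.shape[0] != dep.shape[1]:
        raise ValueError(f"dependency matrix must be square, got {dep.shape}")
    m = dep.shape[0]
    if labels is None:
        labels = [f"x{i + 1}" for i in range(m)]
    if len(labels) != m:
        raise ValueError("labels length must match matrix size")
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for j in range(m):
        for i in range(m):
            if dep[j, i]:
                g.add_edge(labels[j], labels[i])
    return InferenceDiagram(g)


def scc_decompose(d: InferenceDiagram) -> SCCDecomposition:
    """Strongly-connected-component partition with per-component root flag.

    A component is a root when it receives no edge from any *other*
    component (self-loops and intra-component edges do not count).
    """
    comps = [frozenset(c) for c in nx.strongly_connected_components(d.graph)]
    member = {node: k for k, comp in enumerate(comps) for node in comp}
    incoming = [False] * len(comps)
    for a, b in d.graph.edges:
        if member[a] != member[b]:
            incoming[member[b]] = True
    return SCCDecomposition(components=comps,
                            is_root=[not inc for inc in incoming])


def root_sccs(s: SCCDecomposition, d: InferenceDiagram) -> list[frozenset]:
    """Components of ``s`` with no incoming cross-component edge in ``d``."""
    if set().union(*s.components) != set(d.graph.nodes):
        raise ValueError("decomposition does not cover the diagram's nodes")
    return s.roots()


def propose_sensors(roots: Sequence[frozenset]) -> list[frozenset]:
    """All minimal sensor sets: one monitored variable per root SCC."""
    if not roots:
        raise ValueError("no root SCCs given")
    sets = [frozenset(combo) for combo in product(*[sorted(r) for r in roots])]
    return sorted(sets, key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# Lie-derivative rank test
# ---------------------------------------------------------------------------

@dataclass
class LieRankResult:
    """Numerical rank of the stacked Lie-derivative Jacobian at a point.

    ``indeterminate`` is set when any singular value falls in the grey band
    around the rank threshold, in which case the rank is a flag, not a
    verdict.
    """

    rank: int
    singular_values: np.ndarray
    indeterminate: bool
    threshold: float


#: Singular values below RANK_TOL*sigma_max are treated as zero; values in
#: [BAND_LO, BAND_HI]*sigma_max are flagged indeterminate.
RANK_TOL = 1e-6
BAND_LO, BAND_HI = 1e-8, 1e-4


def _rank_from_singulars(s: np.ndarray) -> LieRankResult:
    smax = float(s[0]) if s.size and s[0] > 0 else 0.0
    if smax == 0.0:
        return LieRankResult(0, s, False, 0.0)
    thr = RANK_TOL * smax
    rank = int((s > thr).sum())
    indeterminate = bool(np.any((s >= BAND_LO * smax) & (s <= BAND_HI * smax)))
    return LieRankResult(rank, s, indeterminate, thr)


def circadian_field_sympy(p: ModelParameters, u_value: float = 0.0):
    """Symbolic state vector and right-hand side of the oscillator with a
    frozen (constant) input value."""
    x = sp.symbols("x1:6")
    x1, x2, x3, x4, x5 = x
    KIn = sp.Float(p.KI) ** p.n
    f = sp.Matrix([
        p.vs * KIn / (KIn + x5 ** p.n) - p.vm * x1 / (p.Km + x1) + u_value,
        p.ks * x1 - p.v1 * x2 / (p.K1 + x2) + p.v2 * x3 / (p.K2 + x3),
        p.v1 * x2 / (p.K1 + x2) - p.v2 * x3 / (p.K2 + x3)
        - p.v3 * x3 / (p.K3 + x3) + p.v4 * x4 / (p.K4 + x4),
        p.v3 * x3 / (p.K3 + x3) - p.v4 * x4 / (p.K4 + x4)
        - p.vd * x4 / (p.Kd + x4) - p.k1 * x4 + p.k2 * x5,
        p.k1 * x4 - p.k2 * x5,
    ])
    return sp.Matrix(x), f


def _lie_jacobian_sympy(states: sp.Matrix, f: sp.Matrix, outputs: sp.Matrix,
                        orders: int) -> Callable:
    rows = list(outputs)
    frontier = list(outputs)
    for _ in range(orders):
        frontier = [(sp.Matrix([h]).jacobian(states) * f)[0, 0] for h in frontier]
        rows.extend(frontier)
    J = sp.Matrix(rows).jacobian(states)
    return sp.lambdify(list(states), J, "numpy", cse=True)


def lie_rank_general(states: sp.Matrix, f: sp.Matrix, outputs: sp.Matrix,
                     point: Sequence[float], orders: int | None = None) -> LieRankResult:
    """Rank test for an arbitrary symbolic system ``dx/dt = f(x)`` with
    output map ``outputs``; ``orders`` defaults to dim(x) - 1."""
    n = len(states)
    if orders is None:
        orders = n - 1
    if outputs.is_zero_matrix:
        return LieRankResult(0, np.zeros(n), False, 0.0)
    fn = _lie_jacobian_sympy(states, f, outputs, orders)
    J = np.atleast_2d(np.asarray(fn(*point), dtype=float))
    s = np.linalg.svd(J, compute_uv=False)
    return _rank_from_singulars(s)


def _lie_jacobian_fd(field: Callable, outputs: Sequence[Callable],
                     point: np.ndarray, orders: int, rel_step: float) -> np.ndarray:
    """Stacked Jacobian via nested central differences.

    Each differentiation level multiplies the noise floor; steps grow by
    ~30x per nesting level to rebalance truncation against round-off.  Only
    trustworthy at low orders — kept as an independent cross-check of the
    symbolic route, not as the default.
    """
    n = point.size

    def grad(fun, x, h_scale):
        g = np.empty(n)
        for i in range(n):
            h = h_scale * max(1.0, abs(x[i]))
            ei = np.zeros(n)
            ei[i] = h
            g[i] = (fun(x + ei) - fun(x - ei)) / (2 * h)
        return g

    rows = []
    for h0 in outputs:
        level = h0
        step = rel_step
        rows.append(grad(level, point, step))
        for _ in range(orders):
            prev, s_in = level, step

            def level(x, _prev=prev, _s=s_in):
                return float(grad(_prev, x, _s) @ field(x))

            step = min(1e-1, step * 30.0)
            rows.append(grad(level, point, step))
    return np.array(rows)


def lie_rank(p: ModelParameters,
             sensors: Sequence[int],
             point: Sequence[float],
             u_value: float = 0.0,
             orders: int = 4,
             scalings: Sequence[float] | None = None,
             method: str = "symbolic") -> LieRankResult:
    """Numerical rank of the order-0..``orders`` Lie-derivative Jacobian of
    the circadian model's outputs at ``point``.

    ``sensors`` are 1-based state indices; ``scalings`` (optional, default
    1) multiply the outputs but cannot change the rank.  Rank 5 at a point
    supports local observability of the full state from those sensors.
    The default route is exact symbolic differentiation; ``method="fd"``
    uses nested central differences (cross-check only, reliable at
    ``orders <= 2``).
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (N_STATES,):
        raise ValueError("point must have 5 components")
    if np.any(point <= 0):
        raise ValueError("point must lie in the open positive orthant")
    sensors = [int(s) for s in sensors]
    if any(not 1 <= s <= N_STATES for s in sensors):
        raise ValueError(f"sensor indices must lie in 1..{N_STATES}")
    if scalings is None:
        scalings = [1.0] * len(sensors)

    if method == "symbolic":
        states, f = circadian_field_sympy(p, u_value)
        outputs = sp.Matrix([c * states[s - 1] for s, c in zip(sensors, scalings)])
        return lie_rank_general(states, f, outputs, point, orders)
    if method == "fd":
        from .model import vector_field
        field = lambda x: vector_field(x, p, u_value)
        outs = [(lambda x, _s=s, _c=c: float(_c * x[_s - 1]))
                for s, c in zip(sensors, scalings)]
        J = _lie_jacobian_fd(field, outs, point, orders, rel_step=1e-5)
        s = np.linalg.svd(J, compute_uv=False)
        return _rank_from_singulars(s)
    raise ValueError(f"unknown method {method!r}")
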