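"""Tree-structured quasi-tridiagonal solver (Hines Gaussian elimination).

The implicit voltage update of a branched cable discretization produces a
sparse symmetric system with exactly one sub-diagonal entry per row: row n
couples compartment n to its parent p(n) through the constant coefficients
a_n = b_n = -1/r_n (µS), where r_n is the axial resistance between n and
p(n).  With depth-first numbering (p(n) < n) the system is solved without
fill-in by a leaves-to-root elimination (backward triangulation) followed by
a root-to-leaves back-solve (forward substitution).  Only ``d`` and ``rhs``
mutate; ``a`` and ``b`` are constant across steps.

The system is formulated for the voltage increment Δv:

    d_n Δv_n + b_n Δv_p(n) + Σ_{c: p(c)=n} a_c Δv_c = rhs_n
    d_n  = C_n/dt + G_n + Σ_{c} 1/r_c + [n non-root] 1/r_n
    rhs_n = -Σ_i g_i·x_i·(v_n - E_i) + I_stim,n
            + Σ_c (v_c - v_n)/r_c - [non-root] (v_n - v_p(n))/r_n

so the right-hand side set-up needs the *neighboring voltages* of the
previous step — the dependency structure that branch-parallel execution
synchronizes across subtree boundaries.  A subtree whose root attaches to a
parent subtree eliminates its root row against the cached parent voltage and
emits a :class:`BoundaryContribution` (δd, δrhs) that the parent folds into
the connecting compartment's row before its own triangulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class SingularMatrixError(RuntimeError):
    pass


class SynchronizationError(RuntimeError):
    """A cross-subtree value needed by the solver was not provided."""


@dataclass
class BoundaryContribution:
    """Eliminated subtree root's fold into its parent compartment's row."""

    delta_d: float
    delta_rhs: float


@dataclass
class SolverArrays:
    """Per-subtree solver state: the Δv system plus the voltage vector."""

    p: np.ndarray    # parent index per row; p[0] = -1
    a: np.ndarray    # child-coupling coefficient of row p(n) for column n (µS)
    b: np.ndarray    # parent-coupling coefficient of row n for column p(n) (µS)
    d: np.ndarray    # main diagonal (µS)
    rhs: np.ndarray  # nA; holds Δv (mV) after substitution
    v: np.ndarray    # membrane voltage (mV)
    has_parent: bool = False  # True for a subtree attached below another

    @classmethod
    def from_tree(cls, tree, v_init: float = -65.0) -> "SolverArrays":
        n = tree.n
        inv_r = np.zeros(n)
        if n > 1:
            inv_r[1:] = 1.0 / tree.r[1:]
        coef = -inv_r
        return cls(tree.p.copy(), coef.copy(), coef.copy(), np.zeros(n),
                   np.zeros(n), np.full(n, float(v_init)), has_parent=False)

    @property
    def n(self) -> int:
        return int(self.p.size)

    def inv_r(self) -> np.ndarray:
        return -self.a


def setup_matrix(arr: SolverArrays, G: np.ndarray, i_total: np.ndarray,
                 C: np.ndarray, dt: float,
                 parent_boundary_v: float | None = None,
                 child_axial=()) -> None:
    """Rebuild ``d`` and ``rhs`` for one timestep.

    ``G`` and ``i_total`` are the summed instantaneous conductance (µS) and
    outward mechanism current (nA) per compartment, evaluated at the current
    voltage and half-step gating states.  ``parent_boundary_v`` is the cached
    voltage of the parent subtree's connecting compartment (required iff
    ``arr.has_parent``).  ``child_axial`` lists ``(row, child_root_v,
    child_inv_r)`` axial contributions from child-subtree roots attached
    below row ``row``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d, rhs, v, p = arr.d, arr.rhs, arr.v, arr.p
    inv = arr.inv_r()
    d[:] = C / dt + G
    rhs[:] = -i_total
    if arr.n > 1:
        d[1:] += inv[1:]
        np.add.at(d, p[1:], inv[1:])
        diff = (v[p[1:]] - v[1:]) * inv[1:]
        rhs[1:] += diff
        np.add.at(rhs, p[1:], -diff)
    if arr.has_parent:
        if parent_boundary_v is None:
            raise SynchronizationError(
                "subtree has a parent but no cached parent boundary voltage")
        d[0] += inv[0]
        rhs[0] += (parent_boundary_v - v[0]) * inv[0]
    for row, child_v, child_inv_r in child_axial:
        d[row] += child_inv_r
        rhs[row] += (child_v - v[row]) * child_inv_r


def apply_boundary(arr: SolverArrays, row: int,
                   contrib: BoundaryContribution) -> None:
    """Fold an eliminated child subtree into the connecting compartment."""
    arr.d[row] += contrib.delta_d
    arr.rhs[row] += contrib.delta_rhs


def backward_triangulate(arr: SolverArrays) -> BoundaryContribution | None:
    """Leaves-to-root elimination, in fixed descending-index order.

    Any topological leaves→root order yields the same result up to floating
    point; descending index is the deterministic default.  If the subtree
    attaches to a parent subtree, the root row is eliminated against the
    cross-boundary coupling and the resulting (δd, δrhs) returned for the
    parent's connecting row; otherwise returns ``None``.
    """
    a, b, d, rhs, p = arr.a, arr.b, arr.d, arr.rhs, arr.p
    for i in range(arr.n - 1, 0, -1):
        di = d[i]
        if di == 0.0:
            raise SingularMatrixError(f"zero pivot at row {i}")
        f = a[i] / di
        j = p[i]
        d[j] -= f * b[i]
        rhs[j] -= f * rhs[i]
    if arr.has_parent:
        if d[0] == 0.0:
            raise SingularMatrixError("zero pivot at subtree root")
        f = a[0] / d[0]
        return BoundaryContribution(-f * b[0], -f * rhs[0])
    return None


def forward_substitute(arr: SolverArrays,
                       parent_delta_v: float | None = None) -> None:
    """Root-to-leaves back-solve; ``rhs`` holds Δv (mV) afterwards."""
    b, d, rhs, p = arr.b, arr.d, arr.rhs, arr.p
    if arr.has_parent:
        if parent_delta_v is None:
            raise SynchronizationError(
                "subtree has a parent but no parent Δv was provided")
        rhs[0] = (rhs[0] - b[0] * parent_delta_v) / d[0]
    else:
        if d[0] == 0.0:
            raise SingularMatrixError("zero pivot at root")
        rhs[0] = rhs[0] / d[0]
    for i in range(1, arr.n):
        rhs[i] = (rhs[i] - b[i] * rhs[p[i]]) / d[i]


def solve_tree(arr: SolverArrays) -> np.ndarray:
    """Triangulate + substitute a whole-neuron system; returns Δv."""
    if arr.has_parent:
        raise SynchronizationError("solve_tree expects a whole-neuron system")
    backward_triangulate(arr)
    forward_substitute(arr)
    return arr.rhs.copy()


def assemble_dense(arr: SolverArrays) -> np.ndarray:
    """Dense N×N matrix of the system (for oracle comparisons and debugging)."""
    n = arr.n
    m = np.zeros((n, n))
    m[np.arange(n), np.arange(n)] = arr.d
    for i in range(1, n):
        m[i, arr.p[i]] = arr.b[i]
        m[arr.p[i], i] = arr.a[i]
    return m


def check_diagonal_dominance(arr: SolverArrays) -> bool:
    """Warn (once, at t=0) if the assembled system is not diagonally dominant."""
    n = arr.n
    off = np.zeros(n)
    for i in range(1, n):
        off[i] += abs(arr.b[i])
        off[arr.p[i]] += abs(arr.a[i])
    ok = bool(np.all(arr.d > off))
    if not ok:
        warnings.warn("system is not strictly diagonally dominant",
                      RuntimeWarning, stacklevel=2)
    return ok


def dump_csv(arr: SolverArrays, path) -> None:
    """Debug dump of (p, a, b, d, rhs, v) for fixture diffing."""
    data = np.column_stack([arr.p, arr.a, arr.b, arr.d, arr.rhs, arr.v])
    header = "p,a,b,d,rhs,v"
    np.savetxt(path, data, delimiter=",", header=header, comments="")
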