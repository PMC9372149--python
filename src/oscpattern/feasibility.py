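"""Existence of nonnegative / strictly positive couplings for a target pattern.

Given the incidence matrix ``B``, zero-mean natural frequencies ``omega``
and target per-edge differences ``x``, a coupling vector ``delta``
realizes the pattern iff ``B D(x) delta = omega``.  Only the *signs* of
the sines matter for feasibility under ``delta >= 0``: with ``Bbar = B
sign(D(x))``, a nonnegative solution exists iff ``omega`` lies in the cone
generated by the columns of ``Bbar``.  This module provides

* an exact decision procedure (linear programming on the cone membership),
* the sufficient certificate conditions (sign-scaled column products
  nonpositive, positive frequency projections, range condition) with the
  explicit pseudoinverse solution they induce, and
* the Hamiltonian-path route to *strictly* positive couplings, where the
  off-path edges receive a small positive fill weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "CertificateSet",
    "FeasibilityResult",
    "nonneg_feasible",
    "check_sufficient_conditions",
    "solve_via_certificate",
    "find_hamiltonian_path",
    "hamiltonian_positive_solution",
]

_RESID_TOL = 1e-8


@dataclass
class CertificateSet:
    """Edge-column subset certifying feasibility.

    ``kind="hamiltonian"`` indicates the columns trace a directed
    Hamiltonian path in the sign-adjusted incidence matrix; ``node_order``
    then lists the visited nodes.
    """

    indices: list[int]
    kind: str = "general"
    node_order: list[int] | None = None


@dataclass
class FeasibilityResult:
    status: str  # feasible_nonneg | feasible_strict | infeasible | undetermined
    witness: np.ndarray | None = None
    certificate: CertificateSet | None = None
    diagnostics: dict = field(default_factory=dict)


def _center(omega):
    omega = np.asarray(omega, dtype=float)
    return omega - omega.mean()


def _check_witness(B, x, delta, omega, tol=_RESID_TOL):
    resid = B @ (np.sin(x) * delta) - omega
    return float(np.max(np.abs(resid))) <= tol


def nonneg_feasible(B, omega, x, zero_tol: float = 1e-12) -> FeasibilityResult:
    """Exact decision of ``B D(x) delta = omega`` with ``delta >= 0``.

    Solves the linear feasibility problem ``Bbar deltabar = omega``,
    ``deltabar >= 0`` with HiGHS and maps any solution back through the
    sine magnitudes.  Edges whose sine vanishes carry free weights and are
    reported as 0.
    """
    B = np.asarray(B, dtype=float)
    x = np.asarray(x, dtype=float)
    omega = _center(omega)
    s = np.sin(x)
    nz = np.abs(s) > zero_tol
    Bbar = B[:, nz] * np.sign(s[nz])
    if Bbar.shape[1] == 0:
        if np.max(np.abs(omega)) <= _RESID_TOL:
            return FeasibilityResult("feasible_nonneg", np.zeros(B.shape[1]))
        return FeasibilityResult("infeasible", diagnostics={"reason": "all sines vanish but omega != 0"})
    res = linprog(
        c=np.zeros(Bbar.shape[1]),
        A_eq=Bbar,
        b_eq=omega,
        bounds=(0, None),
        method="highs",
    )
    if res.status == 2:
        return FeasibilityResult("infeasible", diagnostics={"lp_message": res.message})
    if not res.success:
        return FeasibilityResult("undetermined", diagnostics={"lp_message": res.message})
    delta = np.zeros(B.shape[1])
    delta[nz] = res.x / np.abs(s[nz])
    if not _check_witness(B, x, delta, omega):
        return FeasibilityResult("undetermined", diagnostics={"reason": "witness residual too large"})
    return FeasibilityResult("feasible_nonneg", delta)


def check_sufficient_conditions(B, omega, x, S: CertificateSet | list[int], zero_tol: float = 1e-12):
    """Evaluate the three certificate conditions for a column set S.

    (a) for every pair i, j in S with nonvanishing sines, the sign-scaled
        inner product ``D_ii D_jj B_i^T B_j`` is nonpositive (M-matrix
        structure of the scaled Gram matrix);
    (b) ``omega^T B_i D_ii > 0`` for every i in S (positive frequency
        projections along the sign-adjusted columns);
    (c) ``omega`` lies in the column span of ``B[:, S]``.

    Returns ``(ok, report)`` where ``report`` details each condition.
    Together these imply a nonnegative solution exists, with the explicit
    witness of :func:`solve_via_certificate`.
    """
    idx = list(S.indices) if isinstance(S, CertificateSet) else list(S)
    if len(idx) == 0:
        raise ValueError("certificate set must be nonempty")
    B = np.asarray(B, dtype=float)
    x = np.asarray(x, dtype=float)
    omega = _center(omega)
    s = np.sin(x)
    zero_sine = [i for i in idx if abs(s[i]) <= zero_tol]

    cond_a = True
    worst_pair = None
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            if abs(s[i]) <= zero_tol or abs(s[j]) <= zero_tol:
                continue  # stated exemption when a sine vanishes
            val = s[i] * s[j] * float(B[:, i] @ B[:, j])
            if val > 1e-12:
                cond_a = False
                worst_pair = (i, j, val)

    proj = {i: float(omega @ B[:, i]) * s[i] for i in idx}
    cond_b = all(v > 0 for v in proj.values())

    BS = B[:, idx]
    resid = omega - BS @ np.linalg.lstsq(BS, omega, rcond=None)[0]
    cond_c = float(np.linalg.norm(resid)) <= 1e-9 * max(1.0, float(np.linalg.norm(omega)))

    report = {
        "a": cond_a,
        "b": cond_b,
        "c": cond_c,
        "projections": proj,
        "violating_pair": worst_pair,
        "zero_sine_edges": zero_sine,
        "range_residual": float(np.linalg.norm(resid)),
    }
    return cond_a and cond_b and cond_c, report


def _independent_subset(BS: np.ndarray, idx: list[int]) -> list[int]:
    """Greedy column subset of full rank (QR with column pivoting)."""
    from scipy.linalg import qr

    if np.linalg.matrix_rank(BS) == BS.shape[1]:
        return idx
    _, _, piv = qr(BS, pivoting=True)
    r = np.linalg.matrix_rank(BS)
    keep = sorted(piv[:r])
    return [idx[k] for k in keep]


def solve_via_certificate(B, omega, x, S: CertificateSet | list[int]) -> np.ndarray:
    """Nonnegative witness ``delta_S = pinv(B_S D_SS) omega``, zero outside S.

    When the columns of ``B[:, S]`` are linearly dependent, S is first
    restricted to an independent subset, which preserves the construction.
    """
    idx = list(S.indices) if isinstance(S, CertificateSet) else list(S)
    B = np.asarray(B, dtype=float)
    x = np.asarray(x, dtype=float)
    omega = _center(omega)
    idx = _independent_subset(B[:, idx], idx)
    A = B[:, idx] * np.sin(x[idx])
    delta_S = np.linalg.pinv(A) @ omega
    delta = np.zeros(B.shape[1])
    delta[idx] = delta_S
    if not _check_witness(B, x, delta, omega, tol=1e-10):
        raise ValueError("certificate solve left a nonzero residual; conditions likely violated")
    return delta


def _directed_arcs(Bbar: np.ndarray, zero_tol: float = 1e-12):
    """Column -> (source, sink) arcs of the sign-adjusted incidence matrix."""
    arcs = {}
    for col in range(Bbar.shape[1]):
        c = Bbar[:, col]
        src = np.where(c < -zero_tol)[0]
        snk = np.where(c > zero_tol)[0]
        if len(src) == 1 and len(snk) == 1:
            arcs[col] = (int(src[0]), int(snk[0]))
    return arcs


def find_hamiltonian_path(Bbar, limit: int = 12, path: list[int] | None = None) -> CertificateSet | None:
    """Directed Hamiltonian path in the sign-adjusted graph, or ``None``.

    Exhaustive bitmask dynamic programming up to ``limit`` nodes; beyond
    that a user-supplied node ``path`` (0-based) is required and is only
    verified.  The search is exact, so ``None`` certifies non-existence
    for small graphs.
    """
    Bbar = np.asarray(Bbar, dtype=float)
    n = Bbar.shape[0]
    arcs = _directed_arcs(Bbar)
    arc_lookup = {}  # (u, v) -> column
    for col, (u, v) in arcs.items():
        arc_lookup.setdefault((u, v), col)

    if path is not None:
        if sorted(path) != list(range(n)):
            raise ValueError("user path must visit every node exactly once")
        cols = []
        for u, v in zip(path, path[1:]):
            if (u, v) not in arc_lookup:
                return None
            cols.append(arc_lookup[(u, v)])
        return CertificateSet(cols, kind="hamiltonian", node_order=list(path))

    if n > limit:
        raise ValueError(f"n={n} exceeds the exhaustive search limit {limit}; supply a path")

    succ = [[] for _ in range(n)]
    for (u, v) in arc_lookup:
        succ[u].append(v)
    full = (1 << n) - 1
    # dp[(mask, v)] = predecessor node, for reconstruction
    dp = {}
    for v in range(n):
        dp[(1 << v, v)] = -1
    frontier = [(1 << v, v) for v in range(n)]
    while frontier:
        new = []
        for mask, v in frontier:
            for w in succ[v]:
                if mask & (1 << w):
                    continue
                key = (mask | (1 << w), w)
                if key not in dp:
                    dp[key] = v
                    new.append(key)
        frontier = new
    end = next((v for v in range(n) if (full, v) in dp), None)
    if end is None:
        return None
    order = [end]
    mask = full
    while dp[(mask, order[-1])] != -1:
        prev = dp[(mask, order[-1])]
        mask ^= 1 << order[-1]
        order.append(prev)
    order.reverse()
    cols = [arc_lookup[(u, v)] for u, v in zip(order, order[1:])]
    return CertificateSet(cols, kind="hamiltonian", node_order=order)


def hamiltonian_positive_solution(
    B,
    omega,
    x,
    H: CertificateSet,
    eps: float = 0.1,
    eps_floor: float = 1e-8,
) -> np.ndarray:
    """Strictly positive witness from a Hamiltonian-path certificate.

    Off-path edges receive the fill weight ``eps`` and the path weights
    follow from ``delta_H = pinv(B_H D_HH) (omega - B_Ht D_Ht eps 1)``.
    ``eps`` is halved geometrically until every entry is positive; if no
    value down to ``eps_floor`` works, the positivity-breaking edge is
    reported.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    B = np.asarray(B, dtype=float)
    x = np.asarray(x, dtype=float)
    omega = _center(omega)
    m = B.shape[1]
    idxH = list(H.indices)
    idxT = [k for k in range(m) if k not in idxH]
    s = np.sin(x)
    AH = B[:, idxH] * s[idxH]
    pinvAH = np.linalg.pinv(AH)
    cur = eps
    last_delta = None
    while cur >= eps_floor:
        fill = np.full(len(idxT), cur)
        rhs = omega - (B[:, idxT] * s[idxT]) @ fill if idxT else omega
        dH = pinvAH @ rhs
        delta = np.zeros(m)
        delta[idxH] = dH
        delta[idxT] = fill
        last_delta = delta
        if np.all(delta > 0):
            if not _check_witness(B, x, delta, omega, tol=1e-10):
                raise ValueError("positive construction left a nonzero residual")
            return delta
        cur /= 2.0
    bad = int(np.argmin(last_delta))
    raise ValueError(f"no fill weight in range yields positivity; breaking edge column {bad}")
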