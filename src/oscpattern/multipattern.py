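"""Coexisting equilibria and multi-pattern coupling design.

For fixed couplings ``delta`` (all nonzero), every phase-locked
equilibrium ``x`` of the network satisfies ``diag(delta) sin(x) in
B^+ omega + ker(B)``; the kernel of the incidence matrix — the cycle space
of the graph — therefore parameterizes all patterns a given network can
sustain.  Conversely, to realize several target patterns with one weight
vector, ``delta`` must lie in the intersection of the affine sets
``D(x^(i))^{-1}(B^+ omega + ker(B))``, which reduces to a stacked linear
system.  For homogeneous trees and cycles (unit weights, zero
frequencies) the full equilibrium set is enumerable in closed form:
``2^(n-1)`` binary {0, pi} patterns, plus the ``n-1`` splay states on a
cycle, where consecutive phases are spaced by ``2*pi*m/n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .network_core import (
    DiffVector,
    OscillatorNetwork,
    build_incidence,
    equilibrium_residual,
    wrap_angle,
    _as_values,
)

__all__ = [
    "AffineSet",
    "EquilibriumFamily",
    "MultiPatternDesign",
    "kernel_basis",
    "compatible_set",
    "is_compatible",
    "weights_for_patterns",
    "enumerate_equilibria",
]


@dataclass
class AffineSet:
    """Affine subspace ``point + span(basis columns)``."""

    point: np.ndarray
    basis: np.ndarray  # (m, k), orthonormal columns


@dataclass
class EquilibriumFamily:
    members: list[DiffVector]
    parametric: Callable[[float], DiffVector] | None = None
    parametric_domain: tuple[float, float] | None = None


@dataclass
class MultiPatternDesign:
    status: str  # optimal | infeasible
    delta: np.ndarray | None
    multiplicity: str | None  # singleton | subspace
    kernel_dim: int
    residual: float


def kernel_basis(B) -> np.ndarray:
    """Orthonormal basis of ker(B), the cycle space of the graph.

    Its dimension is ``m - n + c`` with ``c`` the number of connected
    components; for a tree it is empty.
    """
    B = np.asarray(B, dtype=float)
    ns = null_space(B)
    return ns


def compatible_set(network: OscillatorNetwork) -> AffineSet:
    """The affine set that ``diag(delta) sin(x)`` must occupy at equilibrium."""
    B = build_incidence(network)
    omega = network.omega - network.omega.mean()
    return AffineSet(np.linalg.pinv(B) @ omega, kernel_basis(B))


def is_compatible(network: OscillatorNetwork, x, tol: float = 1e-9) -> bool:
    """Whether the pattern ``x`` is an equilibrium of the given network.

    Checks that ``diag(delta) sin(x) - B^+ omega`` lies in ker(B), which
    for a connected network is equivalent to a vanishing equilibrium
    residual.  Requires all couplings nonzero (otherwise the affine
    characterization does not apply).
    """
    if np.any(network.delta == 0):
        raise ValueError("compatibility requires nonzero coupling weights")
    xv = _as_values(x)
    aset = compatible_set(network)
    v = network.delta * np.sin(xv) - aset.point
    # remove the kernel component and test the remainder
    if aset.basis.size:
        v = v - aset.basis @ (aset.basis.T @ v)
    return float(np.max(np.abs(v))) <= tol


def weights_for_patterns(
    B,
    omega,
    patterns,
    positive: bool = False,
    tol: float = 1e-8,
) -> MultiPatternDesign:
    """Couplings realizing several target patterns simultaneously.

    Stacks the equality constraints ``B D(x^(i)) delta = omega`` over all
    targets into one least-squares solve and classifies the solution set
    (singleton vs. subspace) from the rank of the stacked operator.  With
    ``positive=True`` a point in the nonnegative orthant is sought by
    linear programming instead.
    """
    B = np.asarray(B, dtype=float)
    omega = np.asarray(omega, dtype=float)
    omega = omega - omega.mean()
    xs = [_as_values(x) for x in patterns]
    if not xs:
        raise ValueError("at least one target pattern is required")
    for x in xs:
        if np.any(np.abs(np.sin(x)) < 1e-12):
            raise ValueError("target pattern has a difference at a multiple of pi")
    A = np.vstack([B * np.sin(x) for x in xs])
    b = np.concatenate([omega] * len(xs))
    kdim = A.shape[1] - np.linalg.matrix_rank(A)

    if positive:
        res = linprog(np.zeros(A.shape[1]), A_eq=A, b_eq=b, bounds=(0, None), method="highs")
        if not res.success:
            return MultiPatternDesign("infeasible", None, None, kdim, np.inf)
        delta = res.x
    else:
        delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = float(np.max(np.abs(A @ delta - b)))
    if resid > tol:
        return MultiPatternDesign("infeasible", None, None, kdim, resid)
    return MultiPatternDesign(
        "optimal", delta, "singleton" if kdim == 0 else "subspace", kdim, resid
    )


# ---------------------------------------------------------------------------
# closed-form enumeration for homogeneous trees and cycles


def _cycle_order(network: OscillatorNetwork) -> list[int]:
    adj: dict[int, list[int]] = {k: [] for k in range(network.n)}
    for i, j in network.edges:
        adj[i].append(j)
        adj[j].append(i)
    if any(len(v) != 2 for v in adj.values()):
        raise ValueError("not a single cycle")
    order = [0, sorted(adj[0])[0]]
    while len(order) < network.n:
        nxt = [v for v in adj[order[-1]] if v != order[-2]]
        order.append(nxt[0])
    return order


def _cyclic_to_lex(network: OscillatorNetwork, order: list[int], vals: np.ndarray) -> DiffVector:
    """Map values on cyclic arcs (order[k] -> order[k+1]) to lexicographic edges."""
    x = np.zeros(network.m)
    index = {e: k for k, e in enumerate(network.edges)}
    n = network.n
    for k in range(n):
        u, v = order[k], order[(k + 1) % n]
        val = vals[k]
        if u < v:
            x[index[(u, v)]] = val
        else:
            x[index[(v, u)]] = -val
    return DiffVector(wrap_angle(x), edges=list(network.edges))


def enumerate_equilibria(network: OscillatorNetwork, check_tol: float = 1e-9) -> EquilibriumFamily:
    """All phase-locked equilibria of a homogeneous tree or cycle network.

    Requires uniform positive couplings and zero natural frequencies.
    Trees admit exactly the ``2^(n-1)`` assignments of {0, pi} to the
    edges.  A single cycle admits ``2^(n-1)`` binary patterns — the
    closing arc is fixed by the cycle-sum constraint — plus the ``n-1``
    splay states with every consecutive difference equal to ``2*pi*m/n``.
    Every returned member is verified to have zero equilibrium residual.
    """
    if not np.allclose(network.delta, network.delta[0]) or network.delta[0] <= 0:
        raise ValueError("enumeration requires uniform positive couplings")
    if np.max(np.abs(network.omega - network.omega.mean())) > 1e-12:
        raise ValueError("enumeration requires identical natural frequencies")
    if not network.is_connected:
        raise ValueError("network must be connected")
    n, m = network.n, network.m
    members: list[DiffVector] = []
    if m == n - 1:  # tree
        for bits in range(2 ** m):
            vals = np.array([(np.pi if (bits >> k) & 1 else 0.0) for k in range(m)])
            members.append(DiffVector(vals, edges=list(network.edges)))
    elif m == n:  # single cycle
        order = _cycle_order(network)
        for bits in range(2 ** (n - 1)):
            vals = np.array([(np.pi if (bits >> k) & 1 else 0.0) for k in range(n - 1)])
            closing = wrap_angle(-vals.sum())
            members.append(_cyclic_to_lex(network, order, np.append(vals, closing)))
        for mm in range(1, n):
            vals = np.full(n, 2.0 * np.pi * mm / n)
            members.append(_cyclic_to_lex(network, order, vals))
    else:
        raise ValueError("unsupported topology: enumeration covers trees and single cycles")
    for x in members:
        r = equilibrium_residual(network, x)
        if np.max(np.abs(r)) > check_tol:
            raise AssertionError("enumerated member failed the residual check")
    return EquilibriumFamily(members)
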