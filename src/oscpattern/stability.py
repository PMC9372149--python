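"""Spectral stability of phase-locked patterns and sign-based instability tests.

Linearizing the phase dynamics at a locked configuration ``x`` gives the
Jacobian ``J = -L(x)`` where ``L(x)`` is the Laplacian of the
*cosine-scaled* network: the graph whose edge weights are
``A_ij cos(x_ij)``.  ``J`` always has a zero eigenvalue along the
all-ones direction (rotational symmetry); the pattern is (orbitally)
stable when every other eigenvalue is negative.

When some differences exceed ``pi/2`` in a positive network, the
cosine-scaled graph acquires negative edges and ``L(x)`` becomes a signed
Laplacian.  If that signed graph is *structurally balanced* — its nodes
split into two camps with all negative edges across and all positive
edges within — the spectrum contains a positive eigenvalue and the
pattern is unstable.  Two specializations follow for positive-weight
topologies: a line network cannot sustain any ``|x_ij| > pi/2``, and a
cycle can be stable only with at most one difference in
``(pi/2, gamma)`` where ``gamma ~= 1.789776`` solves
``gamma - tan(gamma) = 2*pi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .network_core import OscillatorNetwork, build_incidence, _as_values
from .feasibility import FeasibilityResult, nonneg_feasible

__all__ = [
    "JacobianReport",
    "BalancePartition",
    "jacobian",
    "is_structurally_balanced",
    "instability_tests",
    "gamma_threshold",
    "signflip_design",
]

_EIG_TOL = 1e-9


@dataclass
class JacobianReport:
    matrix: np.ndarray
    eigenvalues: np.ndarray  # ascending
    classification: str  # stable | marginal | unstable
    zero_index: int
    disks: list[tuple[float, float]]  # Gerschgorin (center, radius)


@dataclass
class BalancePartition:
    signs: np.ndarray
    balanced: bool
    partition: tuple[list[int], list[int]] | None


def jacobian(network: OscillatorNetwork, x, tol: float = _EIG_TOL) -> JacobianReport:
    """Jacobian ``J = -B diag(delta cos x) B^T`` with spectral classification.

    The structural zero mode (eigenvector along the all-ones direction) is
    excluded from classification: stable if the remaining eigenvalues are
    all below ``-tol``, unstable if any exceeds ``+tol``, marginal
    otherwise.
    """
    xv = _as_values(x)
    B = build_incidence(network)
    w = network.delta * np.cos(xv)
    J = -(B * w) @ B.T
    evals, evecs = np.linalg.eigh(J)
    # the rotational zero: eigenvalue of smallest magnitude whose
    # eigenvector has the largest overlap with the all-ones direction
    ones = np.ones(network.n) / np.sqrt(network.n)
    overlap = np.abs(evecs.T @ ones)
    near_zero = np.abs(evals) <= max(tol, np.abs(evals).min() + tol)
    cand = np.where(near_zero)[0]
    zero_idx = int(cand[np.argmax(overlap[cand])])
    rest = np.delete(evals, zero_idx)
    if rest.size == 0 or np.all(rest < -tol):
        cls = "stable"
    elif np.any(rest > tol):
        cls = "unstable"
    else:
        cls = "marginal"
    disks = [(float(J[i, i]), float(np.sum(np.abs(J[i])) - abs(J[i, i]))) for i in range(network.n)]
    return JacobianReport(J, evals, cls, zero_idx, disks)


def is_structurally_balanced(signs, edges=None, n=None, network: OscillatorNetwork | None = None) -> BalancePartition:
    """Two-color the signed graph: positive edges bind, negative edges cut.

    ``signs`` is per-edge (aligned with ``edges`` or ``network.edges``).
    The graph is balanced iff the coloring is consistent — equivalently,
    no cycle carries an odd number of negative edges.  Edges with zero
    sign are ignored.
    """
    if network is not None:
        edges, n = network.edges, network.n
    signs = np.asarray(signs, dtype=float)
    color = [-1] * n
    adj: dict[int, list[tuple[int, int]]] = {k: [] for k in range(n)}
    for (i, j), s in zip(edges, signs):
        if s == 0:
            continue
        rel = 0 if s > 0 else 1  # parity relation between endpoint colors
        adj[i].append((j, rel))
        adj[j].append((i, rel))
    balanced = True
    for start in range(n):
        if color[start] != -1:
            continue
        color[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for v, rel in adj[u]:
                want = color[u] ^ rel
                if color[v] == -1:
                    color[v] = want
                    stack.append(v)
                elif color[v] != want:
                    balanced = False
    if not balanced:
        return BalancePartition(signs, False, None)
    part = ([k for k in range(n) if color[k] == 0], [k for k in range(n) if color[k] == 1])
    return BalancePartition(signs, True, part)


def _topology(network: OscillatorNetwork) -> str:
    deg = np.zeros(network.n, dtype=int)
    for i, j in network.edges:
        deg[i] += 1
        deg[j] += 1
    if network.is_connected and network.m == network.n - 1 and deg.max() <= 2:
        return "line"
    if network.is_connected and network.m == network.n and np.all(deg == 2):
        return "cycle"
    return "other"


def instability_tests(network: OscillatorNetwork, x) -> dict:
    """Sign-based instability screening before any spectral computation.

    Returns a verdict:

    * ``UNSTABLE`` — the cosine-scaled network is structurally balanced
      with at least one genuinely negative edge and a nonempty
      bipartition (the balance theorem), or a positive line network has a
      difference beyond ``pi/2``;
    * ``CANNOT_BE_STABLE`` — a positive cycle network violates the
      one-large-difference rule (more than one ``|x| > pi/2``, or a
      difference at or beyond the threshold ``gamma``);
    * ``INCONCLUSIVE`` — defer to the Jacobian spectrum.

    The balance theorem is deliberately not applied to all-positive sign
    patterns (which are only vacuously balanced): with every cosine-scaled
    weight positive the Laplacian argument gives stability, not
    instability.
    """
    xv = _as_values(x)
    signs = np.sign(network.delta * np.cos(xv))
    reasons = []
    verdict = "INCONCLUSIVE"

    bal = is_structurally_balanced(signs, network=network)
    has_negative = bool(np.any(signs < 0))
    if (
        has_negative
        and bal.balanced
        and bal.partition is not None
        and all(len(p) > 0 for p in bal.partition)
    ):
        verdict = "UNSTABLE"
        reasons.append("structurally balanced cosine-scaled network with a negative edge")

    topo = _topology(network)
    positive = bool(np.all(network.delta > 0))
    if positive and topo == "line" and np.any(np.abs(xv) > np.pi / 2):
        verdict = "UNSTABLE"
        reasons.append("line network with a phase difference beyond pi/2")
    if positive and topo == "cycle":
        g = gamma_threshold()
        big = np.abs(xv)[np.abs(xv) > np.pi / 2]
        if big.size >= 2 or np.any(big >= g):
            if verdict != "UNSTABLE":
                verdict = "CANNOT_BE_STABLE"
            reasons.append(
                "cycle network admits at most one difference in (pi/2, gamma)"
            )
    return {"verdict": verdict, "reasons": reasons, "balance": bal, "topology": topo}


@lru_cache(maxsize=1)
def gamma_threshold() -> float:
    """Largest admissible cycle difference: the root of ``g - tan(g) = 2*pi``.

    Solved by bracketed root finding on ``(pi/2, pi)``, staying clear of
    the tangent pole; the value is approximately 1.789776 rad.
    """
    f = lambda g: g - np.tan(g) - 2.0 * np.pi
    return float(brentq(f, np.pi / 2 + 1e-9, np.pi - 1e-9, xtol=1e-12, rtol=8.9e-16))


def gamma_threshold_bisect(tol: float = 1e-12) -> float:
    """Plain bisection root of ``g - tan(g) = 2*pi`` (independent of brentq)."""
    lo, hi = np.pi / 2 + 1e-12, np.pi - 1e-12
    flo = lo - np.tan(lo) - 2 * np.pi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = mid - np.tan(mid) - 2 * np.pi
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def signflip_design(B, x, omega) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stable mixed-sign couplings via column sign flips.

    Flips the incidence columns of edges with ``cos(x_ij) < 0`` (the
    diagonal sign matrix ``Delta``) and solves ``B Delta D(x) delta =
    omega`` for ``delta >= 0``.  The physical couplings are then
    ``Delta @ delta``, every cosine-scaled edge weight is nonnegative, and
    the Jacobian is an ordinary Laplacian — stable up to the rotational
    zero mode.  Returns ``(signs, delta, final_couplings)``.
    """
    B = np.asarray(B, dtype=float)
    xv = _as_values(x)
    signs = np.where(np.cos(xv) >= 0, 1.0, -1.0)
    res: FeasibilityResult = nonneg_feasible(B * signs, omega, xv)
    if res.status not in ("feasible_nonneg", "feasible_strict"):
        raise ValueError(f"auxiliary feasibility problem is {res.status}")
    delta = res.witness
    return signs, delta, signs * delta
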