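"""Optimal coupling and frequency corrections that enforce target patterns.

Three convex programs are solved here, all built on the equilibrium
equation ``B D(x)(delta + alpha) = omega``:

* **minimal weight correction** — the smallest (l2 or l1) change
  ``alpha`` of the couplings that makes one or several target patterns
  exact equilibria while keeping all couplings nonnegative;
* **stability-promoting correction** — same constraints, but the
  objective shrinks only the post-correction weights on edges whose
  cosine is negative.  Shrinking those edges contracts the Gerschgorin
  disks of the Jacobian that protrude into the right half-plane, which
  heuristically (not provably) stabilizes the pattern;
* **joint weight/frequency correction** — when the natural frequencies
  may also move, the problem is an unconstrained least-norm solve with
  the closed form ``[alpha; beta] = pinv([B D(x), -I]) (omega - B D(x)
  delta)``.

The l2 programs are equality-constrained nonnegative least squares; they
are solved exactly by reducing onto the nullspace of the equality
constraints and applying the Lawson-Hanson chain (least squares with
inequalities -> least distance programming -> NNLS).  The l1 programs are
linear programs via epigraph splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog, nnls

from .network_core import DiffVector, OscillatorNetwork, build_incidence, _as_values
from .stability import JacobianReport, jacobian

__all__ = [
    "ControlCorrection",
    "TuneConfig",
    "tune_weights",
    "stability_promoting_tune",
    "joint_tune",
    "correction_trace",
    "solve_eq_nnls",
]

_EQ_TOL = 1e-8
_INEQ_TOL = 1e-10


@dataclass
class TuneConfig:
    norm: str = "l2"  # l2 | l1
    penalty_weights: np.ndarray | None = None  # per-edge scaling for the stability objective
    tolerance: float = 1e-9


@dataclass
class ControlCorrection:
    alpha: np.ndarray | None
    beta: np.ndarray | None
    objective: float
    status: str  # optimal | infeasible | undetermined
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# exact solver: min ||C y - d||_2  s.t.  A y = b,  y >= 0


def _ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray | None:
    """Least distance programming: min ||w|| s.t. G w >= h (Lawson-Hanson).

    Returns None when the constraints are inconsistent.
    """
    p, k = G.shape
    E = np.vstack([G.T, h.reshape(1, -1)])  # (k+1) x p
    f = np.zeros(k + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f)
    r = E @ u - f
    if np.linalg.norm(r) <= 1e-12:
        return None
    return -r[:k] / r[-1]


def solve_eq_nnls(A, b, C, d, feas_tol: float = _EQ_TOL):
    """Exact minimizer of ``||C y - d||`` subject to ``A y = b``, ``y >= 0``.

    Reduces the equality constraint onto its nullspace, then solves the
    resulting inequality-constrained least squares through the LDP/NNLS
    chain.  Returns ``(y, status)`` with status in
    {"optimal", "infeasible"}.
    """
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    C = np.asarray(C, float)
    d = np.asarray(d, float)
    y_p = np.linalg.pinv(A) @ b
    if np.max(np.abs(A @ y_p - b)) > feas_tol:
        return None, "infeasible"
    Z = null_space(A)
    if Z.shape[1] == 0:
        if y_p.min() < -1e-9:
            return None, "infeasible"
        return np.maximum(y_p, 0.0), "optimal"
    # min ||E v - f|| s.t. G v >= h
    E = C @ Z
    f = d - C @ y_p
    G, h = Z, -y_p
    U, sv, Vt = np.linalg.svd(E, full_matrices=False)
    if sv.min() <= 1e-12 * max(1.0, sv.max()):
        raise np.linalg.LinAlgError("objective operator is rank deficient on the feasible set")
    GV = (G @ Vt.T) / sv  # G V Sigma^{-1}
    h2 = h - GV @ (U.T @ f)
    w = _ldp(GV, h2)
    if w is None:
        return None, "infeasible"
    v = (Vt.T / sv) @ (w + U.T @ f)
    y = y_p + Z @ v
    y = np.where(np.abs(y) < 1e-13, 0.0, y)
    if y.min() < -1e-8 or np.max(np.abs(A @ y - b)) > 10 * feas_tol:
        return None, "infeasible"
    return np.maximum(y, 0.0), "optimal"


def _l1_tune(A, b, delta):
    """min ||y - delta||_1 s.t. A y = b, y >= 0 (epigraph LP)."""
    m = delta.size
    n_eq = A.shape[0]
    c = np.concatenate([np.zeros(m), np.ones(m)])
    A_eq = np.hstack([A, np.zeros((n_eq, m))])
    I = np.eye(m)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.concatenate([delta, -delta])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b, bounds=(0, None), method="highs")
    if res.status == 2:
        return None, "infeasible"
    if not res.success:
        return None, "undetermined"
    return res.x[:m], "optimal"


def _normalize_targets(targets):
    """Accept a single DiffVector/array or a sequence of them."""
    if isinstance(targets, DiffVector):
        return [targets]
    if isinstance(targets, np.ndarray) and targets.ndim == 1:
        return [targets]
    if isinstance(targets, (list, tuple)) and targets and np.isscalar(targets[0]):
        return [np.asarray(targets, float)]
    return list(targets)


def _stacked_system(network: OscillatorNetwork, targets):
    B = build_incidence(network)
    omega = network.omega - network.omega.mean()
    xs = [_as_values(t) for t in targets]
    A = np.vstack([B * np.sin(x) for x in xs])
    b = np.concatenate([omega] * len(xs))
    return A, b, xs


def tune_weights(network: OscillatorNetwork, targets, config: TuneConfig | None = None) -> ControlCorrection:
    """Minimal correction ``alpha`` making every target an exact equilibrium.

    Solves ``min ||alpha||`` subject to ``B D(x^(i)) (delta + alpha) =
    omega`` for all targets and ``delta + alpha >= 0``.  With the l2 norm
    the minimizer is unique (strictly convex objective); the l1 norm
    promotes sparse corrections.
    """
    config = config or TuneConfig()
    targets = _normalize_targets(targets)
    if not targets:
        raise ValueError("at least one target is required")
    A, b, _ = _stacked_system(network, targets)
    delta = network.delta
    if config.norm == "l2":
        y, status = solve_eq_nnls(A, b, np.eye(delta.size), delta)
    elif config.norm == "l1":
        y, status = _l1_tune(A, b, delta)
    else:
        raise ValueError("norm must be 'l2' or 'l1'")
    if y is None:
        return ControlCorrection(None, None, np.inf, status)
    alpha = y - delta
    obj = float(np.linalg.norm(alpha, 2 if config.norm == "l2" else 1))
    return ControlCorrection(alpha, None, obj, "optimal", {"new_delta": y})


def stability_promoting_tune(
    network: OscillatorNetwork, x, config: TuneConfig | None = None, tiebreak: float = 1e-6
) -> ControlCorrection:
    """Correction that shrinks the weights on negative-cosine edges.

    Minimizes the (optionally penalty-weighted) l2 norm of the
    post-correction weights on ``N = {(i,j): cos(x_ij) < 0}`` under the
    same equality and nonnegativity constraints as :func:`tune_weights`.
    Among the typically non-unique minimizers, a small tie-break term
    (weight ``tiebreak``) prefers the one closest to the original
    couplings.  The Jacobian reports before and after the correction are
    attached; stability of the outcome is promoted, not guaranteed.
    """
    config = config or TuneConfig()
    xv = _as_values(x)
    A, b, _ = _stacked_system(network, [xv])
    delta = network.delta
    m = delta.size
    N = np.where(np.cos(xv) < 0)[0]
    w = np.ones(m) if config.penalty_weights is None else np.asarray(config.penalty_weights, float)
    if np.any(w <= 0):
        raise ValueError("penalty weights must be positive")
    SN = np.zeros((len(N), m))
    for r, e in enumerate(N):
        SN[r, e] = w[e]
    C = np.vstack([SN, tiebreak * np.eye(m)])
    d = np.concatenate([np.zeros(len(N)), tiebreak * delta])
    y, status = solve_eq_nnls(A, b, C, d)
    if y is None:
        return ControlCorrection(None, None, np.inf, status)
    alpha = y - delta
    before = jacobian(network, xv)
    after = jacobian(network.with_delta(y), xv)
    obj = float(np.linalg.norm(w[N] * y[N])) if len(N) else 0.0
    return ControlCorrection(
        alpha, None, obj, "optimal",
        {"new_delta": y, "negative_cosine_edges": N.tolist(), "jacobian_before": before, "jacobian_after": after},
    )


def joint_tune(network: OscillatorNetwork, x) -> ControlCorrection:
    """Closed-form joint weight and frequency correction.

    Always feasible: the frequency correction ``beta`` can absorb any
    residual.  Returns the unique least-norm pair from
    ``[alpha; beta] = pinv([B D(x), -I]) (omega - B D(x) delta)``.  No
    sign constraint is applied to the corrected couplings in this mode.
    """
    xv = _as_values(x)
    B = build_incidence(network)
    A = B * np.sin(xv)
    K = np.hstack([A, -np.eye(network.n)])
    rhs = network.omega - A @ network.delta
    sol = np.linalg.pinv(K) @ rhs
    alpha, beta = sol[: network.m], sol[network.m:]
    return ControlCorrection(alpha, beta, float(np.linalg.norm(sol)), "optimal",
                             {"new_delta": network.delta + alpha, "new_omega": network.omega + beta})


def correction_trace(network: OscillatorNetwork, x, alpha, fractions=(0.0, 1 / 3, 2 / 3, 1.0)) -> list[JacobianReport]:
    """Jacobian spectra as a correction is applied gradually.

    Evaluates the Jacobian at ``delta + f * alpha`` for each fraction
    ``f``, tracing how the eigenvalues (and Gerschgorin disks) migrate as
    the intervention is ramped up.
    """
    xv = _as_values(x)
    alpha = np.asarray(alpha, float)
    return [jacobian(network.with_delta(network.delta + f * alpha), xv) for f in fractions]
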