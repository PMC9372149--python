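"""Network representation and incidence algebra for phase-oscillator models.

A network of :math:`n` Kuramoto oscillators is described by an undirected
weighted graph with per-node natural frequencies.  Most of the analysis in
this package happens in *edge space*: for each edge ``(i, j)`` with
``i < j`` we track the phase difference :math:`x_{ij} = \\theta_j -
\\theta_i`.  The oriented incidence matrix :math:`B` (one column per edge,
``-1`` at the lower-indexed endpoint, ``+1`` at the higher-indexed one)
links node space and edge space, and a phase-locked equilibrium of the
dynamics is exactly a solution of

.. math:: B\\,D(x)\\,\\delta = \\omega,

where :math:`D(x)` is the diagonal matrix of edge sines, :math:`\\delta`
the coupling weights and :math:`\\omega` the (zero-mean) natural
frequencies.

Node indices are 1-based in all on-disk formats and 0-based internally.
Phase differences are stored as canonical representatives in ``(-pi, pi]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OscillatorNetwork",
    "DiffVector",
    "FunctionalPattern",
    "wrap_angle",
    "build_incidence",
    "difference_operator",
    "default_spanning_tree",
    "reconstruct_diffs",
    "diffs_from_phases",
    "phases_from_diffs",
    "analytic_pattern",
    "equilibrium_residual",
    "assign_frequencies",
    "load_network",
    "save_network",
    "load_diff_vector",
    "save_diff_vector",
    "load_pattern",
    "save_pattern",
]


def wrap_angle(x):
    """Reduce angles to the canonical branch ``(-pi, pi]``."""
    x = np.asarray(x, dtype=float)
    y = np.mod(x, 2.0 * np.pi)
    y = np.where(y > np.pi, y - 2.0 * np.pi, y)
    return y


def _as_values(x) -> np.ndarray:
    """Accept a DiffVector, a sequence, or an ndarray of per-edge values."""
    if isinstance(x, DiffVector):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


@dataclass
class OscillatorNetwork:
    """Undirected weighted oscillator network.

    Parameters
    ----------
    n:
        Number of oscillators.
    edges:
        Ordered list of 0-based node pairs ``(i, j)`` with ``i < j``,
        lexicographically sorted and duplicate-free.
    delta:
        Per-edge coupling weight, aligned with ``edges``.
    omega:
        Per-node natural frequency (rad / time unit).
    """

    n: int
    edges: list[tuple[int, int]]
    delta: np.ndarray
    omega: np.ndarray
    _connected: bool | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        edges = [(int(i), int(j)) for i, j in self.edges]
        for i, j in edges:
            if not (0 <= i < j < self.n):
                raise ValueError(f"invalid edge ({i}, {j}) for n={self.n}")
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges")
        if edges != sorted(edges):
            raise ValueError("edges must be lexicographically sorted")
        self.edges = edges
        self.delta = np.asarray(self.delta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.delta.shape != (len(edges),):
            raise ValueError("delta must have one entry per edge")
        if self.omega.shape != (self.n,):
            raise ValueError("omega must have one entry per node")

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    @property
    def is_connected(self) -> bool:
        if self._connected is None:
            self._connected = _n_components(self.n, self.edges) == 1
        return self._connected

    def adjacency(self) -> np.ndarray:
        """Symmetric weighted adjacency matrix A."""
        A = np.zeros((self.n, self.n))
        for (i, j), d in zip(self.edges, self.delta):
            A[i, j] = A[j, i] = d
        return A

    def with_delta(self, delta) -> "OscillatorNetwork":
        return OscillatorNetwork(self.n, list(self.edges), np.asarray(delta, float), self.omega.copy())

    def with_omega(self, omega) -> "OscillatorNetwork":
        return OscillatorNetwork(self.n, list(self.edges), self.delta.copy(), np.asarray(omega, float))


def _n_components(n: int, edges: Sequence[tuple[int, int]]) -> int:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(k) for k in range(n)})


@dataclass
class DiffVector:
    """Per-edge phase differences ``x_ij = theta_j - theta_i``.

    Values are stored on the canonical branch ``(-pi, pi]`` in the
    lexicographic edge order of the owning network.
    """

    values: np.ndarray
    edges: list[tuple[int, int]] | None = None

    def __post_init__(self):
        self.values = wrap_angle(np.asarray(self.values, dtype=float))

    def __len__(self):
        return len(self.values)


@dataclass
class FunctionalPattern:
    """Symmetric matrix of pairwise phase correlations.

    Entry ``(i, j)`` is the time-averaged cosine of the phase difference
    between oscillators ``i`` and ``j``; at a phase-locked configuration it
    equals ``cos(theta_j - theta_i)`` and the matrix has rank at most two.
    """

    matrix: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.matrix, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("pattern must be a square matrix")
        self.matrix = R

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# incidence algebra


def build_incidence(network: OscillatorNetwork) -> np.ndarray:
    """Oriented incidence matrix B (n x m).

    The column for edge ``(i, j)`` carries ``-1`` at the source row ``i``
    and ``+1`` at the sink row ``j`` (edges are oriented from the lower to
    the higher node index), so ``B.T @ theta`` yields the per-edge
    differences ``theta_j - theta_i`` and every column sums to zero.
    """
    B = np.zeros((network.n, network.m))
    for k, (i, j) in enumerate(network.edges):
        B[i, k] = -1.0
        B[j, k] = 1.0
    return B


def default_spanning_tree(network: OscillatorNetwork) -> list[tuple[int, int]]:
    """Spanning tree used for the independent difference subset.

    Prefers the chain ``(1,2), (2,3), ...`` when all of those edges exist;
    otherwise falls back to a breadth-first tree rooted at node 0.
    """
    if not network.is_connected:
        raise ValueError("network must be connected to define a spanning tree")
    chain = [(k, k + 1) for k in range(network.n - 1)]
    edge_set = set(network.edges)
    if all(e in edge_set for e in chain):
        return chain
    # breadth-first tree from node 0
    adj: dict[int, list[int]] = {k: [] for k in range(network.n)}
    for i, j in network.edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    order = [0]
    tree = []
    while order:
        u = order.pop(0)
        for v in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                order.append(v)
                tree.append((min(u, v), max(u, v)))
    return tree


def difference_operator(
    network: OscillatorNetwork, tree_edges: Sequence[tuple[int, int]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(M, M_min)`` mapping phases to differences.

    ``M`` is the full ``m x n`` operator (``M = B.T``); ``M_min`` restricts
    it to the rows of a spanning tree, giving a full-row-rank
    ``(n-1) x n`` matrix whose kernel is the all-ones direction.
    """
    B = build_incidence(network)
    M = B.T
    tree = list(tree_edges) if tree_edges is not None else default_spanning_tree(network)
    _check_spanning_tree(network.n, tree)
    M_min = np.zeros((network.n - 1, network.n))
    for r, (i, j) in enumerate(tree):
        M_min[r, i] = -1.0
        M_min[r, j] = 1.0
    return M, M_min


def _check_spanning_tree(n: int, tree: Sequence[tuple[int, int]]):
    if len(tree) != n - 1 or _n_components(n, tree) != 1:
        raise ValueError("provided edge set is not a spanning tree")


def reconstruct_diffs(
    x_min,
    network: OscillatorNetwork,
    tree_edges: Sequence[tuple[int, int]] | None = None,
) -> DiffVector:
    """Reconstruct all per-edge differences from values on a spanning tree.

    Computes ``x = M @ pinv(M_min) @ x_min`` and wraps the result to the
    canonical branch.  For a chain tree this reduces to running sums, e.g.
    ``x_13 = x_12 + x_23``.
    """
    x_min = np.asarray(x_min, dtype=float)
    M, M_min = difference_operator(network, tree_edges)
    if x_min.shape != (network.n - 1,):
        raise ValueError("x_min must have n-1 entries, one per tree edge")
    x = M @ np.linalg.pinv(M_min) @ x_min
    return DiffVector(wrap_angle(x), edges=list(network.edges))


def diffs_from_phases(network: OscillatorNetwork, theta) -> DiffVector:
    """Per-edge differences ``theta_j - theta_i`` of a phase vector."""
    theta = np.asarray(theta, dtype=float)
    B = build_incidence(network)
    return DiffVector(wrap_angle(B.T @ theta), edges=list(network.edges))


def phases_from_diffs(network: OscillatorNetwork, x, tol: float = 1e-8) -> np.ndarray:
    """A phase vector (theta_0 = 0) consistent with the differences ``x``.

    Raises if the differences are inconsistent, i.e. some cycle sum is not
    congruent to zero mod 2*pi.
    """
    xv = _as_values(x)
    if xv.shape != (network.m,):
        raise ValueError("x must have one entry per edge")
    theta = np.full(network.n, np.nan)
    theta[0] = 0.0
    lookup = {e: xv[k] for k, e in enumerate(network.edges)}
    adj: dict[int, list[tuple[int, float]]] = {k: [] for k in range(network.n)}
    for (i, j), v in lookup.items():
        adj[i].append((j, v))
        adj[j].append((i, -v))
    stack = [0]
    while stack:
        u = stack.pop()
        for v, d in adj[u]:
            if np.isnan(theta[v]):
                theta[v] = theta[u] + d
                stack.append(v)
    if np.isnan(theta).any():
        raise ValueError("network must be connected")
    # consistency: every edge difference must match mod 2*pi
    resid = wrap_angle((build_incidence(network).T @ theta) - xv)
    if np.max(np.abs(resid)) > tol:
        raise ValueError("inconsistent difference vector (nonzero cycle sums)")
    return theta


def analytic_pattern(arg, network: OscillatorNetwork | None = None) -> FunctionalPattern:
    """Functional pattern of a fixed phase-locked configuration.

    Called with a per-node phase vector alone, or with a per-edge
    difference vector plus its ``network`` (differences are first checked
    for consistency).  Returns the rank-<=2 matrix ``R = c c^T + s s^T``
    with ``c, s`` the elementwise cosine and sine of the phases, i.e.
    ``R_ij = cos(theta_j - theta_i)``.
    """
    if network is not None:
        theta = phases_from_diffs(network, arg)
    elif isinstance(arg, DiffVector):
        raise ValueError("a network is required to interpret a difference vector")
    else:
        theta = np.asarray(arg, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    return FunctionalPattern(np.outer(c, c) + np.outer(s, s))


def equilibrium_residual(network: OscillatorNetwork, x) -> np.ndarray:
    """Per-node residual ``B D(x) delta - omega`` (omega centered to zero mean).

    The zero vector certifies that ``x`` is a phase-locked equilibrium of
    the network.
    """
    xv = _as_values(x)
    B = build_incidence(network)
    omega = network.omega - network.omega.mean()
    return B @ (np.sin(xv) * network.delta) - omega


def assign_frequencies(network: OscillatorNetwork, x) -> np.ndarray:
    """Natural frequencies that make ``x`` an exact equilibrium.

    Returns ``omega = B D(x) delta``; the result has zero mean because the
    incidence columns sum to zero.
    """
    xv = _as_values(x)
    B = build_incidence(network)
    return B @ (np.sin(xv) * network.delta)


# ---------------------------------------------------------------------------
# file formats (1-based on disk)


def load_network(path) -> OscillatorNetwork:
    """Read a network from JSON: {"n", "edges" (1-based), "delta", "omega"}."""
    with open(path) as fh:
        obj = json.load(fh)
    edges = [(int(i) - 1, int(j) - 1) for i, j in obj["edges"]]
    return OscillatorNetwork(int(obj["n"]), edges, np.asarray(obj["delta"], float), np.asarray(obj["omega"], float))


def save_network(network: OscillatorNetwork, path):
    obj = {
        "n": network.n,
        "edges": [[i + 1, j + 1] for i, j in network.edges],
        "delta": list(map(float, network.delta)),
        "omega": list(map(float, network.omega)),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_diff_vector(path, network: OscillatorNetwork) -> DiffVector:
    """Read per-edge differences from CSV with header ``i,j,x`` (1-based)."""
    df = pd.read_csv(path)
    lookup = {(int(r.i) - 1, int(r.j) - 1): float(r.x) for r in df.itertuples()}
    try:
        vals = [lookup[e] for e in network.edges]
    except KeyError as exc:
        raise ValueError(f"target file is missing edge {exc}") from exc
    return DiffVector(np.asarray(vals), edges=list(network.edges))


def save_diff_vector(x: DiffVector, network: OscillatorNetwork, path):
    df = pd.DataFrame(
        {
            "i": [i + 1 for i, _ in network.edges],
            "j": [j + 1 for _, j in network.edges],
            "x": _as_values(x),
        }
    )
    df.to_csv(path, index=False)


def load_pattern(path) -> FunctionalPattern:
    df = pd.read_csv(path, index_col=0)
    return FunctionalPattern(df.to_numpy(dtype=float))


def save_pattern(R: FunctionalPattern, path):
    ids = [str(k + 1) for k in range(R.n)]
    pd.DataFrame(R.matrix, index=ids, columns=ids).to_csv(path)
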