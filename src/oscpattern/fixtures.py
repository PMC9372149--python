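"""Deterministic generators for topologies, stable instances and named cases.

Everything needed to exercise the package is generated in code: standard
topologies (lines, cycles, complete graphs, seeded random connected
graphs), guaranteed-stable phase-locked instances built by construction
(all differences below a bound smaller than pi/2, positive weights, and
frequencies assigned so the target is an exact equilibrium), and a small
set of named instances: the splay state of a homogeneous triangle, the
one-parameter equilibrium family of the homogeneous 4-cycle, the binary
equilibrium families of small trees, and a seven-oscillator target
pattern whose leading difference exceeds pi/2 (its couplings and
frequencies are not part of the package and must be supplied by the
user).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .kuramoto_sim import Trajectory  # noqa: F401  (re-exported convenience)
from .multipattern import EquilibriumFamily, enumerate_equilibria
from .network_core import (
    DiffVector,
    OscillatorNetwork,
    assign_frequencies,
    diffs_from_phases,
    load_network,
    wrap_angle,
)

__all__ = [
    "NamedInstance",
    "make_topology",
    "make_stable_instance",
    "named_instances",
    "four_cycle_family",
    "seven_node_target",
]


@dataclass
class NamedInstance:
    name: str
    network: OscillatorNetwork | None
    target: object  # DiffVector | EquilibriumFamily | callable
    notes: str


def _edges_for(kind: str, n: int, seed=None) -> list[tuple[int, int]]:
    if kind == "line":
        return [(k, k + 1) for k in range(n - 1)]
    if kind == "cycle":
        edges = [(k, k + 1) for k in range(n - 1)] + [(0, n - 1)]
        return sorted(edges)
    if kind == "complete":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    if kind == "random_connected":
        if seed is None:
            raise ValueError("random_connected requires a seed")
        s = int(seed)
        while True:
            G = nx.gnp_random_graph(n, p=min(1.0, 2.5 / max(n - 1, 1)), seed=s)
            if nx.is_connected(G):
                return sorted((min(u, v), max(u, v)) for u, v in G.edges)
            s += 1
    raise ValueError(f"unknown topology kind {kind!r}")


def make_topology(kind: str, n: int, seed=None) -> OscillatorNetwork:
    """Network skeleton with unit weights and zero frequencies.

    ``kind`` is one of ``line``, ``cycle``, ``complete``,
    ``random_connected`` (the latter is reproducible per seed).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    edges = _edges_for(kind, n, seed)
    return OscillatorNetwork(n, edges, np.ones(len(edges)), np.zeros(n))


def make_stable_instance(
    topology: str,
    n: int,
    seed: int,
    max_diff: float = 1.2,
) -> tuple[OscillatorNetwork, DiffVector]:
    """A network together with a stable exact equilibrium, by construction.

    Phases are sampled inside an interval of width ``max_diff`` (which
    must be below pi/2), so every pairwise difference stays strictly
    below the bound; weights are drawn uniformly from [0.5, 2.0]; the
    natural frequencies are then assigned so the sampled pattern is an
    exact equilibrium.  Since all differences are below pi/2 on a
    positive network, the pattern is guaranteed stable.
    """
    if not (0 < max_diff < np.pi / 2):
        raise ValueError("max_diff must lie in (0, pi/2)")
    rng = np.random.default_rng(seed)
    skel = make_topology(topology, n, seed=seed)
    theta = rng.uniform(-max_diff / 2, max_diff / 2, size=n)
    delta = rng.uniform(0.5, 2.0, size=skel.m)
    net = skel.with_delta(delta)
    x = diffs_from_phases(net, theta)
    omega = assign_frequencies(net, x)
    return net.with_omega(omega), x


def four_cycle_family(gamma: float) -> DiffVector:
    """The one-parameter equilibrium family of the homogeneous 4-cycle.

    In cyclic orientation the consecutive differences are
    ``[pi/2 - g, pi/2 + g, pi/2 - g, pi/2 + g]``; every value of the
    parameter keeps the sine vector in the cycle space, so the whole
    circle of patterns is compatible with unit weights and zero
    frequencies.  Values are returned in the lexicographic edge order of
    ``make_topology("cycle", 4)``: (1,2), (1,4), (2,3), (3,4) in 1-based
    labels.
    """
    v = [np.pi / 2 - gamma, np.pi / 2 + gamma, np.pi / 2 - gamma, np.pi / 2 + gamma]
    # cyclic arcs 0->1->2->3->0 mapped onto lexicographic edges
    net = make_topology("cycle", 4)
    x = np.zeros(net.m)
    index = {e: k for k, e in enumerate(net.edges)}
    arcs = [(0, 1), (1, 2), (2, 3), (3, 0)]
    for (u, vv), val in zip(arcs, v):
        if u < vv:
            x[index[(u, vv)]] = val
        else:
            x[index[(vv, u)]] = -val
    return DiffVector(wrap_angle(x), edges=list(net.edges))


def seven_node_target() -> np.ndarray:
    """Differences with respect to oscillator 1 for the 7-node demo target.

    ``[21*pi/32, pi/6, pi/6, pi/8, pi/8, pi/3]`` — the first entry
    exceeds pi/2, so in a positive network the cosine-scaled graph
    acquires a negative edge and stability is not automatic.
    """
    return np.array([21 * np.pi / 32, np.pi / 6, np.pi / 6, np.pi / 8, np.pi / 8, np.pi / 3])


def named_instances() -> list[NamedInstance]:
    """Canonical small instances used across the documentation and tests."""
    out = []

    tri = make_topology("complete", 3)
    splay = DiffVector(np.array([2 * np.pi / 3, -2 * np.pi / 3, 2 * np.pi / 3]),
                       edges=list(tri.edges))
    out.append(NamedInstance(
        "triangle-splay", tri, splay,
        "splay state of the homogeneous triangle: consecutive phases spaced by 2*pi/3",
    ))

    cyc4 = make_topology("cycle", 4)
    out.append(NamedInstance(
        "four-cycle-gamma", cyc4, four_cycle_family,
        "one-parameter equilibrium family of the homogeneous 4-cycle",
    ))

    for n in (3, 4):
        tree = make_topology("line", n)
        out.append(NamedInstance(
            f"tree-{n}-binary", tree, enumerate_equilibria(tree),
            f"the 2^{n - 1} binary (0/pi) equilibria of a homogeneous {n}-node tree",
        ))

    out.append(NamedInstance(
        "seven-node-mixed", None, seven_node_target(),
        "7-oscillator target with one difference beyond pi/2 (differences w.r.t. "
        "oscillator 1); couplings and frequencies must be supplied by the user",
    ))
    return out


def load_seven_node_instance(network_path) -> tuple[OscillatorNetwork, np.ndarray]:
    """Pair the shipped 7-node target with user-supplied network parameters.

    ``network_path`` is a network JSON file providing the couplings and
    natural frequencies; the returned target is the vector of differences
    with respect to oscillator 1.
    """
    net = load_network(network_path)
    if net.n != 7:
        raise ValueError("expected a 7-oscillator network")
    return net, seven_node_target()
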