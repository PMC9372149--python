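"""Cone feasibility, certificate conditions, Hamiltonian-path constructions."""

from itertools import combinations, permutations

import numpy as np
import pytest

import oscpattern as op

from conftest import random_connected_network


def cone_membership_oracle(Bbar, omega, tol=1e-9):
    """Independent decision of `omega in cone(columns of Bbar)`.

    By Caratheodory, membership holds iff some subset of at most rank(Bbar)
    columns expresses omega exactly with nonnegative coefficients; checked
    here by exhaustive subset enumeration with least squares.
    """
    m = Bbar.shape[1]
    if np.linalg.norm(omega) < tol:
        return True
    r = np.linalg.matrix_rank(Bbar)
    for k in range(1, r + 1):
        for sub in combinations(range(m), k):
            A = Bbar[:, sub]
            coef, *_ = np.linalg.lstsq(A, omega, rcond=None)
            if np.linalg.norm(A @ coef - omega) < tol and np.all(coef >= -tol):
                return True
    return False


class TestNonnegFeasible:
    def test_line_increasing_frequencies(self, line3):
        B = op.build_incidence(line3)
        res = op.nonneg_feasible(B, line3.omega, np.array([np.pi / 6, np.pi / 6]))
        assert res.status == "feasible_nonneg"
        assert np.allclose(res.witness, [2.0, 2.0])

    def test_zero_omega_trivial(self, triangle):
        res = op.nonneg_feasible(op.build_incidence(triangle), np.zeros(3), np.full(3, 0.3))
        assert res.status == "feasible_nonneg"
        assert np.allclose(res.witness, 0.0)

    def test_two_node_wrong_direction_infeasible(self):
        net = op.OscillatorNetwork(2, [(0, 1)], np.ones(1), np.array([1.0, -1.0]))
        res = op.nonneg_feasible(op.build_incidence(net), net.omega, np.array([np.pi / 6]))
        assert res.status == "infeasible"

    def test_agrees_with_subset_enumeration_oracle(self, rng):
        """Exactness against brute-force cone membership on small graphs."""
        hits = {True: 0, False: 0}
        for _ in range(60):
            n = int(rng.integers(3, 5))
            net = random_connected_network(rng, n)
            if net.m > 6:
                continue
            x = rng.uniform(-np.pi, np.pi, net.m)
            omega = rng.normal(size=n)
            omega -= omega.mean()
            B = op.build_incidence(net)
            res = op.nonneg_feasible(B, omega, x)
            assert res.status in ("feasible_nonneg", "infeasible")
            s = np.sin(x)
            nz = np.abs(s) > 1e-12
            expected = cone_membership_oracle(B[:, nz] * np.sign(s[nz]), omega)
            got = res.status == "feasible_nonneg"
            assert got == expected
            hits[got] += 1
        assert hits[True] > 0 and hits[False] > 0  # both outcomes exercised

    def test_witness_satisfies_constraints(self, rng):
        for _ in range(20):
            net = random_connected_network(rng, 5)
            x = rng.uniform(-np.pi / 2 + 0.1, np.pi / 2 - 0.1, net.m)
            omega = op.assign_frequencies(net, x)  # feasible by construction
            B = op.build_incidence(net)
            res = op.nonneg_feasible(B, omega, x)
            assert res.status == "feasible_nonneg"
            assert np.all(res.witness >= 0)
            assert np.abs(B @ (np.sin(x) * res.witness) - omega).max() < 1e-8


class TestSufficientConditions:
    def test_line_hand_evaluation(self, line3):
        B = op.build_incidence(line3)
        x = np.array([np.pi / 6, np.pi / 6])
        ok, rep = op.check_sufficient_conditions(B, line3.omega, x, [0, 1])
        assert ok and rep["a"] and rep["b"] and rep["c"]

    def test_negated_frequencies_break_projection(self, line3):
        B = op.build_incidence(line3)
        x = np.array([np.pi / 6, np.pi / 6])
        ok, rep = op.check_sufficient_conditions(B, -line3.omega, x, [0, 1])
        assert not ok and not rep["b"]

    def test_zero_sine_edges_exempt_from_pair_condition(self, triangle):
        B = op.build_incidence(triangle)
        x = np.array([np.pi / 6, 0.0, np.pi / 6])  # middle edge has zero sine
        ok, rep = op.check_sufficient_conditions(
            B, np.array([-1.0, 0.0, 1.0]), x, [0, 1, 2]
        )
        assert rep["zero_sine_edges"] == [1]
        assert rep["a"]  # pairs with the zero-sine edge are exempt

    def test_conditions_imply_lp_feasibility(self, rng):
        """Soundness: whenever the certificate holds, the LP is feasible."""
        checked = 0
        for _ in range(200):
            n = int(rng.integers(3, 7))
            net = random_connected_network(rng, n)
            x = rng.uniform(-np.pi, np.pi, net.m)
            omega = rng.normal(size=n)
            omega -= omega.mean()
            B = op.build_incidence(net)
            size = int(rng.integers(1, min(net.m, n - 1) + 1))
            S = list(rng.choice(net.m, size=size, replace=False))
            ok, _ = op.check_sufficient_conditions(B, omega, x, S)
            if ok:
                checked += 1
                assert op.nonneg_feasible(B, omega, x).status == "feasible_nonneg"
        assert checked > 0


class TestCertificateSolve:
    def test_line_explicit_weights(self, line3):
        B = op.build_incidence(line3)
        d = op.solve_via_certificate(B, line3.omega, np.array([np.pi / 6, np.pi / 6]), [0, 1])
        assert np.allclose(d, [2.0, 2.0])

    def test_zero_omega(self, triangle):
        B = op.build_incidence(triangle)
        d = op.solve_via_certificate(B, np.zeros(3), np.full(3, 0.4), [0, 2])
        assert np.allclose(d, 0.0)

    def test_agrees_with_lp_on_trees(self, rng):
        """When the certificate fires on a tree, it matches the unique LP witness."""
        fired = 0
        for _ in range(40):
            net = op.make_topology("line", 4)
            x = rng.uniform(0.1, np.pi / 2 - 0.1, 3)
            omega = op.assign_frequencies(net.with_delta(rng.uniform(0.5, 2, 3)), x)
            B = op.build_incidence(net)
            S = [0, 1, 2]
            # the projection condition (b) can fail for non-monotone omega;
            # the LP must still be feasible because omega was constructed
            assert op.nonneg_feasible(B, omega, x).status == "feasible_nonneg"
            ok, _ = op.check_sufficient_conditions(B, omega, x, S)
            if not ok:
                continue
            fired += 1
            d_cert = op.solve_via_certificate(B, omega, x, S)
            d_lp = op.nonneg_feasible(B, omega, x).witness
            assert np.allclose(d_cert, d_lp, atol=1e-7)  # tree flows are unique
        assert fired > 0


class TestHamiltonianPath:
    def test_line_chain_is_its_own_path(self, line3):
        B = op.build_incidence(line3)
        cert = op.find_hamiltonian_path(B)
        assert cert is not None and cert.node_order == [0, 1, 2]

    def test_star_has_none(self):
        star = op.OscillatorNetwork(4, [(0, 1), (0, 2), (0, 3)], np.ones(3), np.zeros(4))
        B = op.build_incidence(star)
        Bbar = np.hstack([B, -B])  # both orientations available: still no path
        assert op.find_hamiltonian_path(Bbar) is None

    def test_complete_graph_path_verified_by_permutations(self, rng):
        net = op.make_topology("complete", 5)
        x = rng.uniform(-np.pi, np.pi, net.m)
        Bbar = op.build_incidence(net) * np.sign(np.sin(x))
        cert = op.find_hamiltonian_path(Bbar)
        # brute-force oracle over node permutations
        arcs = set()
        for col in range(Bbar.shape[1]):
            c = Bbar[:, col]
            arcs.add((int(np.argmin(c)), int(np.argmax(c))))
        exists = any(
            all((u, v) in arcs for u, v in zip(p, p[1:]))
            for p in permutations(range(5))
        )
        assert (cert is not None) == exists
        if cert is not None:
            for u, v in zip(cert.node_order, cert.node_order[1:]):
                assert (u, v) in arcs

    def test_user_path_verified(self, line3):
        B = op.build_incidence(line3)
        cert = op.find_hamiltonian_path(B, path=[0, 1, 2])
        assert cert is not None and cert.indices == [0, 1]
        assert op.find_hamiltonian_path(B, path=[1, 0, 2]) is None


class TestStrictlyPositive:
    def test_line_reduces_to_certificate(self, line3):
        B = op.build_incidence(line3)
        x = np.array([np.pi / 6, np.pi / 6])
        cert = op.find_hamiltonian_path(B * np.sign(np.sin(x)))
        d = op.hamiltonian_positive_solution(B, line3.omega, x, cert)
        assert np.allclose(d, [2.0, 2.0])

    def test_triangle_flow_bookkeeping(self, line3):
        """Chord fill weight eps reduces the chain weights by eps*sin(x13)/sin(chain)."""
        net = op.make_topology("complete", 3).with_omega([-1.0, 0.0, 1.0])
        B = op.build_incidence(net)
        # edges (1,2), (1,3), (2,3); chain = {0, 2}, chord = 1
        x = np.array([np.pi / 6, np.pi / 6 + np.pi / 3, np.pi / 3])
        cert = op.CertificateSet([0, 2], kind="hamiltonian", node_order=[0, 1, 2])
        eps = 0.1
        d = op.hamiltonian_positive_solution(B, net.omega, x, cert, eps=eps)
        assert d[1] == pytest.approx(eps)
        # node-1 balance: delta12 sin(x12) + delta13 sin(x13) = 1
        assert d[0] * np.sin(np.pi / 6) + eps * np.sin(np.pi / 2) == pytest.approx(1.0)
        assert np.all(d > 0)

    def test_positivity_threshold_scales_with_chord_sine(self):
        """Positivity fails once the chord weight passes c / sin(x12 + x23)."""
        net = op.make_topology("complete", 3).with_omega([-1.0, 0.0, 1.0])
        B = op.build_incidence(net)
        x12 = x23 = np.pi / 3
        x = np.array([x12, x12 + x23, x23])
        cert = op.CertificateSet([0, 2], kind="hamiltonian", node_order=[0, 1, 2])
        # with the chain solution delta12 = (1 - eps sin(x12+x23)) / sin(x12),
        # positivity requires eps < 1 / sin(x12 + x23)
        threshold = 1.0 / np.sin(x12 + x23)
        d = op.hamiltonian_positive_solution(B, net.omega, x, cert, eps=0.9 * threshold)
        assert np.all(d > 0) and d[1] == pytest.approx(0.9 * threshold)
        d2 = op.hamiltonian_positive_solution(B, net.omega, x, cert, eps=1.1 * threshold)
        assert d2[1] < threshold  # the fill weight had to be halved below the bound

    def test_monotone_line_rule(self, rng):
        """Lines with increasing frequencies and |x| < pi/2 always admit delta > 0."""
        for n in range(3, 9):
            for _ in range(10):
                net = op.make_topology("line", n)
                x = rng.uniform(0.05, np.pi / 2 - 0.05, n - 1)
                omega = np.sort(rng.normal(size=n))
                omega -= omega.mean()
                if np.any(np.diff(omega) <= 1e-6):
                    continue
                B = op.build_incidence(net)
                cert = op.find_hamiltonian_path(B * np.sign(np.sin(x)))
                assert cert is not None
                d = op.hamiltonian_positive_solution(B, omega, x, cert)
                assert np.all(d > 0)
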