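# Methods and numerical conventions

This note records the model, conventions, algorithms and tolerances used
throughout `oscpattern`, so results can be reproduced and limitations judged.

## Model

Heterogeneous Kuramoto dynamics on a weighted undirected graph with `n`
nodes and edge set `E` (`m = |E|`):

```
dtheta_i/dt = omega_i + sum_j A_ij sin(theta_j - theta_i)
```

Edges are stored 0-based internally (1-based in files), sorted
lexicographically with `i < j`. The oriented incidence matrix `B` has, for
edge `(i, j)` with `i < j`, entry `-1` at row `i` and `+1` at row `j`; thus
`1^T B = 0` and `ker(B)` is the cycle space of the graph, of dimension
`m - n + c` with `c` the number of connected components.

A phase-locked trajectory has constant pairwise differences; collecting the
per-edge differences `x_e = theta_j - theta_i` gives the equilibrium
condition in the rotating frame

```
B diag(sin x) delta = omega - mean(omega) * 1
```

The functional pattern of a locked state is `R = c c^T + s s^T` with
`c = cos(theta)`, `s = sin(theta)` (rank at most 2, ones on the diagonal).
Angles are always reduced to the canonical branch `(-pi, pi]` by
`wrap_angle` (`mod 2*pi`, then shift).

## Feasibility of nonnegative weights

`nonneg_feasible` decides, exactly, whether `omega - mean(omega)` lies in the
cone generated by the columns of `B_bar = B * sign(sin x)`; edges with
`sin(x_e) = 0` (|sin| < 1e-12) carry no flow and are excluded, their weights
reported as 0. The decision is a phase-1 LP solved with `scipy.optimize.linprog`
(HiGHS). Witnesses are mapped back to weights by dividing by `|sin(x_e)|`.

`check_sufficient_conditions` evaluates, for an edge subset `S`:
(a) `D_ii D_jj B_i^T B_j <= 0` for all pairs in `S` (zero-sine edges exempt);
(b) `omega^T B_i D_ii > 0` for each edge in `S`;
(c) `omega` in the range of `B_S` (residual tolerance 1e-9).
When they hold, `solve_via_certificate` returns
`delta_S = pinv(B_S D_SS) omega` (restricted to a QR-pivoted independent
column subset), which is entrywise nonnegative by construction. The
conditions are sufficient, not necessary; the LP remains the ground truth.

Strictly positive solutions use a directed Hamiltonian path in the digraph
induced by `B_bar` (arc from the `-1` row to the `+1` row of each column),
found by bitmask dynamic programming (exact, limited to `n <= 12`; a
user-supplied path of any length is verified instead when given).
`hamiltonian_positive_solution` assigns a small weight `eps` (default 0.1)
to all off-path edges and solves for the path weights by pseudoinverse; if
any path weight is nonpositive, `eps` is halved geometrically down to 1e-8.
Residuals are verified to 1e-10 before returning.

## Multi-pattern compatibility and design

A pattern `x` is an equilibrium of some weighting iff
`sin(x) in diag(delta)^{-1} (B^+ omega + ker B)`; compatibility of a given
network/pattern pair is tested by projecting `delta * sin(x) - B^+ omega`
onto the orthogonal complement of `ker(B)` (tolerance 1e-9). Zero weights are
rejected. `weights_for_patterns` stacks `B diag(sin x^{(k)})` over all
targets and solves the joint linear system by least squares (or an LP when
nonnegativity is requested); targets with any `sin(x_e) = 0` are rejected.
The solution set is reported as `singleton` or a `subspace` with its kernel
dimension.

Closed-form enumeration of equilibria is implemented for homogeneous trees
(the `2^(n-1)` vectors with entries in `{0, pi}`) and homogeneous cycles
(those plus the `n - 1` splay states with consecutive cyclic differences
`2*pi*m/n`, `m = 1..n-1`, mapped from the cyclic walk orientation to the
lexicographic edge orientation with sign flips). Every enumerated member is
verified to residual 1e-12. Heterogeneous networks and other topologies are
rejected rather than approximated.

## Stability

The Jacobian at a locked state is `J = -B diag(delta * cos x) B^T`. One zero
eigenvalue (the rotational mode, identified as the near-zero eigenvalue whose
eigenvector has maximal overlap with `1`, tolerance 1e-9) is excluded from
classification; the state is `stable` if all remaining eigenvalues are
negative, `unstable` if any is positive, `marginal` otherwise. Gerschgorin
disks of `J` are reported alongside.

Sign-based screens (`instability_tests`):

- **Structural balance.** The signed graph with edge signs
  `sign(delta_e cos x_e)` is 2-colored (positive = same side, negative =
  opposite). If it is balanced, has at least one genuinely negative edge and
  both sides nonempty, the equilibrium cannot be stable. All-positive
  patterns are vacuously balanced and are deliberately *not* flagged.
- **Line rule.** On a tree path, any `|x_e| > pi/2` implies instability.
- **Cycle rule.** On a cycle, at most one difference may lie in
  `(pi/2, gamma)` where `gamma` solves `gamma - tan(gamma) = 2*pi` on
  `(pi/2, pi)`; `gamma = 1.789776...` is computed both by `brentq` and by an
  independent bisection (`gamma_threshold_bisect`), agreeing to 1e-9.

Verdicts are `UNSTABLE`, `CANNOT_BE_STABLE` or `INCONCLUSIVE`; the screens
are one-sided and never certify stability — use the Jacobian for that.

`signflip_design` searches for mixed-sign weights realizing a pattern
stably: it solves `B Delta D(x) delta = omega` with
`Delta = diag(sign cos x)` for `delta >= 0` via the same LP, returning the
signs, magnitudes and signed weights.

## Optimal corrections

- **Weight tuning** (`tune_weights`): minimize `||alpha||` subject to
  `B D(x^{(k)}) (delta + alpha) = omega_centered` for all targets and
  `delta + alpha >= 0`. The l2 problem is solved *exactly* by nullspace
  reduction followed by the Lawson-Hanson chain (least squares with
  inequality constraints -> least distance programming -> `scipy.optimize.nnls`);
  no iterative convex-programming solver is involved. The l1 problem is the
  standard epigraph LP.
- **Stability-promoting tuning** (`stability_promoting_tune`): same
  constraints, objective restricted to the weights of negative-cosine edges,
  with a small regularization (1e-6) toward the original weights to select a
  unique minimizer on the flat directions. Jacobian reports before and after
  are attached to the result.
- **Joint tuning** (`joint_tune`): simultaneous weight and frequency
  corrections from the closed form
  `[alpha; beta] = pinv([B D(x), -I]) (omega - B D(x) delta)` (raw, not
  centered, frequencies: the frequency correction absorbs the mean).
- `correction_trace` reports Jacobian classifications along fractions
  0, 1/3, 2/3, 1 of a correction.

## Simulation and empirical patterns

Fixed-step integration, default RK4 with `dt = 0.01` (explicit Euler
available for convergence testing); non-finite states raise. Lock detection
computes finite-difference instantaneous frequencies on a trailing window
(default last 20% of the trajectory) and requires their spread below 1e-6;
the locked difference vector is read from the final state. Empirical
patterns average `cos(theta_i - theta_j)` over the trailing window via Gram
matrices `(C^T C + S^T S)/T`. Pearson patterns (`pearson_pattern`) are plain
`np.corrcoef` of signal columns with zero-variance columns rejected; on
phase-locked cosine signals averaged over whole periods they approximate the
cosine pattern to spectral-norm error below 0.05 (property-tested).

## Fixtures

`make_topology` builds line, cycle, complete and seeded random connected
graphs (edges always sorted); `make_stable_instance` draws phases with
differences below `max_diff` (default 1.2 < pi/2), weights in [0.5, 2], and
assigns frequencies so the target is an exact, provably stable equilibrium.
Named instances include the triangle splay state, a parametric 4-cycle
family of equilibria, small trees, and a 7-node mixed-sign target whose
network parameters are distributed separately (loader provided, parameters
not bundled).

## Limitations

- Exact Hamiltonian-path search is limited to 12 nodes (supply a known path
  for larger graphs).
- Equilibrium enumeration covers homogeneous trees and cycles only; general
  graphs would require solving trigonometric systems.
- The sign-based stability screens are necessary-condition tests only.
- Fixed-step integration: no adaptive error control; choose `dt` against the
  stiffest frequency/weight scale (the provided defaults suit the bundled
  fixtures).
- The 7-node benchmark spectrum cannot be reproduced without the separately
  distributed parameters; the corresponding acceptance test fails by design
  until they are supplied at `tests/data/seven_node_network.json`.
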