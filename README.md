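# oscpattern

Functional-pattern analysis and control of Kuramoto oscillator networks.

A *functional pattern* is the matrix of time-averaged cosines of pairwise
phase differences, `R_ij = <cos(theta_j - theta_i)>` — the model analogue of a
functional-connectivity matrix. On a phase-locked trajectory all differences
are constant, so the pattern is determined by a vector `x` of per-edge phase
differences. This package answers, for a given interconnection structure and
natural frequencies:

- **Feasibility** — does a nonnegative (or strictly positive) assignment of
  coupling weights make a desired pattern an equilibrium? Exact decision by
  linear programming over the cone of sign-adjusted incidence columns, plus
  cheap sufficient certificates and Hamiltonian-path constructions for
  strictly positive solutions.
- **Multi-pattern design** — which patterns can coexist as equilibria of one
  network, characterized through the cycle space of the graph, and how to
  compute one weight vector serving several target patterns at once.
- **Stability** — Jacobian spectra of phase-locked equilibria, sign-based
  instability screens (structural balance of the cosine-scaled signed graph;
  a line rule for differences beyond pi/2; a cycle rule built on the
  threshold `gamma = 1.789776`, the root of `gamma - tan(gamma) = 2*pi`), and
  mixed-sign weight designs that restore stability.
- **Optimal correction** — minimum-norm adjustments of weights (l2 or l1),
  stability-promoting adjustments that suppress negative-cosine edges, and
  joint weight/frequency corrections in closed form.
- **Simulation** — fixed-step RK4 integration of the phase dynamics, lock
  detection, empirical patterns from trajectories, and Pearson-correlation
  patterns of cosine signals for comparison with data-style pipelines.

The dynamics are the standard heterogeneous Kuramoto model on an undirected
graph with weights `delta >= 0` and natural frequencies `omega`:

```
dtheta_i/dt = omega_i + sum_j A_ij * sin(theta_j - theta_i)
```

Equilibria in the rotating frame satisfy `B D(x) delta = omega - mean(omega)`
with `B` the oriented incidence matrix and `D(x) = diag(sin x)`. All solvers
work directly on this linear-algebraic form.

## Quick start

```python
import numpy as np
import oscpattern as op

# a 5-node network with a target functional pattern
net, x = op.make_stable_instance("random_connected", 5, seed=42)

# is the target realizable with nonnegative weights?
res = op.nonneg_feasible(op.build_incidence(net), net.omega, x.values)
print(res.status)                       # feasible_nonneg

# detune the weights, then compute the minimum-norm correction
detuned = net.with_delta(net.delta * 1.4)
corr = op.tune_weights(detuned, x)
print(np.round(corr.alpha, 3))          # [-0.494 -0.041 -0.906  0.007  0.022 -0.542 -0.528]

# simulate the corrected network from a perturbed start
fixed = detuned.with_delta(detuned.delta + corr.alpha)
theta0 = op.phases_from_diffs(fixed, x) + 0.05
traj = op.simulate(fixed, theta0, t_end=100)
rep = op.detect_phase_lock(traj, fixed)
print(rep.locked, rep.frequency)        # True 0.0

R = op.empirical_pattern(traj, window=0.2)
err = np.abs(R.matrix - op.analytic_pattern(x, fixed).matrix).max()
print(f"{err:.2e}")                     # 7.99e-15

print(op.jacobian(fixed, x).classification)   # stable
```

## Command line

The same workflows are exposed as a CLI:

```
oscpattern fixtures --make random_connected --n 5 --seed 8 --stable --out net.json,x.csv
oscpattern feasibility --network net.json --target x.csv
oscpattern feasibility --network net.json --target x.csv --strict
oscpattern stability --network net.json --x x.csv
oscpattern tune --network net.json --target x.csv --mode weights --out corr.json
oscpattern simulate --network net.json --t-end 40 --out traj.csv
oscpattern pattern --traj traj.csv --out R.csv
oscpattern multipattern check --network net.json --target x.csv
oscpattern multipattern design --structure net.json --target p1.csv --target p2.csv
```

Networks are JSON (1-based node indices), difference vectors and patterns are
CSV; see `docs/methods.md` for the formats and all numerical conventions.

## Package layout

| Module | Contents |
| --- | --- |
| `network_core` | network/pattern data types, incidence and difference operators, I/O |
| `kuramoto_sim` | RK4 simulation, lock detection, empirical and Pearson patterns |
| `feasibility` | LP feasibility, sufficient certificates, Hamiltonian-path positivity |
| `multipattern` | cycle-space compatibility, multi-pattern weight design, equilibrium enumeration |
| `stability` | Jacobian spectra, structural balance, sign-based screens, sign-flip designs |
| `pattern_control` | optimal l2/l1, stability-promoting, and joint corrections |
| `fixtures` | topology generators, guaranteed-stable instances, named benchmarks |
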