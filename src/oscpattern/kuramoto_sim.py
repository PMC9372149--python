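"""Numerical integration of the Kuramoto dynamics and empirical patterns.

The dynamics integrated here are

.. math:: \\dot\\theta_i = \\omega_i + \\sum_j A_{ij} \\sin(\\theta_j - \\theta_i),

in unwrapped phase coordinates (angles are only wrapped when patterns are
computed).  The empirical functional pattern is the entrywise time average
of ``cos(theta_j - theta_i)`` over a trailing window, and phase locking is
detected from the spread of instantaneous (finite-difference) frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_core import (
    DiffVector,
    FunctionalPattern,
    OscillatorNetwork,
    build_incidence,
    wrap_angle,
)

__all__ = [
    "Trajectory",
    "LockReport",
    "simulate",
    "empirical_pattern",
    "detect_phase_lock",
    "pearson_pattern",
    "load_trajectory",
    "save_trajectory",
]


@dataclass
class Trajectory:
    """Uniformly sampled unwrapped phases: ``phases[k]`` at ``times[k]``."""

    times: np.ndarray
    phases: np.ndarray  # shape (n_samples, n)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.shape[0] != self.times.shape[0]:
            raise ValueError("times and phases disagree in length")


@dataclass
class LockReport:
    locked: bool
    frequency: float
    x_hat: np.ndarray
    max_freq_spread: float


def _vector_field(network: OscillatorNetwork):
    B = build_incidence(network)
    delta = network.delta
    omega = network.omega

    def f(theta):
        return omega - B @ (np.sin(B.T @ theta) * delta)

    return f


def simulate(
    network: OscillatorNetwork,
    theta0,
    t_end: float,
    dt: float = 0.01,
    method: str = "rk4",
) -> Trajectory:
    """Integrate the phase dynamics from ``theta(0) = theta0``.

    Uses a classical fixed-step 4th-order Runge-Kutta scheme by default
    (``method="euler"`` is available for step-halving convergence checks).
    Raises if the state becomes non-finite.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    theta = np.array(theta0, dtype=float)
    if theta.shape != (network.n,):
        raise ValueError("theta0 must have one phase per oscillator")
    f = _vector_field(network)
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, network.n))
    out[0] = theta
    for k in range(n_steps):
        if method == "rk4":
            k1 = f(theta)
            k2 = f(theta + 0.5 * dt * k1)
            k3 = f(theta + 0.5 * dt * k2)
            k4 = f(theta + dt * k3)
            theta = theta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        elif method == "euler":
            theta = theta + dt * f(theta)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite state at t={times[k + 1]:.6g}")
        out[k + 1] = theta
    return Trajectory(times, out)


def _trailing_slice(n_samples: int, window: float) -> slice:
    if not (0.0 < window <= 1.0):
        raise ValueError("window must lie in (0, 1]")
    start = n_samples - max(1, int(np.ceil(window * n_samples)))
    return slice(start, n_samples)


def empirical_pattern(trajectory: Trajectory, window: float = 0.2) -> FunctionalPattern:
    """Time-averaged cosine pattern over the trailing ``window`` fraction.

    Uses the identity ``cos(a - b) = cos a cos b + sin a sin b`` so the
    average is a pair of Gram matrices.
    """
    sel = _trailing_slice(trajectory.phases.shape[0], window)
    th = trajectory.phases[sel]
    c, s = np.cos(th), np.sin(th)
    T = th.shape[0]
    return FunctionalPattern((c.T @ c + s.T @ s) / T)


def detect_phase_lock(
    trajectory: Trajectory,
    network: OscillatorNetwork | None = None,
    tol: float = 1e-6,
    window: float = 0.2,
) -> LockReport:
    """Decide whether the trailing window of a trajectory is phase-locked.

    Locked means the per-node instantaneous frequencies (finite
    differences) agree within ``tol`` across nodes throughout the window.
    Reports the common frequency (which at lock equals the mean natural
    frequency) and the per-edge differences at the final sample when a
    network is supplied (otherwise differences with respect to node 0).
    """
    if trajectory.times.shape[0] < 2:
        raise ValueError("need at least two samples")
    sel = _trailing_slice(trajectory.phases.shape[0] - 1, window)
    dtv = np.diff(trajectory.times)[:, None]
    freqs = np.diff(trajectory.phases, axis=0) / dtv
    fw = freqs[sel]
    spread = float(np.max(fw.max(axis=1) - fw.min(axis=1)))
    locked = spread <= tol
    theta_end = trajectory.phases[-1]
    if network is not None:
        x_hat = wrap_angle(build_incidence(network).T @ theta_end)
    else:
        x_hat = wrap_angle(theta_end - theta_end[0])
    return LockReport(locked, float(fw.mean()), x_hat, spread)


def pearson_pattern(signals) -> np.ndarray:
    """Pearson correlation matrix of per-node time series.

    ``signals`` has one column per node.  Provided to compare classical
    functional connectivity F against the phase-based pattern R on
    synthetic cosine signals.
    """
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2:
        raise ValueError("signals must be a 2-D array (time x node)")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance series")
    return np.corrcoef(X, rowvar=False)


def save_trajectory(traj: Trajectory, path):
    n = traj.phases.shape[1]
    cols = {"t": traj.times}
    for k in range(n):
        cols[f"theta_{k + 1}"] = traj.phases[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    th = df[[c for c in df.columns if c.startswith("theta_")]].to_numpy()
    return Trajectory(t, th)
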