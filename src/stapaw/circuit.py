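"""Minimal mutual-inhibition rate circuit for state-switching navigation.

Two noisy rate units, one per behavioral state (S = steer-enriched,
T = turn-enriched), obey

    tau dx_i/dt = -x_i + sum_j J_ij phi(x_j) + B_i I(t) + xi_i

with mutual inhibition (J_ST, J_TS < 0), a rectified-linear rate function
``phi``, and white noise ``xi``.  The sensory input ``I = F - S`` is the
difference of a fast and a slow filter of the experienced concentration
(an adapting ON response: positive transients when concentration rises):

    dF/dt = a C - b F,     dS/dt = g (F - S).

The unit with the larger activity dictates the behavioral strategy at each
moment; mutual inhibition makes the winner persist (hysteresis), grouping
turns into bouts and gating their termination on rising concentration.
Simulation uses the Euler method at dt = 0.1 s.

The S unit receives the input with positive weight and the T unit with
negative weight, so rising concentration favors running and falling
concentration favors turning — the same logic as the fitted state
transition kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import Environment, GaussianEnvironment
from .preprocessing import wrap_angle
from .simulate import _conc, _reflect

__all__ = [
    "CircuitParams",
    "BehaviorMap",
    "sensory_filter",
    "integrate_circuit",
    "run_navigation",
    "dwell_times",
]


@dataclass(frozen=True)
class CircuitParams:
    """Two-unit rate network parameters (units labeled S=0, T=1)."""

    tau: float = 1.0  # s
    J: tuple[tuple[float, float], tuple[float, float]] = ((0.0, -5.0), (-5.0, 0.0))
    B: tuple[float, float] = (3.0, -3.0)  # input weights onto (S, T)
    noise: float = 2.0
    alpha: float = 0.1  # concentration -> fast filter gain (1/s)
    beta: float = 0.5  # fast filter decay (1/s)
    gamma: float = 0.3  # slow filter rate (1/s)
    dt: float = 0.1  # s, Euler step

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be > 0")
        J = np.asarray(self.J, float)
        if J.shape != (2, 2) or J[0, 0] != 0 or J[1, 1] != 0:
            raise ValueError("J must be 2x2 with zero diagonal")
        if J[0, 1] > 0 or J[1, 0] > 0:
            raise ValueError("off-diagonal coupling must be <= 0 (inhibition)")

    def without_motif(self) -> "CircuitParams":
        """The J = 0 control: same units and inputs, no mutual inhibition."""
        return replace(self, J=((0.0, 0.0), (0.0, 0.0)))


@dataclass(frozen=True)
class BehaviorMap:
    """Winner-conditioned kinematics (per 0.1 s circuit step).

    A turn is a committed maneuver: once initiated (probability
    ``turn_prob`` per step for the current winner) the agent arcs through
    a reversal over ``turn_duration`` steps at the turn-state speed before
    it can resume running, like an omega turn that takes about a second.
    """

    turn_prob: tuple[float, float] = (0.005, 0.15)  # initiation P per step (S, T)
    kappa_wv: float = 150.0
    speed: tuple[float, float] = (0.005, 0.0015)  # cm per step for (S, T)
    turn_duration: int = 10  # steps (~1 s)
    turn_noise: float = 0.15  # rad per maneuver step, around the arc


def _phi(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sensory_filter(
    alpha: float, beta: float, gamma: float, C: np.ndarray, dt: float
) -> np.ndarray:
    """Fast-minus-slow filtered concentration, I = F - S (Euler integrated).

    Zero initial conditions; a constant input decays to I = 0 (adaptation),
    a step increase yields a positive transient.
    """
    if dt * beta >= 2 or dt * gamma >= 2:
        raise ValueError("dt too large for the filter rates (Euler unstable)")
    C = np.asarray(C, float)
    F = S = 0.0
    out = np.empty(len(C))
    for t, c in enumerate(C):
        F += dt * (alpha * c - beta * F)
        S += dt * gamma * (F - S)
        out[t] = F - S
    return out


def integrate_circuit(
    params: CircuitParams,
    I: np.ndarray,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the two-unit circuit driven by input series ``I``.

    Returns (activity (T, 2), winner (T,)).  Ties in the argmax are broken
    toward the current winner (sticky), so the winner series is
    well-defined under exact symmetry.
    """
    rng = np.random.default_rng(seed)
    I = np.asarray(I, float)
    T = len(I)
    J = np.asarray(params.J, float)
    B = np.asarray(params.B, float)
    dt, tau = params.dt, params.tau
    x = np.zeros(2) if x0 is None else np.asarray(x0, float).copy()
    xs = np.empty((T, 2))
    winner = np.empty(T, int)
    w = 0
    sq = np.sqrt(dt)
    for t in range(T):
        noise = params.noise * sq * rng.standard_normal(2)
        x = x + (dt / tau) * (-x + J @ _phi(x) + B * I[t]) + noise
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite circuit activity at step {t}")
        if x[0] != x[1]:
            w = int(np.argmax(x))
        xs[t] = x
        winner[t] = w
    return xs, winner


def dwell_times(winner: np.ndarray, dt: float) -> dict[int, np.ndarray]:
    """Per-state dwell-time samples (s) from a winner series."""
    winner = np.asarray(winner)
    change = np.flatnonzero(np.diff(winner)) + 1
    bounds = np.concatenate([[0], change, [len(winner)]])
    out: dict[int, list] = {0: [], 1: []}
    for a, b in zip(bounds[:-1], bounds[1:]):
        out[int(winner[a])].append((b - a) * dt)
    return {k: np.asarray(v) for k, v in out.items()}


def run_navigation(
    params: CircuitParams,
    env: Environment | None = None,
    behavior: BehaviorMap | None = None,
    n_tracks: int = 200,
    n_steps: int = 12000,
    seed: int = 0,
    start_radius: float = 2.5,
    ci_radius: float | None = None,
) -> dict:
    """Closed-loop navigation driven by the circuit's winner unit.

    Per step: sense concentration at the pose, update the sensory filters
    and circuit, read the winner, draw kinematics from the winner's
    behavior (S: weathervane-like run; T: frequent turns at low speed),
    and move.  Returns chemotaxis index, final distances, per-state dwell
    times, and the winner fraction.
    """
    env = env or GaussianEnvironment()
    behavior = behavior or BehaviorMap()
    rng = np.random.default_rng(seed)
    dt, tau = params.dt, params.tau
    if dt * params.beta >= 2 or dt * params.gamma >= 2:
        raise ValueError("dt too large for the filter rates")
    J = np.asarray(params.J, float)
    B = np.asarray(params.B, float)
    source = np.asarray(getattr(env, "center", (0.0, 0.0)), float)
    n = n_tracks
    ang = rng.uniform(-np.pi, np.pi, n)
    pos = source + start_radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    heading = rng.uniform(-np.pi, np.pi, n)
    F = np.zeros(n)
    S = np.zeros(n)
    x = np.zeros((n, 2))
    w = np.zeros(n, int)
    winners = np.empty((n, n_steps), int)
    sq = np.sqrt(dt)
    tp = np.asarray(behavior.turn_prob)
    speed = np.asarray(behavior.speed)
    maneuver = np.zeros(n, int)
    arc_dir = np.ones(n)

    for t in range(n_steps):
        C = _conc(env, pos)
        F += dt * (params.alpha * C - params.beta * F)
        S += dt * params.gamma * (F - S)
        I = F - S
        noise = params.noise * sq * rng.standard_normal((n, 2))
        x = x + (dt / tau) * (-x + _phi(x) @ J.T + I[:, None] * B[None, :]) + noise
        tie = x[:, 0] == x[:, 1]
        w = np.where(tie, w, np.argmax(x, axis=1))
        winners[:, t] = w

        # initiate committed reversal maneuvers; agents mid-maneuver arc on
        start = (maneuver == 0) & (rng.random(n) < tp[w])
        if start.any():
            maneuver[start] = behavior.turn_duration
            arc_dir[start] = rng.choice([-1.0, 1.0], size=int(start.sum()))
        active = maneuver > 0
        dtheta = np.empty(n)
        if active.any():
            k = int(active.sum())
            dtheta[active] = (arc_dir[active] * np.pi / behavior.turn_duration
                              + behavior.turn_noise * rng.standard_normal(k))
            maneuver[active] -= 1
        if (~active).any():
            dtheta[~active] = rng.vonmises(0.0, behavior.kappa_wv,
                                           size=int((~active).sum()))
        heading = wrap_angle(heading + dtheta)
        v = np.where(active, speed[1], speed[w])
        move = v[:, None] * np.stack([np.cos(heading), np.sin(heading)], axis=1)
        pos, heading = _reflect(pos + move, heading, env.bounds)

    d = np.linalg.norm(pos - source, axis=1)
    radius = ci_radius if ci_radius is not None else 0.5 * getattr(env, "sigma", 2.0)
    dw = {0: [], 1: []}
    for i in range(n):
        di = dwell_times(winners[i], dt)
        dw[0].append(di[0])
        dw[1].append(di[1])
    return {
        "ci": float(np.mean(d <= radius)),
        "final_distances": d,
        "dwell_times": {k: np.concatenate(v) if v else np.array([]) for k, v in dw.items()},
        "winner_fraction_T": float(np.mean(winners == 1)),
        "winners": winners,
        "ci_radius": radius,
    }
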