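"""Data-constrained reinforcement-learning model of state-switching navigation.

A two-action POMDP agent navigates a concentration landscape at constant
speed.  Its actions select behavioral states with fixed kinematic
statistics taken from the fitted two-state model: action 0 emits small
weathervane-like heading changes, action 1 emits broad turn/reversal
heading changes.  The only sensory observation is the one-step
concentration difference ``dC`` experienced while moving; the policy

    pi(a=1 | dC) = 1 / (1 + exp(K dC + b))

has two scalar parameters trained by REINFORCE (policy gradient on the
discounted return) with an Adam update.  The reward is the negative
distance to the source minus a switching penalty: an exponential filter of
the discrete actions weighted by ``lam``, which discourages pathological
rapid alternation and shapes realistic state occupancy.

Controls for evaluation: ``shuffled`` permutes a trained agent's action
sequence within episode (sensory-independent switching with identical
aggregate kinematics, the stateless-model analogue), ``fixed0``/``fixed1``
lock the agent in one state, and ``iid`` draws actions independently at the
trained agent's mean turn rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import Environment, GaussianEnvironment
from .preprocessing import wrap_angle
from .simulate import _reflect

__all__ = [
    "Policy",
    "RLKinematics",
    "RLConfig",
    "EpisodeBatch",
    "policy_prob",
    "reward",
    "step",
    "train",
    "evaluate",
    "CONTROLS",
]

CONTROLS = ("trained", "shuffled", "fixed0", "fixed1", "iid")


@dataclass
class Policy:
    """Logistic switching policy on the one-step concentration difference."""

    K: float = 0.0
    b: float = 0.0


@dataclass(frozen=True)
class RLKinematics:
    """State-conditioned heading-change statistics at constant speed.

    Action 0 draws from a von Mises around zero (weathervane-like run,
    optionally steered by the perpendicular concentration difference with
    gain ``steering_gain``); action 1 draws from the uniform/von Mises
    turn mixture centered on pi.
    """

    kappa_wv: float = 25.0
    kappa_turn: float = 1.2
    alpha: float = 0.1
    speed: float = 0.05  # cm per step
    steering_gain: float = 0.0  # rad per unit concentration difference


@dataclass(frozen=True)
class RLConfig:
    env: Environment = field(default_factory=lambda: GaussianEnvironment())
    kinematics: RLKinematics = field(default_factory=RLKinematics)
    lam: float = 0.1  # switching-penalty weight
    phi_tau: float = 5.0  # action-filter time constant, steps
    discount: float = 0.98
    lr: float = 0.05
    epochs: int = 1000
    episode_len: int = 400
    batch_size: int = 16
    start_radius: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.discount < 1):
            raise ValueError("discount must be in [0, 1)")
        if self.lam < 0 or self.phi_tau <= 0 or self.lr < 0:
            raise ValueError("lam, phi_tau must be positive; lr >= 0")


@dataclass
class EpisodeBatch:
    """Vectorized episode rollouts."""

    positions: np.ndarray  # (n, T+1, 2)
    actions: np.ndarray  # (n, T)
    observations: np.ndarray  # (n, T) dC available when each action was chosen
    rewards: np.ndarray  # (n, T)
    dthetas: np.ndarray  # (n, T)

    @property
    def final_positions(self) -> np.ndarray:
        return self.positions[:, -1]

    @property
    def returns(self) -> np.ndarray:
        return self.rewards.sum(axis=1)


def policy_prob(policy: Policy, dC: np.ndarray | float) -> np.ndarray | float:
    """Probability of choosing the turn action (a=1) given observation dC."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(policy.K * np.asarray(dC) + policy.b))


def reward(
    position: np.ndarray,
    action_history: np.ndarray,
    source: tuple[float, float],
    lam: float = 0.1,
    phi_tau: float = 5.0,
) -> float:
    """Reward at one step: -distance to source - lam * filtered action trace.

    The action filter is first-order exponential with time constant
    ``phi_tau`` steps and unit steady-state gain, applied causally to the
    history (most recent action last).
    """
    d = float(np.linalg.norm(np.asarray(position, float) - np.asarray(source, float)))
    a = np.asarray(action_history, float)
    decay = np.exp(-1.0 / phi_tau)
    phi = 0.0
    for ai in a:
        phi = decay * phi + (1 - decay) * ai
    return -d - lam * phi


def step(
    env: Environment,
    position: np.ndarray,
    heading: np.ndarray,
    action: np.ndarray,
    kin: RLKinematics,
    rng: np.random.Generator,
    sensor_offset: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance pose(s) one step; returns (position, heading, dC observation).

    Heading change is drawn from the action's state-conditioned
    distribution, the pose advances at constant speed, and the observation
    is the concentration difference across the move.
    """
    position = np.atleast_2d(np.asarray(position, float))
    heading = np.atleast_1d(np.asarray(heading, float))
    action = np.atleast_1d(np.asarray(action, int))
    n = len(heading)
    dtheta = np.empty(n)
    run = action == 0
    if run.any():
        mu = np.zeros(int(run.sum()))
        if kin.steering_gain != 0.0:
            h = heading[run]
            normal = np.stack([-np.sin(h), np.cos(h)], axis=1)
            p = position[run]
            dcp = (_safe_conc(env, p + sensor_offset * normal)
                   - _safe_conc(env, p - sensor_offset * normal))
            mu = kin.steering_gain * dcp
        dtheta[run] = rng.vonmises(mu, kin.kappa_wv)
    if (~run).any():
        k = int((~run).sum())
        vals = rng.vonmises(np.pi, kin.kappa_turn, size=k)
        u = rng.random(k) < kin.alpha
        vals[u] = rng.uniform(-np.pi, np.pi, size=int(u.sum()))
        dtheta[~run] = vals
    c_old = _safe_conc(env, position)
    heading = wrap_angle(heading + dtheta)
    move = kin.speed * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    position, heading = _reflect(position + move, heading, env.bounds)
    dC = _safe_conc(env, position) - c_old
    return position, heading, dC


def _safe_conc(env: Environment, p: np.ndarray) -> np.ndarray:
    xmin, xmax, ymin, ymax = env.bounds
    q = np.atleast_2d(np.asarray(p, float)).copy()
    q[:, 0] = np.clip(q[:, 0], xmin, xmax)
    q[:, 1] = np.clip(q[:, 1], ymin, ymax)
    return env._concentration(q)


def _run_episodes(
    cfg: RLConfig,
    policy: Policy,
    n_episodes: int,
    rng: np.random.Generator,
    forced_actions: np.ndarray | None = None,
    fixed_action: int | None = None,
    iid_p: float | None = None,
) -> EpisodeBatch:
    env, kin = cfg.env, cfg.kinematics
    T = cfg.episode_len
    n = n_episodes
    source = getattr(env, "center", (0.0, 0.0))
    ang = rng.uniform(-np.pi, np.pi, n)
    pos = np.asarray(source, float) + cfg.start_radius * np.stack(
        [np.cos(ang), np.sin(ang)], axis=1)
    heading = rng.uniform(-np.pi, np.pi, n)
    decay = np.exp(-1.0 / cfg.phi_tau)
    phi = np.zeros(n)
    obs = np.zeros(n)

    positions = np.empty((n, T + 1, 2))
    positions[:, 0] = pos
    actions = np.empty((n, T), int)
    observations = np.empty((n, T))
    rewards = np.empty((n, T))
    dthetas = np.empty((n, T))

    for t in range(T):
        observations[:, t] = obs
        if forced_actions is not None:
            a = forced_actions[:, t]
        elif fixed_action is not None:
            a = np.full(n, fixed_action, int)
        elif iid_p is not None:
            a = (rng.random(n) < iid_p).astype(int)
        else:
            p1 = np.asarray(policy_prob(policy, obs))
            a = (rng.random(n) < p1).astype(int)
        h_prev = heading.copy()
        pos, heading, obs = step(env, pos, heading, a, kin, rng)
        dthetas[:, t] = wrap_angle(heading - h_prev)
        phi = decay * phi + (1 - decay) * a
        d = np.linalg.norm(pos - np.asarray(source, float), axis=1)
        rewards[:, t] = -d - cfg.lam * phi
        actions[:, t] = a
        positions[:, t + 1] = pos
    return EpisodeBatch(positions, actions, observations, rewards, dthetas)


def train(cfg: RLConfig) -> tuple[Policy, dict]:
    """REINFORCE training of the switching policy.

    Returns the trained policy and learning curves: per-epoch expected
    total reward, its 50-epoch running average, and the chemotaxis index
    probed every 50 epochs.
    """
    rng = np.random.default_rng(cfg.seed)
    policy = Policy(0.0, 0.0)
    theta = np.array([policy.K, policy.b])
    m_adam = np.zeros(2)
    v_adam = np.zeros(2)
    eps = 1e-8
    beta1, beta2 = 0.9, 0.999
    gpow = cfg.discount ** np.arange(cfg.episode_len)
    rewards_curve = []
    ci_curve = []
    ci_radius = _ci_radius(cfg.env)
    source = getattr(cfg.env, "center", (0.0, 0.0))

    for epoch in range(cfg.epochs):
        batch = _run_episodes(cfg, Policy(*theta), cfg.batch_size, rng)
        disc = batch.rewards * gpow[None, :]
        # discounted reward-to-go with a batch-mean baseline per time step
        G = np.flip(np.cumsum(np.flip(disc, axis=1), axis=1), axis=1) / gpow[None, :]
        adv = G - G.mean(axis=0, keepdims=True)
        ell = theta[0] * batch.observations + theta[1]
        with np.errstate(over="ignore"):
            p1 = 1.0 / (1.0 + np.exp(ell))
        score = p1 - batch.actions  # d log pi(a) / d logit
        gK = float(np.mean(np.sum(adv * score * batch.observations, axis=1)))
        gb = float(np.mean(np.sum(adv * score, axis=1)))
        grad = np.array([gK, gb])
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite policy gradient at epoch {epoch}")
        if cfg.lr > 0:
            m_adam = beta1 * m_adam + (1 - beta1) * grad
            v_adam = beta2 * v_adam + (1 - beta2) * grad**2
            mhat = m_adam / (1 - beta1 ** (epoch + 1))
            vhat = v_adam / (1 - beta2 ** (epoch + 1))
            theta = theta + cfg.lr * mhat / (np.sqrt(vhat) + eps)  # ascent
        rewards_curve.append(float(batch.returns.mean()))
        if (epoch + 1) % 50 == 0 or epoch == cfg.epochs - 1:
            d = np.linalg.norm(batch.final_positions - np.asarray(source), axis=1)
            ci_curve.append((epoch, float(np.mean(d <= ci_radius))))

    rewards_curve = np.asarray(rewards_curve)
    k = min(50, len(rewards_curve))
    running = np.convolve(rewards_curve, np.ones(k) / k, mode="valid")
    return Policy(*theta), {
        "expected_reward": rewards_curve,
        "running_average_50": running,
        "ci_probe": ci_curve,
    }


def _ci_radius(env: Environment) -> float:
    sigma = getattr(env, "sigma", None)
    return 0.5 * sigma if sigma else 1.0


def evaluate(
    policy: Policy,
    cfg: RLConfig,
    control: str = "trained",
    n_episodes: int = 200,
    seed: int = 0,
    env: Environment | None = None,
) -> dict:
    """Chemotaxis index and final-distance distribution for an agent.

    ``control='shuffled'`` first rolls out the trained policy, then replays
    with each episode's action sequence permuted (identical aggregate
    kinematics, sensory-independent timing).
    """
    if control not in CONTROLS:
        raise ValueError(f"control must be one of {CONTROLS}")
    if env is not None:
        from dataclasses import replace as _replace
        cfg = _replace(cfg, env=env)
    rng = np.random.default_rng(seed)
    if control == "trained":
        batch = _run_episodes(cfg, policy, n_episodes, rng)
    elif control == "fixed0":
        batch = _run_episodes(cfg, policy, n_episodes, rng, fixed_action=0)
    elif control == "fixed1":
        batch = _run_episodes(cfg, policy, n_episodes, rng, fixed_action=1)
    else:
        ref = _run_episodes(cfg, policy, n_episodes, np.random.default_rng(seed + 1))
        if control == "iid":
            batch = _run_episodes(cfg, policy, n_episodes, rng,
                                  iid_p=float(ref.actions.mean()))
        else:  # shuffled within episode
            forced = np.stack([
                row[rng.permutation(len(row))] for row in ref.actions
            ])
            batch = _run_episodes(cfg, policy, n_episodes, rng,
                                  forced_actions=forced)
    source = np.asarray(getattr(cfg.env, "center", (0.0, 0.0)), float)
    d = np.linalg.norm(batch.final_positions - source, axis=1)
    radius = _ci_radius(cfg.env)
    return {
        "control": control,
        "ci": float(np.mean(d <= radius)),
        "final_distances": d,
        "ci_radius": radius,
        "batch": batch,
    }
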