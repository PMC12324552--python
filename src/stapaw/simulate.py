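"""Generative simulation of navigation trajectories from staPAW parameters.

``simulate`` runs the model closed-loop in a concentration landscape: at
every step the agent senses the field at its pose, the latent state evolves
through the input-driven transition matrix, the turn decision and
kinematics are drawn from the state's emissions, and the pose advances
(with a reflecting arena boundary).  ``simulate_open_loop`` drives the same
behavioral machinery with externally supplied sensory series (no positional
feedback), as in optogenetic stimulation protocols.

``fixture_params`` provides documented ground-truth parameter presets that
emulate the measured two-state phenomenology: a steer-enriched state with
rare turns, higher speed and active weathervane steering; a turn-enriched
state with ~2 reversals per bout at lower speed and a concentration-
integrating turn kernel; mirror-image derivative-shaped transition kernels
(entering the turn state when concentration falls, leaving it when
concentration rises); and baselines giving seconds-scale dwell times
(4.6 s turn-enriched, 8.1 s steer-enriched at the 5/14 s step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import Environment, LinearEnvironment
from .model import (
    EmissionParams,
    Kernel,
    RaisedCosineBasis,
    StaPAWParams,
    Standardization,
    TransitionParams,
)
from .preprocessing import Dataset, Track, wrap_angle

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "simulate_open_loop",
    "fixture_params",
    "negate_transition_kernels",
    "PRESETS",
]

DT = 5.0 / 14.0


@dataclass(frozen=True)
class SimConfig:
    """Closed-loop simulation settings."""

    n_tracks: int = 40
    n_steps: int = 1500
    seed: int = 0
    start_frac: float = 0.5  # start poses uniform over this central fraction
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass
class SimResult:
    """Simulated tracks with their latent state and turn-decision series."""

    tracks: list[Track]
    z: list[np.ndarray]
    q: list[np.ndarray]

    def to_dataset(self, metadata: dict | None = None) -> Dataset:
        return Dataset(self.tracks, dict(metadata or {}))


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------


def _clip_to_bounds(p: np.ndarray, bounds) -> np.ndarray:
    xmin, xmax, ymin, ymax = bounds
    out = p.copy()
    out[..., 0] = np.clip(out[..., 0], xmin, xmax)
    out[..., 1] = np.clip(out[..., 1], ymin, ymax)
    return out


def _conc(env: Environment, p: np.ndarray) -> np.ndarray:
    """Concentration with sample points clipped into the domain (sensor
    offsets may poke past the arena wall)."""
    return env._concentration(np.atleast_2d(_clip_to_bounds(p, env.bounds)))


def _reflect(pos: np.ndarray, heading: np.ndarray, bounds):
    xmin, xmax, ymin, ymax = bounds
    x, y = pos[:, 0].copy(), pos[:, 1].copy()
    h = heading.copy()
    for _ in range(2):  # two passes handle corner cases
        m = x < xmin
        x[m] = 2 * xmin - x[m]
        h[m] = np.pi - h[m]
        m = x > xmax
        x[m] = 2 * xmax - x[m]
        h[m] = np.pi - h[m]
        m = y < ymin
        y[m] = 2 * ymin - y[m]
        h[m] = -h[m]
        m = y > ymax
        y[m] = 2 * ymax - y[m]
        h[m] = -h[m]
    x = np.clip(x, xmin, xmax)
    y = np.clip(y, ymin, ymax)
    return np.stack([x, y], axis=1), wrap_angle(h)


class _KernelBank:
    """Realized lag weights of all kernels, for O(L) per-step drives."""

    def __init__(self, params: StaPAWParams):
        Z = params.n_states
        L = params.basis.n_lags
        self.L = L
        self.trans_w = np.zeros((Z, Z, L))
        for (i, j), k in params.transitions.kernels.items():
            self.trans_w[i, j] = k.weights
        self.trans_ow = None
        if params.transitions.O is not None:
            self.trans_ow = np.zeros((Z, Z, L))
            for (i, j), k in params.transitions.O.items():
                self.trans_ow[i, j] = k.weights
        self.kc = np.stack([em.K_C.weights for em in params.emissions])
        self.kh = np.stack([em.K_h.weights for em in params.emissions])
        self.kd = np.stack([em.K_dcp.weights for em in params.emissions])
        self.ko = None
        if all(em.K_O is not None for em in params.emissions):
            self.ko = np.stack([em.K_O.weights for em in params.emissions])


def _draw_dtheta(rng, em: EmissionParams, q: np.ndarray, mu_wv: np.ndarray):
    n = len(q)
    out = np.empty(n)
    turn = q == 1
    n_turn = int(turn.sum())
    if n_turn:
        uniform = rng.random(n_turn) < em.alpha
        vals = rng.vonmises(np.pi, em.kappa_turn, size=n_turn)
        vals[uniform] = rng.uniform(-np.pi, np.pi, size=int(uniform.sum()))
        out[turn] = vals
    if n_turn < n:
        out[~turn] = rng.vonmises(mu_wv[~turn], em.kappa_wv)
    return wrap_angle(out)


def _zero_drive_matrix(params: StaPAWParams) -> np.ndarray:
    Z = params.n_states
    logits = np.diag(params.transitions.baselines)
    P = np.exp(logits - logits.max(axis=1, keepdims=True))
    return P / P.sum(axis=1, keepdims=True)


def _stationary(P: np.ndarray) -> np.ndarray:
    v = np.ones(P.shape[0]) / P.shape[0]
    for _ in range(500):
        v = v @ P
    return v / v.sum()


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------


def simulate(
    params: StaPAWParams, env: Environment, cfg: SimConfig,
    sensor_offset: float = 0.05,
) -> SimResult:
    """Sample navigation trajectories closed-loop in a landscape.

    Per step and per track: sense (C and the perpendicular difference at
    the current pose), advance the latent state from the input-driven
    transition matrix, draw the turn decision, draw heading change and
    speed from the state's emissions, then move with a reflecting boundary.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_tracks, cfg.n_steps
    Z = params.n_states
    st = params.standardization
    bank = _KernelBank(params)
    L = bank.L
    xmin, xmax, ymin, ymax = env.bounds
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    hx, hy = (xmax - xmin) / 2 * cfg.start_frac, (ymax - ymin) / 2 * cfg.start_frac
    pos = np.stack([
        rng.uniform(cx - hx, cx + hx, n),
        rng.uniform(cy - hy, cy + hy, n),
    ], axis=1)
    heading = rng.uniform(-np.pi, np.pi, n)
    z = rng.choice(Z, size=n, p=_stationary(_zero_drive_matrix(params)))

    # rolling history buffers, column 0 = lag 1 (standardized units)
    buf_c = np.zeros((n, L))
    buf_h = np.zeros((n, L))
    buf_d = np.zeros((n, L))

    rec = {k: np.empty((n, T)) for k in
           ("dtheta", "dr", "heading", "C", "dcp", "z", "q")}
    rec_pos = np.empty((n, T, 2))

    gshape = np.array([[em.gamma_turn[0], em.gamma_run[0]] for em in params.emissions])
    gscale = np.array([[em.gamma_turn[1], em.gamma_run[1]] for em in params.emissions])

    for t in range(T):
        C = _conc(env, pos)
        zc = np.asarray(st.c(C))

        # input-driven transition using history strictly before t
        drive = np.einsum("ijl,nl->nij", bank.trans_w, buf_c)
        logits = drive + np.diag(params.transitions.baselines)[None]
        logits -= logits.max(axis=2, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=2, keepdims=True)
        rows = P[np.arange(n), z]
        z = (rng.random(n)[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)

        # turn decision
        u = np.einsum("zl,nl->nz", bank.kc, buf_c)[np.arange(n), z]
        u = u + np.einsum("zl,nl->nz", bank.kh, buf_h)[np.arange(n), z]
        mz = np.array([em.m for em in params.emissions])[z]
        Mz = np.array([em.M for em in params.emissions])[z]
        with np.errstate(over="ignore"):
            p = mz + (Mz - mz) / (1 + np.exp(u))
        q = (rng.random(n) < p).astype(int)

        # heading change and speed
        mu_wv = -np.einsum("zl,nl->nz", bank.kd, buf_d)[np.arange(n), z]
        dtheta = np.empty(n)
        for zz in range(Z):
            m = z == zz
            if m.any():
                dtheta[m] = _draw_dtheta(rng, params.emissions[zz], q[m], mu_wv[m])
        heading = wrap_angle(heading + dtheta)
        dr = rng.gamma(gshape[z, 1 - q], gscale[z, 1 - q])

        # sense the steering signal at the new heading
        normal = np.stack([-np.sin(heading), np.cos(heading)], axis=1)
        dcp = (_conc(env, pos + sensor_offset * normal)
               - _conc(env, pos - sensor_offset * normal))

        rec_pos[:, t] = pos
        rec["dtheta"][:, t] = dtheta
        rec["dr"][:, t] = dr
        rec["heading"][:, t] = heading
        rec["C"][:, t] = C
        rec["dcp"][:, t] = dcp
        rec["z"][:, t] = z
        rec["q"][:, t] = q

        # push into history buffers (used from step t+1 on)
        buf_c = np.roll(buf_c, 1, axis=1)
        buf_c[:, 0] = zc
        buf_h = np.roll(buf_h, 1, axis=1)
        buf_h[:, 0] = np.abs(dtheta)
        buf_d = np.roll(buf_d, 1, axis=1)
        buf_d[:, 0] = np.asarray(st.dcp(dcp))

        # move
        step = dr[:, None] * np.stack([np.cos(heading), np.sin(heading)], axis=1)
        pos, heading = _reflect(pos + step, heading, env.bounds)

    tracks, zs, qs = [], [], []
    for i in range(n):
        tracks.append(Track(
            track_id=f"sim{i:03d}", dt=params.dt,
            dtheta=rec["dtheta"][i], dr=rec["dr"][i],
            position=rec_pos[i], heading=rec["heading"][i],
            C=rec["C"][i], dC_perp=rec["dcp"][i],
        ))
        zs.append(rec["z"][i].astype(int))
        qs.append(rec["q"][i].astype(int))
    return SimResult(tracks=tracks, z=zs, q=qs)


# ---------------------------------------------------------------------------
# open-loop simulation
# ---------------------------------------------------------------------------


def simulate_open_loop(
    params: StaPAWParams,
    C: np.ndarray,
    dC_perp: np.ndarray | None = None,
    I: np.ndarray | None = None,
    seed: int = 0,
) -> SimResult:
    """Draw states and kinematics under fixed external sensory input.

    ``C`` (and optionally ``dC_perp`` and an optogenetic series ``I``) are
    experienced passively: there is no feedback through position.  Returns
    a single-track :class:`SimResult` whose positions are dead-reckoned
    from the emitted kinematics.
    """
    rng = np.random.default_rng(seed)
    C = np.asarray(C, float)
    T = len(C)
    dC_perp = np.zeros(T) if dC_perp is None else np.asarray(dC_perp, float)
    if len(dC_perp) != T or (I is not None and len(I) != T):
        raise ValueError("sensory series lengths must match")
    st = params.standardization
    bank = _KernelBank(params)
    L = bank.L
    Z = params.n_states

    zc = np.asarray(st.c(C))
    zd = np.asarray(st.dcp(dC_perp))
    buf_c = np.zeros(L)
    buf_h = np.zeros(L)
    buf_d = np.zeros(L)
    buf_i = np.zeros(L)

    z = int(rng.choice(Z, p=_stationary(_zero_drive_matrix(params))))
    ms = np.array([em.m for em in params.emissions])
    Ms = np.array([em.M for em in params.emissions])

    out = {k: np.empty(T) for k in ("dtheta", "dr", "z", "q")}
    for t in range(T):
        logits = bank.trans_w[z] @ buf_c + np.where(
            np.arange(Z) == z, params.transitions.baselines, 0.0)
        if bank.trans_ow is not None and I is not None:
            logits = logits + bank.trans_ow[z] @ buf_i
        P = np.exp(logits - logits.max())
        P /= P.sum()
        z = int(rng.choice(Z, p=P))

        u = bank.kc[z] @ buf_c + bank.kh[z] @ buf_h
        if bank.ko is not None and I is not None:
            u += bank.ko[z] @ buf_i
        p = ms[z] + (Ms[z] - ms[z]) / (1 + np.exp(u))
        q = int(rng.random() < p)
        em = params.emissions[z]
        mu = -(bank.kd[z] @ buf_d)
        dtheta = float(_draw_dtheta(rng, em, np.array([q]), np.array([mu]))[0])
        a, b = em.gamma_turn if q else em.gamma_run
        dr = float(rng.gamma(a, b))

        out["dtheta"][t] = dtheta
        out["dr"][t] = dr
        out["z"][t] = z
        out["q"][t] = q

        buf_c = np.roll(buf_c, 1)
        buf_c[0] = zc[t]
        buf_h = np.roll(buf_h, 1)
        buf_h[0] = abs(dtheta)
        buf_d = np.roll(buf_d, 1)
        buf_d[0] = zd[t]
        if I is not None:
            buf_i = np.roll(buf_i, 1)
            buf_i[0] = I[t]

    heading = wrap_angle(np.cumsum(out["dtheta"]))
    steps = out["dr"][:, None] * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    pos = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)[:-1]])
    track = Track(
        track_id="openloop", dt=params.dt,
        dtheta=out["dtheta"], dr=out["dr"], position=pos, heading=heading,
        C=C, dC_perp=dC_perp, I=None if I is None else np.asarray(I, float),
    )
    return SimResult(tracks=[track], z=[out["z"].astype(int)],
                     q=[out["q"].astype(int)])


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

PRESETS = ("paperlike-2state", "hmm-2state", "dpaw-1state", "opto-2state")

# target dwell times (s) for the two states under zero sensory drive
DWELL_T_S = 4.6
DWELL_S_S = 8.1

# gain of the derivative-shaped transition kernels on standardized
# concentration: sized so that run-speed motion along the default linear
# gradient (~0.01 standardized units across the 2+2-lag window) shifts the
# transition logit by roughly 1.5
TRANSITION_GAIN = 160.0
# turning-kernel gain within a state (biased-random-walk strength); the
# derivative profile sees windowed concentration differences (~0.01
# standardized units), the integrator profile sees the level itself (~1
# unit), so their gains differ by the corresponding factor to keep the
# logit contribution of order one (a graded, non-saturated nonlinearity)
TURN_GAIN = 60.0
TURN_INTEG_GAIN = 2.5


def _profiles(basis: RaisedCosineBasis):
    L = basis.n_lags
    # fast biphasic (derivative-like) profile: the gating window must be
    # commensurate with heading persistence inside a turn bout (~2 steps),
    # or directional gating of bout exits is averaged away
    deriv = np.zeros(L)
    k = min(2, L // 2)
    deriv[:k] = 1.0 / k
    deriv[k:2 * k] = -1.0 / k
    # positive weights lower the decision drive when concentration is low
    # (the drive enters as 1/(1+exp(u))), i.e. turn more when life is worse
    integ = np.zeros(L)
    integ[:8] = 1.0 / 8
    refr = np.exp(-np.arange(L) / 2.0)
    steer = np.zeros(L)
    steer[:3] = -np.array([0.08, 0.04, 0.02])
    pulse = np.exp(-np.arange(L) / 4.0)
    return deriv, integ, refr, steer, pulse


def fixture_params(preset: str, seed: int | None = None) -> StaPAWParams:
    """Ground-truth parameter presets for simulation and testing.

    Presets are deterministic (``seed`` is accepted for interface
    compatibility and ignored).  ``paperlike-2state`` is the reference
    two-state model; ``hmm-2state`` zeroes its transition kernels;
    ``dpaw-1state`` is a single-state reduction; ``opto-2state`` adds
    optogenetic kernels that drive entry into the turn-enriched state.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    basis = RaisedCosineBasis(n_basis=4, n_lags=14)
    deriv, integ, refr, steer, pulse = _profiles(basis)
    st = Standardization(c_mean=25.0, c_scale=14.4, dcp_mean=0.0, dcp_scale=0.3)

    def K(profile, gain=1.0):
        # biphasic (zero-sum) targets keep their level-insensitivity
        zero_sum = abs(profile.sum()) < 1e-9
        return Kernel.from_weights(gain * profile, basis, zero_sum=zero_sum)

    zero = Kernel.zeros(basis)
    opto = preset == "opto-2state"

    # Steer-enriched state: rare turns at a constant low rate (mean
    # inter-turn interval ~9 s), active weathervane steering, higher speed.
    em_S = EmissionParams(
        M=0.04, m=0.04,
        K_C=zero,  # turning modulation lives in the T-state
        K_h=zero,
        alpha=0.20, kappa_turn=3.0, kappa_wv=25.0,
        K_dcp=K(steer, 0.1),  # weathervane toward the higher side (weak)
        gamma_turn=(5.0, 0.0012), gamma_run=(10.0, 0.0012),
        K_O=K(pulse, -0.8) if opto else None,
    )
    # Turn-enriched state: ~2 turns per 4.6 s bout, lower speed, an
    # integrating turn kernel (turn more when concentration is low) and a
    # refractory heading-history kernel; steering suppressed.
    em_T = EmissionParams(
        M=0.60, m=0.10,
        K_C=K(integ, TURN_INTEG_GAIN),
        K_h=K(refr, 0.5),
        alpha=0.20, kappa_turn=2.5, kappa_wv=8.0,
        K_dcp=zero,
        gamma_turn=(4.0, 0.0008), gamma_run=(5.0, 0.0011),
        K_O=K(pulse, -0.4) if opto else None,
    )

    dt = DT
    if preset == "dpaw-1state":
        # the stateless control: mildly modulated memoryless turning, so
        # its inter-turn intervals stay close to a single exponential
        em = replace(em_S, M=0.5, m=0.05,
                     K_C=K(deriv, TURN_GAIN / 4), K_h=K(refr, 0.5))
        return StaPAWParams(
            n_states=1, emissions=[em],
            transitions=TransitionParams(n_states=1, baselines=np.zeros(1)),
            dt=dt, standardization=st, basis=basis,
        )

    stay_S = 1.0 - dt / DWELL_S_S
    stay_T = 1.0 - dt / DWELL_T_S
    baselines = np.array([
        np.log(stay_S / (1 - stay_S)),
        np.log(stay_T / (1 - stay_T)),
    ])
    if preset == "hmm-2state":
        kernels = {}
    else:
        kernels = {
            (0, 1): K(deriv, -TRANSITION_GAIN),  # enter T when C falls
            (1, 0): K(deriv, +TRANSITION_GAIN),  # exit T when C rises
        }
    O = None
    if opto:
        O = {
            (0, 1): K(pulse, 1.2),  # stimulation drives entry into T
            (1, 0): K(pulse, -0.6),
        }
    trans = TransitionParams(n_states=2, baselines=baselines, kernels=kernels, O=O)
    return StaPAWParams(
        n_states=2, emissions=[em_S, em_T], transitions=trans,
        dt=dt, standardization=st, basis=basis,
    )


def negate_transition_kernels(params: StaPAWParams) -> StaPAWParams:
    """Flip the sign of all concentration transition kernels (goal reversal)."""
    trans = params.transitions
    flipped = {p: Kernel(-k.coeffs, k.basis) for p, k in trans.kernels.items()}
    return replace(params, transitions=replace(trans, kernels=flipped))
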