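"""staPAW parameterization and probability computations.

The model is hierarchical:

* latent state ``z_t`` (steer-enriched S vs turn-enriched T) follows an
  input-driven Markov chain whose transition logits are temporal kernels
  applied to the recent concentration history, plus a per-state baseline on
  the self-transition;
* within a state, a Bernoulli turn decision ``q_t`` is a range-limited
  logistic function of filtered concentration and turn-magnitude history,
  ``P(q=1) = m + (M - m) / (1 + exp(K_C.C + K_h.|dtheta|))``;
* heading change is a uniform/von Mises mixture centered on pi for turns
  (q=1) and a von Mises steered by the perpendicular concentration history
  for weathervaning (q=0); speed is Gamma distributed per (state, decision).

Temporal kernels are low-dimensional: coefficients on a raised-cosine basis
spanning L steps of history (about 5 s at the 5/14 s step).  Sensory inputs
are z-scored with dataset-level constants stored in the parameters so that
simulation and fitting use identical filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import gammaln, i0e, i1e

from .preprocessing import Track, wrap_angle

__all__ = [
    "RaisedCosineBasis",
    "Kernel",
    "Standardization",
    "EmissionParams",
    "TransitionParams",
    "StaPAWParams",
    "TrackFeatures",
    "featurize",
    "featurize_track",
    "transition_matrix",
    "transition_matrices",
    "turn_probability",
    "turn_probability_series",
    "heading_density",
    "speed_density",
    "emission_loglik",
    "emission_components",
    "posterior_turn_probability",
    "vonmises_logpdf",
    "gamma_logpdf",
    "canonicalize",
    "save_params",
    "load_params",
    "DR_FLOOR",
]

# stationary frames produce dr == 0, which has zero Gamma density; floor at
# a tenth of a micron-scale step so log densities stay finite
DR_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# temporal basis and kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaisedCosineBasis:
    """Raised-cosine temporal basis over history lags 1..n_lags.

    ``matrix`` has shape (n_lags, n_basis); column k is a smooth bump
    centered at ``centers[k]`` lags into the past.  Four bumps over 14 lags
    (~5 s of history at the 5/14 s step) are the default.
    """

    n_basis: int = 4
    n_lags: int = 14

    def __post_init__(self) -> None:
        if self.n_lags < 1 or self.n_basis < 1:
            raise ValueError("n_lags and n_basis must be >= 1")

    @property
    def centers(self) -> np.ndarray:
        if self.n_basis == 1:
            return np.array([(1 + self.n_lags) / 2.0])
        return np.linspace(1, self.n_lags, self.n_basis)

    @property
    def matrix(self) -> np.ndarray:
        lags = np.arange(1, self.n_lags + 1, dtype=float)[:, None]
        c = self.centers[None, :]
        if self.n_basis == 1:
            half = float(self.n_lags)
        else:
            half = 1.5 * (self.n_lags - 1) / (self.n_basis - 1)
        arg = np.clip(np.pi * (lags - c) / half, -np.pi, np.pi)
        return 0.5 * (1 + np.cos(arg))

    def to_dict(self) -> dict:
        return {"n_basis": self.n_basis, "n_lags": self.n_lags}


@dataclass
class Kernel:
    """A temporal filter: coefficients on a raised-cosine basis.

    ``weights`` are the realized lag weights (length n_lags, index 0 = lag
    1, the most recent past sample).
    """

    coeffs: np.ndarray
    basis: RaisedCosineBasis

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, float))
        if self.coeffs.shape != (self.basis.n_basis,):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} != (n_basis={self.basis.n_basis},)"
            )

    @property
    def weights(self) -> np.ndarray:
        return self.basis.matrix @ self.coeffs

    @classmethod
    def zeros(cls, basis: RaisedCosineBasis) -> "Kernel":
        return cls(np.zeros(basis.n_basis), basis)

    @classmethod
    def from_weights(
        cls, target: np.ndarray, basis: RaisedCosineBasis, zero_sum: bool = False
    ) -> "Kernel":
        """Least-squares projection of a target lag profile onto the basis.

        With ``zero_sum=True`` the realized weights are constrained to sum
        to zero, so a derivative-like kernel stays insensitive to the
        absolute level of its input (the unconstrained projection of a
        sharp biphasic profile onto smooth bumps leaks a net offset).
        """
        target = np.asarray(target, float)
        if len(target) != basis.n_lags:
            raise ValueError("target length must equal basis.n_lags")
        B = basis.matrix
        if not zero_sum:
            coeffs, *_ = np.linalg.lstsq(B, target, rcond=None)
            return cls(coeffs, basis)
        s = B.sum(axis=0)
        n = basis.n_basis
        kkt = np.zeros((n + 1, n + 1))
        kkt[:n, :n] = B.T @ B
        kkt[:n, n] = s
        kkt[n, :n] = s
        rhs = np.concatenate([B.T @ target, [0.0]])
        sol = np.linalg.solve(kkt, rhs)
        return cls(sol[:n], basis)

    def apply_history(self, history: np.ndarray) -> float:
        """Dot the kernel with a time-ordered history array (oldest first).

        Histories shorter than n_lags are zero-padded at the distant end.
        """
        h = np.asarray(history, float)[::-1]  # most recent first = lag order
        w = self.weights
        L = min(len(h), len(w))
        return float(w[:L] @ h[:L])


def featurize(series: np.ndarray, basis: RaisedCosineBasis) -> np.ndarray:
    """Basis-projected history features: F[t, k] = sum_l B[l, k] s[t-1-l].

    Lags extending before the start of the series are zero-padded, matching
    the convention that pre-track history equals the (standardized) dataset
    mean.
    """
    s = np.asarray(series, float)
    T = len(s)
    B = basis.matrix
    out = np.zeros((T, basis.n_basis))
    for k in range(basis.n_basis):
        conv = np.convolve(s, B[:, k])
        out[1:, k] = conv[: T - 1]
    return out


@dataclass(frozen=True)
class Standardization:
    """Dataset-level z-scoring constants for sensory inputs."""

    c_mean: float = 0.0
    c_scale: float = 1.0
    dcp_mean: float = 0.0
    dcp_scale: float = 1.0

    def c(self, C: np.ndarray | float) -> np.ndarray | float:
        return (C - self.c_mean) / self.c_scale

    def dcp(self, v: np.ndarray | float) -> np.ndarray | float:
        return (v - self.dcp_mean) / self.dcp_scale

    @classmethod
    def from_dataset(cls, dataset) -> "Standardization":
        C = np.concatenate([tr.C for tr in dataset])
        D = np.concatenate([tr.dC_perp for tr in dataset])
        return cls(
            c_mean=float(np.mean(C)),
            c_scale=float(np.std(C)) or 1.0,
            dcp_mean=float(np.mean(D)),
            dcp_scale=float(np.std(D)) or 1.0,
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class EmissionParams:
    """Per-state emission parameters (turn decision + kinematic densities)."""

    M: float  # max turn probability, in (0, 1]
    m: float  # min turn probability, in [0, 1)
    K_C: Kernel  # turning kernel on concentration history
    K_h: Kernel  # refractory kernel on |dtheta| history
    alpha: float  # uniform weight in the turn heading mixture
    kappa_turn: float  # von Mises concentration of the turn mode (mean pi)
    kappa_wv: float  # von Mises concentration while weathervaning
    K_dcp: Kernel  # steering kernel on perpendicular-concentration history
    gamma_turn: tuple[float, float]  # (shape, scale) of speed while turning
    gamma_run: tuple[float, float]  # (shape, scale) of speed while running
    K_O: Kernel | None = None  # optional optogenetic kernel in the turn decision

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.M <= 1):
            raise ValueError(f"need 0 <= m <= M <= 1, got m={self.m}, M={self.M}")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.kappa_turn <= 0 or self.kappa_wv <= 0:
            raise ValueError("von Mises concentrations must be > 0")
        for a, b in (self.gamma_turn, self.gamma_run):
            if a <= 0 or b <= 0:
                raise ValueError("Gamma shape and scale must be > 0")

    @property
    def mid_turn_probability(self) -> float:
        """Turn probability at zero filtered input (logistic midpoint)."""
        return self.m + (self.M - self.m) / 2.0


@dataclass
class TransitionParams:
    """Input-driven transition model.

    Off-diagonal logit (i -> j) is the kernel ``K[(i, j)]`` applied to the
    concentration history (plus optional optogenetic kernel ``O[(i, j)]``);
    the diagonal logit is the baseline ``b[i]``.  Rows are softmax
    normalized.
    """

    n_states: int
    baselines: np.ndarray  # (Z,)
    kernels: dict[tuple[int, int], Kernel] = field(default_factory=dict)
    O: dict[tuple[int, int], Kernel] | None = None

    def __post_init__(self) -> None:
        self.baselines = np.atleast_1d(np.asarray(self.baselines, float))
        Z = self.n_states
        if self.baselines.shape != (Z,):
            raise ValueError("baselines must have shape (n_states,)")
        for i, j in self.kernels:
            if i == j or not (0 <= i < Z and 0 <= j < Z):
                raise ValueError(f"invalid kernel pair {(i, j)}")


@dataclass
class StaPAWParams:
    """Complete staPAW parameter set.

    ``n_states == 1`` reduces the model to dPAW (no latent state dynamics).
    """

    n_states: int
    emissions: list[EmissionParams]
    transitions: TransitionParams
    dt: float = 5.0 / 14.0
    standardization: Standardization = field(default_factory=Standardization)
    basis: RaisedCosineBasis = field(default_factory=RaisedCosineBasis)

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if len(self.emissions) != self.n_states:
            raise ValueError("one EmissionParams per state required")
        if self.transitions.n_states != self.n_states:
            raise ValueError("transition/emission state count mismatch")

    @property
    def has_opto(self) -> bool:
        return any(e.K_O is not None for e in self.emissions) or (
            self.transitions.O is not None
        )


# ---------------------------------------------------------------------------
# featurized view of a track
# ---------------------------------------------------------------------------


@dataclass
class TrackFeatures:
    """Basis-projected, standardized history features for one track."""

    Cf: np.ndarray  # (T, n_basis) standardized concentration history
    Hf: np.ndarray  # (T, n_basis) |dtheta| history
    Df: np.ndarray  # (T, n_basis) standardized perpendicular-difference history
    If: np.ndarray | None  # (T, n_basis) optogenetic history


def featurize_track(track: Track, params: StaPAWParams) -> TrackFeatures:
    if track.C is None or track.dC_perp is None:
        raise ValueError(f"track {track.track_id}: sensory series missing")
    st = params.standardization
    basis = params.basis
    Cf = featurize(st.c(track.C), basis)
    Hf = featurize(np.abs(track.dtheta), basis)
    Df = featurize(st.dcp(track.dC_perp), basis)
    If = featurize(track.I, basis) if track.I is not None else None
    return TrackFeatures(Cf=Cf, Hf=Hf, Df=Df, If=If)


# ---------------------------------------------------------------------------
# elementary densities
# ---------------------------------------------------------------------------


def vonmises_logpdf(x: np.ndarray | float, mu: np.ndarray | float, kappa: float):
    """log von Mises density on the circle, numerically stable in kappa."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return kappa * (np.cos(np.asarray(x) - mu) - 1.0) - np.log(2 * np.pi * i0e(kappa))


def gamma_logpdf(x: np.ndarray | float, shape: float, scale: float):
    x = np.maximum(np.asarray(x, float), DR_FLOOR)
    return (shape - 1) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)


def mean_resultant(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), the von Mises mean resultant length."""
    return float(i1e(kappa) / i0e(kappa))


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


def _transition_logits(
    trans: TransitionParams,
    Cf: np.ndarray,
    If: np.ndarray | None,
) -> np.ndarray:
    """Per-step transition logits, shape (T, Z, Z)."""
    T = Cf.shape[0]
    Z = trans.n_states
    logits = np.zeros((T, Z, Z))
    for i in range(Z):
        logits[:, i, i] = trans.baselines[i]
    for (i, j), kern in trans.kernels.items():
        logits[:, i, j] += Cf @ kern.coeffs
    if trans.O is not None and If is not None:
        for (i, j), kern in trans.O.items():
            logits[:, i, j] += If @ kern.coeffs
    return logits


def transition_matrices(params: StaPAWParams, feats: TrackFeatures) -> np.ndarray:
    """Row-stochastic transition matrices for every step, shape (T, Z, Z).

    ``out[t]`` governs the transition from step t-1 into step t.
    """
    logits = _transition_logits(params.transitions, feats.Cf, feats.If)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError(
            "non-finite transition logits; are sensory inputs standardized?"
        )
    logits -= logits.max(axis=2, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=2, keepdims=True)
    return P


def transition_matrix(
    params: StaPAWParams,
    C_history: np.ndarray,
    I_history: np.ndarray | None = None,
) -> np.ndarray:
    """Single-step transition matrix from raw time-ordered histories.

    ``C_history`` is the recent concentration series (oldest first); it is
    standardized internally and zero-padded if shorter than the kernel.
    """
    trans = params.transitions
    Z = trans.n_states
    ch = np.asarray(params.standardization.c(np.asarray(C_history, float)))
    logits = np.zeros((Z, Z))
    for i in range(Z):
        logits[i, i] = trans.baselines[i]
    for (i, j), kern in trans.kernels.items():
        logits[i, j] += kern.apply_history(ch)
    if trans.O is not None and I_history is not None:
        for (i, j), kern in trans.O.items():
            logits[i, j] += kern.apply_history(np.asarray(I_history, float))
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite transition logits")
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# turn decision
# ---------------------------------------------------------------------------


def _turn_prob_from_drive(em: EmissionParams, drive: np.ndarray) -> np.ndarray:
    # range-limited logistic: p in [m, M]; large positive drive suppresses turns
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(drive))
    return em.m + (em.M - em.m) * s


def turn_probability_series(em: EmissionParams, feats: TrackFeatures) -> np.ndarray:
    drive = feats.Cf @ em.K_C.coeffs + feats.Hf @ em.K_h.coeffs
    if em.K_O is not None and feats.If is not None:
        drive = drive + feats.If @ em.K_O.coeffs
    return _turn_prob_from_drive(em, drive)


def turn_probability(
    em: EmissionParams,
    C_history: np.ndarray,
    dtheta_history: np.ndarray,
    I_history: np.ndarray | None = None,
    standardization: Standardization | None = None,
) -> float:
    """Single-step turn probability from raw time-ordered histories."""
    st = standardization or Standardization()
    drive = em.K_C.apply_history(np.asarray(st.c(np.asarray(C_history, float))))
    drive += em.K_h.apply_history(np.abs(np.asarray(dtheta_history, float)))
    if em.K_O is not None and I_history is not None:
        drive += em.K_O.apply_history(np.asarray(I_history, float))
    return float(_turn_prob_from_drive(em, np.asarray(drive)))


# ---------------------------------------------------------------------------
# kinematic emissions
# ---------------------------------------------------------------------------


def _log_ptr_heading(em: EmissionParams, dtheta: np.ndarray) -> np.ndarray:
    """Turn heading density: alpha-weighted uniform + von Mises at pi."""
    vm = np.exp(vonmises_logpdf(dtheta, np.pi, em.kappa_turn))
    dens = em.alpha / (2 * np.pi) + (1 - em.alpha) * vm
    with np.errstate(divide="ignore"):  # alpha=0 with far-off-mode dtheta
        return np.log(dens)


def _log_pwv_heading(
    em: EmissionParams, dtheta: np.ndarray, mu: np.ndarray
) -> np.ndarray:
    """Weathervane heading density: von Mises steered by dC_perp history."""
    return vonmises_logpdf(dtheta, mu, em.kappa_wv)


def heading_density(
    em: EmissionParams,
    dtheta: float,
    q: int,
    dcp_history: np.ndarray | None = None,
    standardization: Standardization | None = None,
) -> float:
    """Heading-change density for one step under turn (q=1) or weathervane (q=0)."""
    dtheta = float(wrap_angle(dtheta))
    if q == 1:
        return float(np.exp(_log_ptr_heading(em, np.asarray(dtheta))))
    st = standardization or Standardization()
    hist = np.asarray(st.dcp(np.asarray(dcp_history, float))) if dcp_history is not None else np.zeros(1)
    mu = -em.K_dcp.apply_history(hist)
    return float(np.exp(_log_pwv_heading(em, np.asarray(dtheta), mu)))


def speed_density(em: EmissionParams, dr: float, q: int) -> float:
    a, b = em.gamma_turn if q == 1 else em.gamma_run
    return float(np.exp(gamma_logpdf(dr, a, b)))


def emission_components(
    params: StaPAWParams, track: Track, feats: TrackFeatures | None = None
) -> np.ndarray:
    """Log joint of (kinematics, q) per step and state: shape (T, Z, 2).

    ``out[t, z, q]`` = log P(q | z) + log P(dtheta_t | q, z) + log P(dr_t | q, z).
    Summing (logsumexp) over the last axis gives the emission log-likelihood.
    """
    if feats is None:
        feats = featurize_track(track, params)
    T = len(track)
    Z = params.n_states
    out = np.empty((T, Z, 2))
    dtheta = track.dtheta
    dr = track.dr
    for z, em in enumerate(params.emissions):
        p = turn_probability_series(em, feats)
        mu = -(feats.Df @ em.K_dcp.coeffs)
        lp_turn = _log_ptr_heading(em, dtheta) + gamma_logpdf(dr, *em.gamma_turn)
        lp_wv = _log_pwv_heading(em, dtheta, mu) + gamma_logpdf(dr, *em.gamma_run)
        with np.errstate(divide="ignore"):
            out[:, z, 1] = np.log(p) + lp_turn
            out[:, z, 0] = np.log1p(-p) + lp_wv
    return out


def emission_loglik(
    params: StaPAWParams, track: Track, feats: TrackFeatures | None = None
) -> np.ndarray:
    """Per-step, per-state emission log-likelihood matrix, shape (T, Z)."""
    comp = emission_components(params, track, feats)
    ll = _logsumexp2(comp)
    if not np.all(np.isfinite(ll)):
        t, z = np.argwhere(~np.isfinite(ll))[0]
        raise FloatingPointError(f"non-finite emission loglik at (t={t}, z={z})")
    return ll


def _logsumexp2(comp: np.ndarray) -> np.ndarray:
    m = comp.max(axis=-1)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.sum(np.exp(comp - m[..., None]), axis=-1))
    return np.where(np.isfinite(m), out, m)


def posterior_turn_probability(
    params: StaPAWParams,
    track: Track,
    gamma: np.ndarray,
    feats: TrackFeatures | None = None,
) -> np.ndarray:
    """P(q_t = 1 | data): state-marginal-weighted turn responsibility."""
    comp = emission_components(params, track, feats)
    ll = _logsumexp2(comp)  # (T, Z)
    r1 = np.exp(comp[:, :, 1] - ll)  # P(q=1 | z, data_t)
    return np.sum(gamma * r1, axis=1)


# ---------------------------------------------------------------------------
# state labeling and serialization
# ---------------------------------------------------------------------------


def canonicalize(params: StaPAWParams) -> tuple[StaPAWParams, np.ndarray]:
    """Order states by baseline turn probability: S-like first, T-like last.

    Resolves HMM label switching deterministically.  Returns the permuted
    parameters and the permutation applied (new index -> old index).
    """
    order = np.argsort([em.mid_turn_probability for em in params.emissions],
                       kind="stable")
    if np.all(order == np.arange(params.n_states)):
        return params, order
    inv = {int(old): new for new, old in enumerate(order)}
    trans = params.transitions
    new_trans = TransitionParams(
        n_states=params.n_states,
        baselines=trans.baselines[order],
        kernels={(inv[i], inv[j]): k for (i, j), k in trans.kernels.items()},
        O=None if trans.O is None else {(inv[i], inv[j]): k for (i, j), k in trans.O.items()},
    )
    return replace(
        params,
        emissions=[params.emissions[i] for i in order],
        transitions=new_trans,
    ), order


def _kernel_to_dict(k: Kernel | None) -> list | None:
    return None if k is None else list(map(float, k.coeffs))


def save_params(params: StaPAWParams, path: str | Path) -> None:
    """Serialize parameters to a versioned JSON document."""
    doc = params_to_dict(params)
    Path(path).write_text(json.dumps(doc, indent=1))


def params_to_dict(params: StaPAWParams) -> dict:
    st = params.standardization
    trans = params.transitions
    return {
        "schema": "stapaw-params-v1",
        "n_states": params.n_states,
        "dt": params.dt,
        "basis": params.basis.to_dict(),
        "standardization": {
            "c_mean": st.c_mean, "c_scale": st.c_scale,
            "dcp_mean": st.dcp_mean, "dcp_scale": st.dcp_scale,
        },
        "transitions": {
            "baselines": list(map(float, trans.baselines)),
            "kernels": {f"{i}->{j}": _kernel_to_dict(k) for (i, j), k in trans.kernels.items()},
            "O": None if trans.O is None else {
                f"{i}->{j}": _kernel_to_dict(k) for (i, j), k in trans.O.items()
            },
        },
        "emissions": [
            {
                "M": em.M, "m": em.m, "alpha": em.alpha,
                "kappa_turn": em.kappa_turn, "kappa_wv": em.kappa_wv,
                "gamma_turn": list(em.gamma_turn), "gamma_run": list(em.gamma_run),
                "K_C": _kernel_to_dict(em.K_C), "K_h": _kernel_to_dict(em.K_h),
                "K_dcp": _kernel_to_dict(em.K_dcp), "K_O": _kernel_to_dict(em.K_O),
            }
            for em in params.emissions
        ],
    }


def load_params(path: str | Path) -> StaPAWParams:
    return params_from_dict(json.loads(Path(path).read_text()))


def params_from_dict(doc: dict) -> StaPAWParams:
    if doc.get("schema") != "stapaw-params-v1":
        raise ValueError("unrecognized parameter schema")
    basis = RaisedCosineBasis(**doc["basis"])

    def kern(c):
        return None if c is None else Kernel(np.asarray(c, float), basis)

    def pair_dict(d):
        if d is None:
            return None
        out = {}
        for key, c in d.items():
            i, j = key.split("->")
            out[(int(i), int(j))] = kern(c)
        return out

    emissions = [
        EmissionParams(
            M=e["M"], m=e["m"], alpha=e["alpha"],
            kappa_turn=e["kappa_turn"], kappa_wv=e["kappa_wv"],
            gamma_turn=tuple(e["gamma_turn"]), gamma_run=tuple(e["gamma_run"]),
            K_C=kern(e["K_C"]), K_h=kern(e["K_h"]), K_dcp=kern(e["K_dcp"]),
            K_O=kern(e["K_O"]),
        )
        for e in doc["emissions"]
    ]
    trans = TransitionParams(
        n_states=doc["n_states"],
        baselines=np.asarray(doc["transitions"]["baselines"], float),
        kernels=pair_dict(doc["transitions"]["kernels"]) or {},
        O=pair_dict(doc["transitions"]["O"]),
    )
    return StaPAWParams(
        n_states=doc["n_states"],
        emissions=emissions,
        transitions=trans,
        dt=doc["dt"],
        standardization=Standardization(**doc["standardization"]),
        basis=basis,
    )
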