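"""Descriptive statistics of chemotaxis behavior.

Turn detection (threshold crossing of |dtheta|, default 50 degrees),
inter-turn-interval distributions and their single/double exponential fits,
speed autocorrelation, the classical bout-merging pirouette heuristic,
bearing distributions at state entry/exit with the aligned-fraction
statistic, a shuffled-turn-angle control, and the chemotaxis index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .environment import Environment
from .preprocessing import Track, bearing_deg, wrap_angle

__all__ = [
    "TurnEvents",
    "ExpFit",
    "BearingStats",
    "detect_turns",
    "inter_turn_intervals",
    "fit_exponentials",
    "speed_autocorrelation",
    "identify_pirouettes_classical",
    "bearing_at_transitions",
    "shuffled_exit_control",
    "chemotaxis_index",
]

TURN_THRESHOLD_DEG = 50.0


@dataclass
class TurnEvents:
    """Turn onset indices for one track."""

    indices: np.ndarray
    threshold_deg: float = TURN_THRESHOLD_DEG

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ExpFit:
    """Single or double exponential fit of a decaying curve or density."""

    model: str  # "single" | "double"
    rates: tuple[float, ...]  # 1/s, fast first for double
    weights: tuple[float, ...]
    r2: float
    t_c: float | None = None  # crossing time of the two components (double)


@dataclass
class BearingStats:
    """Bearings (deg) at transition events and the aligned fraction."""

    bearings: np.ndarray
    aligned_fraction: float
    resampled_fractions: np.ndarray

    @property
    def n(self) -> int:
        return len(self.bearings)


# ---------------------------------------------------------------------------
# turns and intervals
# ---------------------------------------------------------------------------


def detect_turns(track: Track, threshold_deg: float = TURN_THRESHOLD_DEG) -> TurnEvents:
    """Turn onsets: steps where |dtheta| first crosses above the threshold.

    Consecutive supra-threshold steps produce a single event at the first.
    """
    if threshold_deg <= 0:
        raise ValueError("threshold must be > 0")
    supra = np.abs(track.dtheta) > np.radians(threshold_deg)
    onset = supra & ~np.concatenate([[False], supra[:-1]])
    return TurnEvents(indices=np.flatnonzero(onset), threshold_deg=threshold_deg)


def inter_turn_intervals(
    events: TurnEvents | list[TurnEvents], dt: float
) -> np.ndarray:
    """Successive turn-onset differences in seconds, pooled across tracks.

    Intervals never span track boundaries; tracks with fewer than two
    events contribute nothing.
    """
    if isinstance(events, TurnEvents):
        events = [events]
    out = [np.diff(ev.indices) * dt for ev in events if len(ev) >= 2]
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_exponentials(
    samples: np.ndarray, model: str = "double", n_bins: int = 32
) -> ExpFit:
    """Exponential fit of an interval distribution.

    The samples are binned into log-spaced bins, normalized to a density,
    and the model is fit by nonlinear least squares on the log-density
    (which weights both timescales evenly); R^2 is reported on the same
    log-density.  The double fit returns the crossing time ``t_c`` of its
    two components, the classical pirouette-merging threshold.
    """
    samples = np.asarray(samples, float)
    samples = samples[samples > 0]
    if len(samples) < 50:
        raise ValueError("need >= 50 positive samples")
    if model not in ("single", "double"):
        raise ValueError("model must be 'single' or 'double'")
    lo, hi = samples.min(), samples.max()
    edges = np.geomspace(lo * 0.999, hi * 1.001, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges, density=True)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = hist > 0
    t, y = centers[keep], np.log(hist[keep])
    if keep.sum() < (3 if model == "single" else 5):
        raise RuntimeError("too few occupied bins for an exponential fit")

    mean = samples.mean()

    if model == "single":
        def resid(th):
            lam = np.exp(th[0])
            return np.log(lam) - lam * t - y

        best = None
        for lam0 in (1 / mean, 2 / mean, 0.5 / mean):
            try:
                res = least_squares(resid, [np.log(lam0)])
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("single-exponential fit failed")
        lam = float(np.exp(best.x[0]))
        yhat = np.log(lam) - lam * t
        return ExpFit("single", (lam,), (1.0,), _r2(y, yhat))

    def model_log(th):
        l1, l2 = np.exp(th[0]), np.exp(th[1])
        w = 1 / (1 + np.exp(-th[2]))
        f = w * l1 * np.exp(-l1 * t) + (1 - w) * l2 * np.exp(-l2 * t)
        return np.log(np.clip(f, 1e-300, None))

    best = None
    for f1, f2 in ((4.0, 0.25), (10.0, 0.5), (2.0, 0.1), (1.0, 1.0)):
        th0 = [np.log(f1 / mean), np.log(f2 / mean), 0.0]
        try:
            res = least_squares(lambda th: model_log(th) - y, th0)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("double-exponential fit failed")
    l1, l2 = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    w = float(1 / (1 + np.exp(-best.x[2])))
    if l1 < l2:  # fast component first
        l1, l2, w = l2, l1, 1 - w
    yhat = model_log(best.x)
    r2 = _r2(y, yhat)
    t_c = None
    if abs(l1 - l2) > 1e-12 and 0 < w < 1:
        t_c = float(np.log(w * l1 / ((1 - w) * l2)) / (l1 - l2))
    return ExpFit("double", (l1, l2), (w, 1 - w), r2, t_c)


def speed_autocorrelation(
    tracks: list[Track], max_lag: int = 60
) -> tuple[np.ndarray, np.ndarray, dict[str, ExpFit]]:
    """Mean-removed normalized speed autocorrelation, averaged over tracks.

    Returns (lag times in s, autocorrelation, exponential fits).  The fits
    are plain least squares of ``A exp(-lam t)`` (single) and a two-term
    sum (double) on the linear autocorrelation values.
    """
    acfs = []
    for tr in tracks:
        v = tr.dr - tr.dr.mean()
        var = float(v @ v) / len(v)
        if var <= 0 or len(v) <= max_lag:
            continue
        ac = np.array([
            float(v[: len(v) - k] @ v[k:]) / ((len(v) - k) * var)
            for k in range(max_lag + 1)
        ])
        acfs.append(ac)
    if not acfs:
        raise ValueError("no track long enough for the requested max_lag")
    acf = np.mean(acfs, axis=0)
    dt = tracks[0].dt
    lags = np.arange(max_lag + 1) * dt

    def fit(model: str) -> ExpFit:
        if model == "single":
            def resid(th):
                return th[0] * np.exp(-np.exp(th[1]) * lags) - acf
            res = least_squares(resid, [1.0, np.log(1.0)])
            A, lam = float(res.x[0]), float(np.exp(res.x[1]))
            return ExpFit("single", (lam,), (A,), _r2(acf, resid(res.x) + acf))
        def resid(th):
            return (th[0] * np.exp(-np.exp(th[2]) * lags)
                    + th[1] * np.exp(-np.exp(th[3]) * lags) - acf)
        best = None
        for f1, f2 in ((3.0, 0.3), (10.0, 1.0), (1.0, 0.1)):
            res = least_squares(resid, [0.5, 0.5, np.log(f1), np.log(f2)])
            if best is None or res.cost < best.cost:
                best = res
        l1, l2 = float(np.exp(best.x[2])), float(np.exp(best.x[3]))
        A1, A2 = float(best.x[0]), float(best.x[1])
        if l1 < l2:
            l1, l2, A1, A2 = l2, l1, A2, A1
        return ExpFit("double", (l1, l2), (A1, A2),
                      _r2(acf, resid(best.x) + acf))

    return lags, acf, {"single": fit("single"), "double": fit("double")}


# ---------------------------------------------------------------------------
# classical pirouette identification
# ---------------------------------------------------------------------------


def identify_pirouettes_classical(
    events: TurnEvents, t_c: float, dt: float, n_steps: int
) -> np.ndarray:
    """Boolean per-step pirouette mask by the classical merging heuristic.

    Turns closer than ``t_c`` seconds are merged into one bout spanning
    first to last turn; isolated turns are single-step bouts.
    """
    if t_c <= 0:
        raise ValueError("t_c must be > 0")
    mask = np.zeros(n_steps, bool)
    idx = np.asarray(events.indices, int)
    if len(idx) == 0:
        return mask
    gap_steps = t_c / dt
    start = prev = idx[0]
    for e in idx[1:]:
        if e - prev < gap_steps:
            prev = e
        else:
            mask[start:prev + 1] = True
            start = prev = e
    mask[start:prev + 1] = True
    return mask


# ---------------------------------------------------------------------------
# bearing analyses
# ---------------------------------------------------------------------------


def _transition_bearings(
    tracks: list[Track],
    states: list[np.ndarray],
    env: Environment,
    mode: str,
    t_state: int,
) -> np.ndarray:
    out = []
    for tr, z in zip(tracks, states):
        z = np.asarray(z)
        if len(z) != len(tr):
            raise ValueError("state series length mismatch")
        change = np.flatnonzero(z[1:] != z[:-1]) + 1
        if mode == "exit":
            steps = change[z[change - 1] == t_state]
        elif mode == "enter":
            steps = change[z[change] == t_state]
        else:
            raise ValueError("mode must be 'enter' or 'exit'")
        if len(steps) == 0:
            continue
        grads = env.gradient(tr.position[steps])
        out.append(bearing_deg(tr.heading[steps], grads))
    if not out:
        raise ValueError("no transition events found")
    b = np.concatenate(out)
    return b[np.isfinite(b)]


def _event_bearings(
    tracks: list[Track], events: list[TurnEvents], env: Environment
) -> np.ndarray:
    out = []
    for tr, ev in zip(tracks, events):
        idx = np.asarray(ev.indices, int)
        if len(idx) == 0:
            continue
        grads = env.gradient(tr.position[idx])
        out.append(bearing_deg(tr.heading[idx], grads))
    if not out:
        raise ValueError("no turn events found")
    b = np.concatenate(out)
    return b[np.isfinite(b)]


def bearing_at_transitions(
    tracks: list[Track],
    states: list[np.ndarray] | list[TurnEvents],
    env: Environment,
    mode: str = "exit",
    unit: str = "state-bout",
    t_state: int = 1,
    n_resamples: int = 50,
    resample_size: int = 2000,
    seed: int = 0,
) -> BearingStats:
    """Bearing distribution at state-bout or single-turn entry/exit.

    For ``unit='state-bout'``, ``states`` are per-track state series (true,
    decoded, or a pirouette mask cast to int) and the event instant is the
    step on which the state changes (exit: out of ``t_state``; enter: into
    it).  For ``unit='single-turn'``, ``states`` are per-track
    :class:`TurnEvents`, and the bearing is taken at the post-turn heading.

    ``aligned_fraction`` is P(bearing < 90 deg); its spread is estimated by
    ``n_resamples`` bootstrap draws of ``resample_size`` events.
    """
    if unit == "state-bout":
        b = _transition_bearings(tracks, states, env, mode, t_state)
    elif unit == "single-turn":
        b = _event_bearings(tracks, states, env)
    else:
        raise ValueError("unit must be 'state-bout' or 'single-turn'")
    aligned = b < 90.0
    rng = np.random.default_rng(seed)
    res = np.array([
        aligned[rng.integers(0, len(b), resample_size)].mean()
        for _ in range(n_resamples)
    ])
    return BearingStats(
        bearings=b,
        aligned_fraction=float(aligned.mean()),
        resampled_fractions=res,
    )


def shuffled_exit_control(
    tracks: list[Track],
    events: list[TurnEvents],
    env: Environment,
    seed: int = 0,
) -> np.ndarray:
    """Exit bearings after permuting turn angles across turn events.

    The heading change at every detected turn is replaced by one drawn
    (without replacement) from the pool of all turn angles; headings are
    replayed with the swapped values and the bearing is re-measured at the
    original event positions.  Breaking the pairing between a turn's
    magnitude and its sensory context destroys systematically directed
    exits.
    """
    rng = np.random.default_rng(seed)
    pool = np.concatenate([
        tr.dtheta[np.asarray(ev.indices, int)]
        for tr, ev in zip(tracks, events) if len(ev)
    ])
    if pool.size == 0:
        raise ValueError("no turn events to shuffle")
    perm = pool[rng.permutation(len(pool))]
    out = []
    k = 0
    for tr, ev in zip(tracks, events):
        idx = np.asarray(ev.indices, int)
        if len(idx) == 0:
            continue
        d = tr.dtheta.copy()
        d[idx] = perm[k:k + len(idx)]
        k += len(idx)
        h0 = tr.heading[0] - tr.dtheta[0]
        heading = wrap_angle(h0 + np.cumsum(d))
        grads = env.gradient(tr.position[idx])
        out.append(bearing_deg(heading[idx], grads))
    b = np.concatenate(out)
    return b[np.isfinite(b)]


# ---------------------------------------------------------------------------
# chemotaxis index
# ---------------------------------------------------------------------------


def chemotaxis_index(
    tracks: list[Track] | np.ndarray,
    source: tuple[float, float],
    radius: float,
) -> float:
    """Fraction of tracks whose final position lies within ``radius`` of
    the source."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if isinstance(tracks, np.ndarray):
        finals = np.atleast_2d(tracks)
    else:
        finals = np.stack([tr.position[-1] for tr in tracks])
    d = np.linalg.norm(finals - np.asarray(source, float), axis=1)
    return float(np.mean(d <= radius))
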