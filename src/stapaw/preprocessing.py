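"""Trajectory IO, preprocessing, and sensory feature extraction.

Raw input is a long-format table of centroid positions (``track_id, t, x, y``
and optionally an optogenetic stimulus column ``I``) sampled at 14 Hz.
Preprocessing smooths the centroid with a centered moving average,
downsamples to one point every 5/14 s, and differentiates to per-step
heading change ``dtheta`` (radians, counter-clockwise positive, wrapped to
(-pi, pi]) and step displacement ``dr`` (cm).  Tracks that cover less than
1 cm^2 of arena or last under 3 minutes are discarded.

Sensory features are reconstructed from a concentration landscape:
``C`` is the concentration experienced at the centroid, and ``dC_perp`` is
the concentration difference between two virtual sensors offset
perpendicular to the heading (left minus right), the steering signal for
weathervaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import Environment

logger = logging.getLogger("stapaw")

__all__ = [
    "RawTrajectory",
    "Track",
    "Dataset",
    "SchemaError",
    "DataError",
    "read_tracks",
    "preprocess",
    "filter_tracks",
    "extract_sensory",
    "wrap_angle",
    "bearing_deg",
]

DEFAULT_FRAME_RATE = 14.0
DEFAULT_DOWNSAMPLE = 5
DEFAULT_SMOOTH_WINDOW = 5


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class DataError(ValueError):
    """Input data violate a structural precondition (named track)."""


def wrap_angle(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return -((np.pi - np.asarray(x)) % (2 * np.pi) - np.pi)


@dataclass
class RawTrajectory:
    """One animal's raw centroid time series."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    I: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.t.size < 2:
            raise DataError(f"track {self.track_id}: needs >= 2 samples")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise DataError(f"track {self.track_id}: ragged series")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"track {self.track_id}: time not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError(f"track {self.track_id}: non-finite positions")


@dataclass
class Track:
    """Preprocessed kinematic and sensory series on a common step grid.

    All per-step series have equal length T.  ``position[t]`` is the pose at
    the start of step t; ``heading[t]`` the heading of the displacement taken
    during step t; ``dtheta[t]`` the wrapped change from the previous
    heading; ``dr[t]`` the step displacement (cm, >= 0).
    """

    track_id: str
    dt: float
    dtheta: np.ndarray
    dr: np.ndarray
    position: np.ndarray  # (T, 2)
    heading: np.ndarray
    C: np.ndarray | None = None
    dC_perp: np.ndarray | None = None
    I: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = len(self.dtheta)
        for name in ("dr", "heading"):
            if len(getattr(self, name)) != T:
                raise DataError(f"track {self.track_id}: {name} length mismatch")
        if self.position.shape != (T, 2):
            raise DataError(f"track {self.track_id}: position shape mismatch")
        for name in ("C", "dC_perp", "I"):
            v = getattr(self, name)
            if v is not None and len(v) != T:
                raise DataError(f"track {self.track_id}: {name} length mismatch")
        if self.dt <= 0:
            raise DataError("dt must be > 0")
        if np.any(self.dr < 0):
            raise DataError("dr must be >= 0")

    def __len__(self) -> int:
        return len(self.dtheta)

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    @property
    def area(self) -> float:
        """Bounding-box area covered by the track (cm^2)."""
        return float(np.ptp(self.position[:, 0]) * np.ptp(self.position[:, 1]))


@dataclass
class Dataset:
    """A collection of tracks sharing a common step duration."""

    tracks: list[Track]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tracks:
            raise DataError("dataset has no tracks")
        dts = {round(tr.dt, 12) for tr in self.tracks}
        if len(dts) > 1:
            raise DataError(f"tracks disagree on dt: {sorted(dts)}")

    @property
    def dt(self) -> float:
        return self.tracks[0].dt

    @property
    def n_steps(self) -> int:
        return int(sum(len(tr) for tr in self.tracks))

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def read_tracks(
    path: str | Path,
    schema: dict[str, str] | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> list[RawTrajectory]:
    """Read a long-format CSV of centroid trajectories.

    ``schema`` maps the logical names ``track_id, t, x, y`` (and optionally
    ``I``) to column names; defaults to identical names.  Returns one
    :class:`RawTrajectory` per track id, each sorted by time.
    """
    schema = dict(schema or {})
    colmap = {k: schema.get(k, k) for k in ("track_id", "t", "x", "y")}
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path}")
    icol = schema.get("I", "I")
    has_I = icol in df.columns
    out = []
    for tid, g in df.groupby(colmap["track_id"], sort=True):
        g = g.sort_values(colmap["t"])
        t = g[colmap["t"]].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"track {tid}: duplicate or non-monotone timestamps")
        out.append(
            RawTrajectory(
                track_id=str(tid),
                t=t,
                x=g[colmap["x"]].to_numpy(float),
                y=g[colmap["y"]].to_numpy(float),
                frame_rate=frame_rate,
                I=g[icol].to_numpy(float) if has_I else None,
            )
        )
    return out


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window clipped at ends)."""
    if window <= 1:
        return v.astype(float)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v, dtype=float), kernel, mode="same")
    return num / den


def preprocess(
    raw: RawTrajectory,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    downsample: int = DEFAULT_DOWNSAMPLE,
) -> Track:
    """Smooth, downsample and differentiate a raw centroid trajectory.

    With 14 Hz input and the default ``downsample=5`` the output step
    duration is 5/14 s.  The first two downsampled points carry no defined
    heading change and are consumed by the differentiation, so the output
    has ``n_kept - 2`` steps.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    n = len(raw.t)
    if n <= downsample * 2 + 1:
        raise DataError(f"track {raw.track_id}: too short to preprocess")
    if n < smooth_window:
        raise DataError(f"track {raw.track_id}: shorter than smoothing window")
    xs = _smooth(raw.x, smooth_window)[::downsample]
    ys = _smooth(raw.y, smooth_window)[::downsample]
    dt = downsample / raw.frame_rate
    p = np.stack([xs, ys], axis=1)
    disp = np.diff(p, axis=0)  # (n-1, 2)
    heading = np.arctan2(disp[:, 1], disp[:, 0])  # heading of step k -> k+1
    dtheta = wrap_angle(np.diff(heading))  # defined for steps 1..n-2
    dr = np.linalg.norm(disp, axis=1)[1:]
    I = None
    if raw.I is not None:
        I = np.asarray(raw.I, float)[::downsample][1:-1]
    return Track(
        track_id=raw.track_id,
        dt=dt,
        dtheta=dtheta,
        dr=dr,
        position=p[1:-1],
        heading=heading[1:],
        I=I,
    )


def filter_tracks(
    tracks: list[Track],
    min_area: float = 1.0,
    min_duration: float = 180.0,
    metadata: dict | None = None,
) -> Dataset:
    """Drop tracks covering < ``min_area`` cm^2 or lasting < ``min_duration`` s."""
    kept, dropped = [], 0
    for tr in tracks:
        if tr.area < min_area or tr.duration < min_duration:
            dropped += 1
        else:
            kept.append(tr)
    logger.info("filter_tracks: kept %d, removed %d", len(kept), dropped)
    if not kept:
        raise DataError("all tracks removed by filters")
    return Dataset(tracks=kept, metadata=dict(metadata or {}))


def extract_sensory(
    track: Track, env: Environment, sensor_offset: float = 0.05
) -> Track:
    """Attach concentration features from a landscape to a track.

    ``C`` is sampled at the centroid; ``dC_perp`` is the field at a point
    ``sensor_offset`` cm to the *left* of the heading minus the point to the
    right (positive when concentration is higher on the animal's left).
    """
    p = track.position
    h = track.heading
    normal = np.stack([-np.sin(h), np.cos(h)], axis=1)  # left of heading
    C = env.concentration(p)
    left = env.concentration(p + sensor_offset * normal)
    right = env.concentration(p - sensor_offset * normal)
    return replace(track, C=np.asarray(C), dC_perp=np.asarray(left - right))


def bearing_deg(heading: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Bearing between heading(s) and gradient vector(s), in degrees [0, 180].

    0 deg means directly upgradient.  Where the gradient vanishes the
    bearing is undefined and NaN is returned.
    """
    heading = np.atleast_1d(np.asarray(heading, float))
    grad = np.atleast_2d(np.asarray(grad, float))
    norm = np.linalg.norm(grad, axis=-1)
    u = np.stack([np.cos(heading), np.sin(heading)], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosb = np.sum(u * grad, axis=-1) / norm
    b = np.degrees(np.arccos(np.clip(cosb, -1.0, 1.0)))
    return np.where(norm > 0, b, np.nan)
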