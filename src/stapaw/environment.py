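"""Concentration landscapes for chemotaxis assays and simulations.

Three field types are supported:

* ``linear`` — a planar gradient ``c(x) = c0 + g . (x - x0)``, emulating the
  linear salt gradients poured across a 9 cm square arena (e.g. 0-50 mM).
* ``gaussian`` — a radially symmetric odor source
  ``c(x) = A exp(-|x - x*|^2 / (2 sigma^2))``.
* ``grid`` — a sampled concentration array with bilinear interpolation,
  for landscapes calibrated empirically.

All fields expose ``concentration`` and ``gradient`` queries and carry
rectangular domain bounds; queries outside the domain raise ``DomainError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DomainError",
    "Environment",
    "LinearEnvironment",
    "GaussianEnvironment",
    "GridEnvironment",
    "from_config",
    "widen",
]


class DomainError(ValueError):
    """Raised when a position falls outside an environment's domain."""


@dataclass(frozen=True)
class Environment:
    """Base class: a queryable scalar concentration field on a 2-D domain.

    ``bounds`` is ``(xmin, xmax, ymin, ymax)`` in cm.
    """

    bounds: tuple[float, float, float, float] = (-4.5, 4.5, -4.5, 4.5)

    kind = "abstract"

    # -- domain handling -------------------------------------------------
    def contains(self, position: np.ndarray) -> np.ndarray:
        p = np.asarray(position, dtype=float)
        x, y = p[..., 0], p[..., 1]
        xmin, xmax, ymin, ymax = self.bounds
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def _check(self, position: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(position, dtype=float))
        if not np.all(self.contains(p)):
            bad = p[~self.contains(p)][0]
            raise DomainError(
                f"position {tuple(bad)} outside domain bounds {self.bounds}"
            )
        return p

    # -- queries ----------------------------------------------------------
    def concentration(self, position: np.ndarray) -> np.ndarray:
        """Concentration at ``position`` (shape (2,) or (n, 2))."""
        p = self._check(position)
        c = self._concentration(p)
        return c[0] if np.asarray(position).ndim == 1 else c

    def gradient(self, position: np.ndarray) -> np.ndarray:
        """Spatial gradient dC/dx at ``position``; same batching as above."""
        p = self._check(position)
        g = self._gradient(p)
        return g[0] if np.asarray(position).ndim == 1 else g

    def _concentration(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _gradient(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class LinearEnvironment(Environment):
    """Planar gradient ``c = c0 + slope . (x - origin)``.

    Defaults reproduce a 0-50 mM salt gradient across a 9 cm arena
    centered on the origin (25 mM at center, rising along +x).
    """

    c0: float = 25.0
    slope: tuple[float, float] = (50.0 / 9.0, 0.0)
    origin: tuple[float, float] = (0.0, 0.0)

    kind = "linear"

    def _concentration(self, p: np.ndarray) -> np.ndarray:
        d = p - np.asarray(self.origin)
        return self.c0 + d @ np.asarray(self.slope)

    def _gradient(self, p: np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.slope, float), p.shape).copy()


@dataclass(frozen=True)
class GaussianEnvironment(Environment):
    """Radial odor source ``c = A exp(-|x - center|^2 / (2 sigma^2))``."""

    amplitude: float = 50.0
    sigma: float = 1.5
    center: tuple[float, float] = (0.0, 0.0)

    kind = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("gaussian sigma must be > 0")

    def _concentration(self, p: np.ndarray) -> np.ndarray:
        d = p - np.asarray(self.center)
        return self.amplitude * np.exp(-np.sum(d**2, axis=-1) / (2 * self.sigma**2))

    def _gradient(self, p: np.ndarray) -> np.ndarray:
        d = p - np.asarray(self.center)
        c = self._concentration(p)
        return -d * (c / self.sigma**2)[..., None]


@dataclass(frozen=True)
class GridEnvironment(Environment):
    """Sampled field with bilinear interpolation; gradient by central differences."""

    x: np.ndarray = field(default_factory=lambda: np.linspace(-4.5, 4.5, 10))
    y: np.ndarray = field(default_factory=lambda: np.linspace(-4.5, 4.5, 10))
    values: np.ndarray = field(default_factory=lambda: np.zeros((10, 10)))

    kind = "grid"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.x), len(self.y)):
            raise ValueError("values must have shape (len(x), len(y))")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid values must be finite")
        object.__setattr__(
            self, "bounds", (self.x[0], self.x[-1], self.y[0], self.y[-1])
        )
        interp = RegularGridInterpolator(
            (np.asarray(self.x, float), np.asarray(self.y, float)), v,
            method="linear", bounds_error=False, fill_value=None,
        )
        object.__setattr__(self, "_interp", interp)

    def _concentration(self, p: np.ndarray) -> np.ndarray:
        return self._interp(p)

    def _gradient(self, p: np.ndarray) -> np.ndarray:
        hx = float(np.min(np.diff(self.x))) / 2.0
        hy = float(np.min(np.diff(self.y))) / 2.0
        # clip stencil points into the domain; one-sided at the boundary
        xmin, xmax, ymin, ymax = self.bounds
        px, py = p[:, 0], p[:, 1]
        xp = np.clip(px + hx, xmin, xmax)
        xm = np.clip(px - hx, xmin, xmax)
        yp = np.clip(py + hy, ymin, ymax)
        ym = np.clip(py - hy, ymin, ymax)
        gx = (self._interp(np.stack([xp, py], -1)) - self._interp(np.stack([xm, py], -1))) / (xp - xm)
        gy = (self._interp(np.stack([px, yp], -1)) - self._interp(np.stack([px, ym], -1))) / (yp - ym)
        return np.stack([gx, gy], axis=-1)


def widen(env: GaussianEnvironment, factor: float) -> GaussianEnvironment:
    """Widen a Gaussian landscape: same center and amplitude, sigma *= factor.

    Used to probe generalization of trained agents to shallower gradients
    (e.g. ``factor=1.7``).
    """
    if not isinstance(env, GaussianEnvironment):
        raise TypeError("widen applies only to gaussian environments")
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return replace(env, sigma=env.sigma * factor)


def from_config(cfg: dict) -> Environment:
    """Build an Environment from a config mapping.

    Expected keys: ``kind`` plus, for linear: ``c0, slope, origin``;
    gaussian: ``amplitude, sigma_cm, center``; grid: ``x, y, values``.
    Optional ``bounds = [xmin, xmax, ymin, ymax]``.
    """
    kind = cfg.get("kind", "linear")
    kw = {}
    if "bounds" in cfg:
        kw["bounds"] = tuple(float(b) for b in cfg["bounds"])
    if kind == "linear":
        return LinearEnvironment(
            c0=float(cfg.get("c0", 25.0)),
            slope=tuple(cfg.get("slope", (50.0 / 9.0, 0.0))),
            origin=tuple(cfg.get("origin", (0.0, 0.0))),
            **kw,
        )
    if kind == "gaussian":
        return GaussianEnvironment(
            amplitude=float(cfg.get("amplitude", 50.0)),
            sigma=float(cfg.get("sigma_cm", cfg.get("sigma", 1.5))),
            center=tuple(cfg.get("center", (0.0, 0.0))),
            **kw,
        )
    if kind == "grid":
        return GridEnvironment(
            x=np.asarray(cfg["x"], float),
            y=np.asarray(cfg["y"], float),
            values=np.asarray(cfg["values"], float),
        )
    raise ValueError(f"unknown environment kind {kind!r}")
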