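"""Domain geometries, window sets and source descriptions.

Three unbounded 2D domains are supported, each with a reflecting obstacle
boundary carrying small absorbing windows:

* :class:`HalfPlane` -- the half-plane on one side of the line ``x = 0``;
  windows are intervals on that line.
* :class:`ExteriorDisk` -- the exterior of a disk of radius ``R`` centred at
  the origin; windows are arcs on the circle.
* :class:`StripWithDisk` -- a disk of radius ``R`` centred on the midline of
  an infinite strip with reflecting walls at ``y = +-a``; windows are arcs on
  the disk.

Lengths are nondimensional; the injection rate ``Q`` and (for the analytic
formulas) the diffusivity ``D`` are scaled to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import DomainError, RegimeViolationError, RegimeWarning

__all__ = [
    "HalfPlane",
    "ExteriorDisk",
    "StripWithDisk",
    "Geometry",
    "WindowSet",
    "SourceSpec",
    "as_point",
]

_BOUNDARY_TOL = 1e-9


def as_point(p) -> np.ndarray:
    """Coerce to a finite (2,) float array."""
    arr = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"point has non-finite components: {arr!r}")
    return arr


@dataclass(frozen=True)
class HalfPlane:
    """Half-plane domain ``{x : side * x[0] > 0}`` bounded by the line x = 0.

    ``side=+1`` puts the domain to the right of the (vertical) boundary line,
    ``side=-1`` to the left.  The physics is mirror symmetric; the orientation
    only fixes on which side sources and trajectories live.
    """

    side: int = 1
    tag: str = field(default="half_plane", init=False, repr=False)

    def __post_init__(self):
        if self.side not in (-1, 1):
            raise DomainError("side must be +1 or -1")

    def contains(self, p, strict: bool = False) -> bool:
        p = as_point(p)
        s = self.side * p[0]
        return s > 0 if strict else s >= -_BOUNDARY_TOL

    def on_boundary(self, p, tol: float = _BOUNDARY_TOL) -> bool:
        return abs(as_point(p)[0]) <= tol

    def mirror(self, p) -> np.ndarray:
        """Image of ``p`` across the boundary line."""
        p = as_point(p)
        return np.array([-p[0], p[1]])

    def boundary_point(self, y: float) -> np.ndarray:
        return np.array([0.0, float(y)])


@dataclass(frozen=True)
class ExteriorDisk:
    """Exterior of the disk of radius ``R`` centred at the origin."""

    R: float
    tag: str = field(default="exterior_disk", init=False, repr=False)

    def __post_init__(self):
        if not (self.R > 0):
            raise DomainError("obstacle radius R must be positive")

    def contains(self, p, strict: bool = False) -> bool:
        r = np.hypot(*as_point(p))
        return r > self.R if strict else r >= self.R - _BOUNDARY_TOL

    def on_boundary(self, p, tol: float = _BOUNDARY_TOL) -> bool:
        return abs(np.hypot(*as_point(p)) - self.R) <= tol

    def image_point(self, p) -> np.ndarray:
        """Inverse point R^2 x / |x|^2 used by the method of images."""
        p = as_point(p)
        r2 = p @ p
        if r2 == 0.0:
            raise DomainError("image point undefined at the origin")
        return (self.R**2 / r2) * p

    def boundary_point(self, angle: float) -> np.ndarray:
        return self.R * np.array([np.cos(angle), np.sin(angle)])


@dataclass(frozen=True)
class StripWithDisk:
    """Disk of radius ``R`` at the origin inside the strip ``|y| < a``.

    The strip walls at ``y = +-a`` reflect; the total strip width is ``2a``.
    """

    R: float
    a: float
    tag: str = field(default="strip_with_disk", init=False, repr=False)

    def __post_init__(self):
        if not (self.R > 0):
            raise DomainError("obstacle radius R must be positive")
        if not (self.a > self.R):
            raise DomainError("strip half-width a must exceed the disk radius R")

    @property
    def width(self) -> float:
        return 2.0 * self.a

    def contains(self, p, strict: bool = False) -> bool:
        p = as_point(p)
        r = np.hypot(*p)
        tol = 0.0 if strict else _BOUNDARY_TOL
        in_strip = abs(p[1]) < self.a + tol if not strict else abs(p[1]) < self.a
        return in_strip and (r > self.R if strict else r >= self.R - _BOUNDARY_TOL)

    def on_boundary(self, p, tol: float = _BOUNDARY_TOL) -> bool:
        return abs(np.hypot(*as_point(p)) - self.R) <= tol

    def image_point(self, p) -> np.ndarray:
        p = as_point(p)
        r2 = p @ p
        if r2 == 0.0:
            raise DomainError("image point undefined at the origin")
        return (self.R**2 / r2) * p

    def boundary_point(self, angle: float) -> np.ndarray:
        return self.R * np.array([np.cos(angle), np.sin(angle)])


Geometry = Union[HalfPlane, ExteriorDisk, StripWithDisk]


def _obstacle_radius(geom: Geometry):
    return getattr(geom, "R", None)


@dataclass(frozen=True)
class WindowSet:
    """Ordered absorbing windows on the obstacle boundary.

    Parameters
    ----------
    centers : (N, 2) array
        Window centre points, all on the boundary of the geometry they are
        used with.
    eps : float
        Common window size, measured as full arclength (a window covers
        ``+- eps/2`` around its centre).
    """

    centers: np.ndarray
    eps: float

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.ndim != 2 or centers.shape[1] != 2 or centers.shape[0] < 1:
            raise DomainError("centers must be an (N, 2) array with N >= 1")
        if not np.all(np.isfinite(centers)):
            raise DomainError("window centers must be finite")
        object.__setattr__(self, "centers", centers)
        if not (self.eps > 0):
            raise RegimeViolationError("window size eps must be positive")

    @classmethod
    def on_line(cls, ys, eps: float) -> "WindowSet":
        """Windows at heights ``ys`` on the half-plane boundary line x=0."""
        ys = np.asarray(ys, dtype=float).ravel()
        return cls(np.column_stack([np.zeros_like(ys), ys]), eps)

    @classmethod
    def from_angles(cls, angles, eps: float, R: float) -> "WindowSet":
        """Windows at the given polar angles on a circle of radius ``R``."""
        angles = np.asarray(angles, dtype=float).ravel()
        return cls(R * np.column_stack([np.cos(angles), np.sin(angles)]), eps)

    @property
    def n_windows(self) -> int:
        return self.centers.shape[0]

    def angles(self) -> np.ndarray:
        """Polar angles of the centres (meaningful for disk geometries)."""
        return np.arctan2(self.centers[:, 1], self.centers[:, 0])

    def pairwise_distances(self) -> np.ndarray:
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    def min_separation(self) -> float:
        if self.n_windows < 2:
            return np.inf
        d = self.pairwise_distances()
        return float(d[np.triu_indices(self.n_windows, k=1)].min())

    def extent(self) -> float:
        """Radius of the smallest origin-centred circle containing all windows."""
        return float(np.hypot(self.centers[:, 0], self.centers[:, 1]).max() + self.eps / 2)

    def validate(self, geom: Geometry, *, warn_factor: float = 5.0) -> None:
        """Check centres sit on the boundary and windows are well separated.

        Raises :class:`RegimeViolationError` when two windows are closer than
        ``eps``; emits :class:`RegimeWarning` when closer than
        ``warn_factor * eps`` (the formulas remain usable but degrade).
        """
        for c in self.centers:
            if not geom.on_boundary(c, tol=1e-7):
                raise DomainError(
                    f"window centre {c} does not lie on the obstacle boundary of {geom.tag}"
                )
        sep = self.min_separation()
        if sep <= self.eps:
            raise RegimeViolationError(
                f"window separation {sep:.3g} <= window size eps={self.eps:.3g}"
            )
        if sep < warn_factor * self.eps:
            warnings.warn(
                f"window separation {sep:.3g} < {warn_factor:g}*eps; "
                "asymptotic formulas are near the edge of their validity",
                RegimeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class SourceSpec:
    """Point source emitting Brownian particles at rate Q.

    The analytic formulas use ``Q = 1`` and ``D = 1``; both are retained for
    documentation and for the simulator (where only their product's scale is
    irrelevant to splitting probabilities).
    """

    x0: np.ndarray
    Q: float = 1.0
    D: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "x0", as_point(self.x0))
        if not (self.Q > 0):
            raise DomainError("injection rate Q must be positive")
        if not (self.D > 0):
            raise DomainError("diffusivity D must be positive")

    def validate(self, geom: Geometry, windows: WindowSet | None = None) -> None:
        if not geom.contains(self.x0):
            raise DomainError(f"source {self.x0} lies outside the domain of {geom.tag}")
        if windows is not None:
            d = np.hypot(*(windows.centers - self.x0).T)
            if np.any(d < windows.eps):
                raise DomainError("source must not sit on an absorbing window")
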