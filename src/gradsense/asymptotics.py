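"""Matched-asymptotic splitting probabilities and sensitivity functions.

In the narrow-escape regime (window size ``eps`` much smaller than window
separations) the steady-state density outside the obstacle is the Neumann
Green's function of the domain plus one logarithmic inner solution per
window,

    P(x) = G(x, x0) + sum_k A_k (ln|x - x_k| - ln eps_hat) + C,

and matching at each window centre yields an (N+1) x (N+1) linear system for
the flux coefficients ``A_k`` and the constant ``C``.  The splitting
probability of window k is ``P_k = pi A_k``; 2D recurrence of Brownian
motion normalises ``sum_k P_k = 1``.

Two conventions matter and are fixed here once:

* **Sign.**  Matching the boundary-layer conditions gives
  ``A_1 - A_2 = (G(x_1, x0) - G(x_2, x0)) / ln(d / eps_hat)``, so the window
  with the larger Green's-function value -- the one nearer the source --
  receives the larger flux.  The hybrid simulator independently confirms
  this orientation.

* **Matching constant.**  The inner problem near a window of arclength
  ``eps`` (an absorbing segment on a reflecting line) has the exact far
  field ``A (ln|x - x_i| - ln(eps/4))``: the logarithmic capacity of a flat
  segment of length ``eps`` is ``eps/4``, not ``eps``.  By default all
  logarithms therefore use the effective size ``eps_hat = eps / 4``
  (``capacity_factor=4``), which is what makes the asymptotics agree with
  Brownian simulation beyond leading logarithmic order.  Passing
  ``capacity_factor=1`` reproduces the plain leading-log formulas in which
  the matching constant is ``ln eps`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    DomainError,
    RegimeViolationError,
)
from .geometry import (
    ExteriorDisk,
    Geometry,
    HalfPlane,
    SourceSpec,
    WindowSet,
    as_point,
)
from .greens import green_neumann_exterior_disk, green_neumann_halfplane
from .results import SplittingResult, WindowSystemSolution

__all__ = [
    "WINDOW_CAPACITY_FACTOR",
    "greens_value",
    "splitting_two_windows",
    "solve_window_system",
    "three_window_explicit",
    "sensitivity_ratio_halfplane",
    "detection_threshold_disk",
    "detection_threshold_disk_asymptotic",
    "two_class_sensitivity_product",
    "source_locus_curve",
    "LocusCurve",
]

_COND_LIMIT = 1e12

#: Default ratio eps / eps_hat: a flat absorbing segment of arclength eps has
#: logarithmic capacity eps/4 (exact inner solution).  Use 1.0 for the plain
#: leading-log convention.
WINDOW_CAPACITY_FACTOR = 4.0


def greens_value(geom: Geometry, x, x0) -> float:
    """Neumann Green's function of ``geom`` evaluated at (x, x0)."""
    if isinstance(geom, HalfPlane):
        return green_neumann_halfplane(x, x0)
    if isinstance(geom, ExteriorDisk):
        return green_neumann_exterior_disk(x, x0, geom.R)
    raise DomainError(
        f"no closed-form Neumann Green's function for geometry {geom.tag!r}; "
        "use the hybrid simulator for this domain"
    )


def _eps_hat(eps: float, capacity_factor: float) -> float:
    if not (capacity_factor > 0):
        raise DomainError("capacity_factor must be positive")
    return eps / capacity_factor


def _log_ratio(windows: WindowSet, i: int, j: int, capacity_factor: float) -> float:
    d = float(np.hypot(*(windows.centers[i] - windows.centers[j])))
    return float(np.log(d / _eps_hat(windows.eps, capacity_factor)))


def splitting_two_windows(
    geom: Geometry,
    windows: WindowSet,
    src: SourceSpec,
    *,
    capacity_factor: float = WINDOW_CAPACITY_FACTOR,
) -> SplittingResult:
    """Closed-form splitting probabilities for exactly two windows.

    ``P_1 = 1/2 + (pi/2) (G(x1,x0) - G(x2,x0)) / ln(d/eps_hat)`` and
    ``P_2 = 1 - P_1`` (exact conservation).
    """
    if windows.n_windows != 2:
        raise DomainError("splitting_two_windows requires exactly two windows")
    windows.validate(geom)
    src.validate(geom, windows)
    x1, x2 = windows.centers
    g1 = greens_value(geom, x1, src.x0)
    g2 = greens_value(geom, x2, src.x0)
    log_d_eps = _log_ratio(windows, 0, 1, capacity_factor)
    p1 = 0.5 + (np.pi / 2.0) * (g1 - g2) / log_d_eps
    return SplittingResult(
        np.array([p1, 1.0 - p1]),
        provenance="analytic",
        diagnostics={"G": [g1, g2], "log_d_eps": log_d_eps},
    )


def solve_window_system(
    geom: Geometry,
    windows: WindowSet,
    src: SourceSpec,
    *,
    capacity_factor: float = WINDOW_CAPACITY_FACTOR,
) -> WindowSystemSolution:
    """Solve the N-window matched-asymptotic linear system.

    The bordered symmetric matrix has off-diagonal entries
    ``ln(|x_i - x_j| / eps_hat)``, a border of ones, zero diagonal; the right
    side is ``(-G(x_1, x0), ..., -G(x_N, x0), 1/pi)``.  Raises on singular or
    badly conditioned window layouts.
    """
    windows.validate(geom)
    src.validate(geom, windows)
    n = windows.n_windows
    a = np.zeros((n + 1, n + 1))
    dists = windows.pairwise_distances()
    off_mask = ~np.eye(n, dtype=bool)
    if np.any(dists[off_mask] <= 0.0):
        raise DegenerateConfigurationError("coincident window centres")
    eps_hat = _eps_hat(windows.eps, capacity_factor)
    np.fill_diagonal(dists, eps_hat)  # placeholder; diagonal is zeroed below
    off = np.log(dists / eps_hat)
    np.fill_diagonal(off, 0.0)
    a[:n, :n] = off
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    b = np.empty(n + 1)
    for i in range(n):
        b[i] = -greens_value(geom, windows.centers[i], src.x0)
    b[n] = 1.0 / np.pi
    cond = float(np.linalg.cond(a))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise DegenerateConfigurationError(
            f"window-system matrix is ill conditioned (cond={cond:.3g})"
        )
    sol = np.linalg.solve(a, b)
    return WindowSystemSolution(A=sol[:n], C=float(sol[n]), cond=cond)


def three_window_explicit(
    geom: Geometry,
    windows: WindowSet,
    src: SourceSpec,
    *,
    capacity_factor: float = WINDOW_CAPACITY_FACTOR,
) -> WindowSystemSolution:
    """Explicit three-window solution via the 2x2 determinant reduction.

    Eliminating ``C`` and ``A_1`` from the matching conditions leaves, with
    ``L_ij = ln(d_ij / eps_hat)`` and ``M = L_12 + L_13 - L_23``::

        2 L_12 A_2 + M A_3 = G_20 - G_10 + L_12 / pi
        M A_2 + 2 L_13 A_3 = G_30 - G_10 + L_13 / pi

    solved by Cramer's rule with determinant ``-(Delta_123)`` where
    ``Delta_123 = M^2 - 4 L_12 L_13``; ``A_1 = 1/pi - A_2 - A_3``.
    """
    if windows.n_windows != 3:
        raise DomainError("three_window_explicit requires exactly three windows")
    windows.validate(geom)
    src.validate(geom, windows)
    l12 = _log_ratio(windows, 0, 1, capacity_factor)
    l13 = _log_ratio(windows, 0, 2, capacity_factor)
    l23 = _log_ratio(windows, 1, 2, capacity_factor)
    m = l12 + l13 - l23
    delta = m * m - 4.0 * l12 * l13
    if abs(delta) < 1e-10 * max(1.0, l12 * l13):
        raise DegenerateConfigurationError(
            "three-window determinant Delta_123 vanishes; configuration is degenerate"
        )
    g10 = greens_value(geom, windows.centers[0], src.x0)
    g20 = greens_value(geom, windows.centers[1], src.x0)
    g30 = greens_value(geom, windows.centers[2], src.x0)
    b1 = g20 - g10 + l12 / np.pi
    b2 = g30 - g10 + l13 / np.pi
    a2 = (m * b2 - 2.0 * l13 * b1) / delta
    a3 = (m * b1 - 2.0 * l12 * b2) / delta
    a1 = 1.0 / np.pi - a2 - a3
    return WindowSystemSolution(A=np.array([a1, a2, a3]), C=np.nan, delta123=delta)


# ---------------------------------------------------------------------------
# sensitivity / detection threshold
# ---------------------------------------------------------------------------

def sensitivity_ratio_halfplane(d: float, L, theta, eps: float, *,
                                capacity_factor: float = WINDOW_CAPACITY_FACTOR):
    """Sensitivity ratio |P1 - P2| of two boundary windows a distance d apart.

    The source sits at distance ``L`` from the midpoint of the pair, at angle
    ``theta`` from the axis perpendicular to the window axis::

        r = | (1/2) ln[(d^2/4 + L^2 - L d sin t) / (d^2/4 + L^2 + L d sin t)]
              / ln(d/eps_hat) |
    """
    d = float(d)
    L = np.asarray(L, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (d > 0) or np.any(L <= 0):
        raise DomainError("require d > 0 and L > 0")
    if not (0 < eps < d):
        raise RegimeViolationError("require 0 < eps < d")
    c = d * d / 4.0 + L * L
    s = L * d * np.sin(theta)
    val = np.abs(0.5 * np.log((c - s) / (c + s))
                 / np.log(d / _eps_hat(eps, capacity_factor)))
    return val if val.ndim else float(val)


def detection_threshold_disk(R: float, L, eps: float, *,
                             capacity_factor: float = WINDOW_CAPACITY_FACTOR):
    """Maximum sensitivity ratio for a disk of radius R and source distance L.

    Achieved by a diametrically opposed window pair aligned with the source::

        f = (1/2) ln[ (1 + L/R)(1 + R/L) / ((L/R - 1)(1 - R/L)) ]
            / ln(2R/eps_hat)

    For large ``L``, ``f ~ 2R / (L ln(2R/eps_hat))``.
    """
    L = np.asarray(L, dtype=float)
    if not (L.min() > R > eps > 0):
        raise DomainError("require L > R > eps > 0")
    u = L / R
    num = (1.0 + u) * (1.0 + 1.0 / u)
    den = (u - 1.0) * (1.0 - 1.0 / u)
    val = 0.5 * np.log(num / den) / np.log(2.0 * R / _eps_hat(eps, capacity_factor))
    return val if val.ndim else float(val)


def detection_threshold_disk_asymptotic(R: float, L, eps: float, *,
                                        capacity_factor: float = WINDOW_CAPACITY_FACTOR):
    """Large-distance decay ``2R / (L ln(2R/eps_hat))`` of the threshold."""
    L = np.asarray(L, dtype=float)
    if not (L.min() > R > eps > 0):
        raise DomainError("require L > R > eps > 0")
    val = 2.0 * R / (L * np.log(2.0 * R / _eps_hat(eps, capacity_factor)))
    return val if val.ndim else float(val)


def two_class_sensitivity_product(R: float, L, eps: float, *,
                                  capacity_factor: float = WINDOW_CAPACITY_FACTOR):
    """Two-particle-class sensitivity ``f^2`` (independent window types)."""
    f = detection_threshold_disk(R, L, eps, capacity_factor=capacity_factor)
    return f * f


# ---------------------------------------------------------------------------
# source locus curve (two windows)
# ---------------------------------------------------------------------------

@dataclass
class LocusCurve:
    """One-dimensional set of source positions consistent with ``P_2 = alpha``.

    ``implicit(x0)`` vanishes on the curve (it equals ``P_2(x0) - alpha``);
    ``points`` is a traced polyline ordered by polar angle around the window
    midpoint (half-plane) or the disk centre.
    """

    geom: Geometry
    windows: WindowSet
    alpha: float
    implicit: Callable
    points: np.ndarray

    def __call__(self, x0):
        return self.implicit(x0)


def _two_window_p2(geom, windows, x0, capacity_factor):
    x1, x2 = windows.centers
    g1 = greens_value(geom, x1, x0)
    g2 = greens_value(geom, x2, x0)
    return 0.5 + (np.pi / 2.0) * (g2 - g1) / _log_ratio(windows, 0, 1,
                                                        capacity_factor)


def source_locus_curve(
    geom: Geometry,
    windows: WindowSet,
    alpha: float,
    *,
    resolution: int = 181,
    r_max: float | None = None,
    capacity_factor: float = WINDOW_CAPACITY_FACTOR,
) -> LocusCurve:
    """Trace the locus of source positions with splitting probability alpha.

    The curve is found by scanning rays from the window midpoint (half-plane)
    or the disk centre and bracketing sign changes of ``P_2(x0) - alpha``
    along each ray, refined by bisection.
    """
    from scipy.optimize import brentq

    if windows.n_windows != 2:
        raise DomainError("source_locus_curve requires exactly two windows")
    if not (0.0 < alpha < 1.0):
        raise DegenerateConfigurationError("alpha must lie strictly in (0, 1)")
    windows.validate(geom)
    d = windows.min_separation()
    if r_max is None:
        r_max = 50.0 * d

    def implicit(x0):
        return _two_window_p2(geom, windows, as_point(x0), capacity_factor) - alpha

    if isinstance(geom, HalfPlane):
        mid = windows.centers.mean(axis=0)
        # rays into the domain: angle from boundary axis in (0, pi)
        phis = np.linspace(1e-3, np.pi - 1e-3, resolution)
        dirs = np.column_stack([geom.side * np.sin(phis), np.cos(phis)])
        r_min = 1e-6 * d
    elif isinstance(geom, ExteriorDisk):
        mid = np.zeros(2)
        phis = np.linspace(-np.pi, np.pi, resolution, endpoint=False)
        dirs = np.column_stack([np.cos(phis), np.sin(phis)])
        r_min = geom.R * (1.0 + 1e-9)
    else:
        raise DomainError(f"locus curve unsupported for geometry {geom.tag!r}")

    pts = []
    radii = np.geomspace(max(r_min, 1e-6 * d), r_max, 160)
    for u in dirs:
        vals = np.empty(radii.size)
        for k, r in enumerate(radii):
            try:
                vals[k] = implicit(mid + r * u)
            except Exception:
                vals[k] = np.nan
        ok = np.isfinite(vals)
        # a ray lying exactly on the curve (symmetry line) contributes its
        # grid points directly; otherwise bracket strict sign changes
        on_curve = ok & (np.abs(vals) < 1e-14)
        for k in np.where(on_curve)[0]:
            pts.append(mid + radii[k] * u)
        idx = np.where(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] < 0.0))[0]
        for k in idx:
            try:
                r_star = brentq(lambda r: implicit(mid + r * u),
                                radii[k], radii[k + 1], xtol=1e-14, rtol=1e-15)
            except ValueError:
                continue
            pts.append(mid + r_star * u)
    points = np.asarray(pts) if pts else np.empty((0, 2))
    return LocusCurve(geom=geom, windows=windows, alpha=alpha,
                      implicit=implicit, points=points)
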