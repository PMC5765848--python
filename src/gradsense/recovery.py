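"""Inversion of observed window fluxes to the source position.

With two windows a single flux ratio constrains the source only to a
one-dimensional locus; with three or more windows the ``N - 1`` independent
fluxes generically intersect in a single point.  The forward map is the
matched-asymptotic window system; inversion is multi-start damped least
squares over a polar grid of initial guesses, with candidate roots deduped
and (for more than two independent fluxes) filtered by the residual of all
window conditions, which discards spurious pairwise curve intersections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .asymptotics import solve_window_system, source_locus_curve, LocusCurve
from .errors import (
    AmbiguityWarning,
    ConfigurationError,
    DomainError,
    NoSolutionError,
)
from .geometry import (
    ExteriorDisk,
    Geometry,
    HalfPlane,
    SourceSpec,
    WindowSet,
)
from .results import RecoveryResult, UncertaintyRegion

__all__ = ["RecoveryProblem", "forward_fluxes", "recover_source",
           "recovery_uncertainty", "distance_flux_map", "recover_two_windows"]


@dataclass(frozen=True)
class RecoveryProblem:
    """Observed fluxes to invert.

    ``observed`` holds the splitting probabilities of the first ``N - 1``
    windows (the last one is redundant by flux conservation); ``eta`` is the
    amplitude of the multiplicative flux perturbation used for uncertainty
    regions.
    """

    geometry: Geometry
    windows: WindowSet
    observed: np.ndarray
    eta: float = 0.0

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float).ravel()
        object.__setattr__(self, "observed", obs)
        n = self.windows.n_windows
        if obs.size != n - 1:
            raise ConfigurationError(
                f"expected {n - 1} observed fluxes for {n} windows, got {obs.size}"
            )
        if np.any(obs <= 0.0) or obs.sum() >= 1.0:
            raise ConfigurationError(
                "observed fluxes must be positive with sum < 1"
            )
        if not (self.eta >= 0.0):
            raise ConfigurationError("eta must be nonnegative")


def forward_fluxes(geom: Geometry, windows: WindowSet, x0) -> np.ndarray:
    """Splitting probabilities of all windows for a source at ``x0``."""
    sol = solve_window_system(geom, windows, SourceSpec(x0))
    return sol.probabilities


# -- parametrisations keeping optimizer iterates inside the domain ----------

def _make_maps(geom: Geometry):
    if isinstance(geom, HalfPlane):
        s = float(geom.side)

        def to_xy(p):
            return np.array([s * abs(p[0]), p[1]])

        def from_xy(x):
            return np.array([abs(x[0]), x[1]])

    elif isinstance(geom, ExteriorDisk):
        R = geom.R

        def to_xy(p):
            r = R + np.exp(p[0])
            return np.array([r * np.cos(p[1]), r * np.sin(p[1])])

        def from_xy(x):
            r = np.hypot(*x)
            return np.array([np.log(max(r - R, 1e-12)), np.arctan2(x[1], x[0])])

    else:
        raise DomainError(
            f"source recovery requires a closed-form forward model; "
            f"geometry {geom.tag!r} is unsupported"
        )
    return to_xy, from_xy


def _default_starts(geom: Geometry, windows: WindowSet, r_max: float):
    mid = (np.zeros(2) if isinstance(geom, ExteriorDisk)
           else windows.centers.mean(axis=0))
    d = windows.min_separation()
    radii = np.geomspace(max(0.5 * d, 1e-3), r_max, 6)
    if isinstance(geom, HalfPlane):
        phis = np.linspace(0.15, np.pi - 0.15, 8)
        dirs = np.column_stack([geom.side * np.sin(phis), np.cos(phis)])
    else:
        phis = np.linspace(-np.pi, np.pi, 8, endpoint=False)
        dirs = np.column_stack([np.cos(phis), np.sin(phis)])
        mid = np.zeros(2)
    starts = [mid + r * u for r in radii for u in dirs]
    if isinstance(geom, ExteriorDisk):
        starts = [p for p in starts if np.hypot(*p) > geom.R * 1.01]
    return starts


def recover_source(
    problem: RecoveryProblem,
    *,
    starts=None,
    r_max_factor: float = 50.0,
    residual_tol: float = 1e-9,
    dedup_tol: float = 1e-4,
) -> RecoveryResult:
    """Locate the source position reproducing the observed fluxes.

    Runs damped least squares from a polar grid of starting points (or the
    supplied ``starts``), keeps converged roots whose full-system residual is
    below ``residual_tol``, dedupes them, and returns the best root.  More
    than one surviving root is reported through ``candidates`` and an
    :class:`AmbiguityWarning`.
    """
    geom, windows, obs = problem.geometry, problem.windows, problem.observed
    if windows.n_windows < 3:
        raise ConfigurationError(
            "recover_source needs at least three windows; "
            "use recover_two_windows for the two-window locus"
        )
    to_xy, from_xy = _make_maps(geom)
    d = windows.min_separation()
    r_max = r_max_factor * d
    if starts is None:
        starts = _default_starts(geom, windows, r_max)

    def residuals(p):
        xy = to_xy(p)
        try:
            fl = forward_fluxes(geom, windows, xy)
        except Exception:
            return np.full(obs.size, 1e3)
        return fl[:-1] - obs

    roots = []
    costs = []
    n_conv = 0
    for s0 in starts:
        try:
            res = least_squares(residuals, from_xy(np.asarray(s0, float)),
                                method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=400)
        except Exception:
            continue
        xy = to_xy(res.x)
        rn = float(np.linalg.norm(residuals(res.x)))
        if rn < residual_tol and np.hypot(*(xy - windows.centers.mean(axis=0))) < 2 * r_max:
            n_conv += 1
            roots.append(xy)
            costs.append(rn)
    if not roots:
        raise NoSolutionError("no source position reproduces the observed fluxes "
                              "inside the search domain")
    roots = np.asarray(roots)
    costs = np.asarray(costs)
    order = np.argsort(costs)
    distinct = []
    distinct_costs = []
    for i in order:
        if all(np.hypot(*(roots[i] - q)) > dedup_tol for q in distinct):
            distinct.append(roots[i])
            distinct_costs.append(costs[i])
    distinct = np.asarray(distinct)
    ambiguous = distinct.shape[0] > 1
    if ambiguous:
        warnings.warn(
            f"{distinct.shape[0]} candidate source positions survive the "
            "all-window flux check", AmbiguityWarning, stacklevel=2)
    return RecoveryResult(
        position=distinct[0],
        residual_norm=float(distinct_costs[0]),
        candidates=distinct,
        ambiguous=ambiguous,
        n_starts_converged=n_conv,
    )


def recovery_uncertainty(
    problem: RecoveryProblem,
    *,
    grid: int = 21,
    r_max_factor: float = 50.0,
) -> UncertaintyRegion:
    """Image of the multiplicative flux-perturbation box under recovery.

    Each observed flux ``o_i`` is perturbed to ``o_i (1 + eta_i)`` with
    ``eta_i`` running over a ``grid x grid`` sample of ``[-eta, eta]^2``
    (all sign combinations of the two independent fluxes are covered, a
    superset of perturbing both with a common factor).  Returns the convex
    hull of the recovered positions; the unperturbed solution is always a
    sample point, so the region contains it.
    """
    if problem.eta < 0:
        raise ConfigurationError("eta must be nonnegative")
    base = recover_source(problem, r_max_factor=r_max_factor)
    if problem.eta == 0.0:
        pt = base.position[None, :]
        return UncertaintyRegion(points=pt, hull_vertices=pt, area=0.0,
                                 eta=0.0, partial=False)
    obs0 = problem.observed
    etas = np.linspace(-problem.eta, problem.eta, grid)
    pts = []
    partial = False
    for e1 in etas:
        for e2 in etas:
            obs = obs0 * (1.0 + np.array([e1, e2]))
            if np.any(obs <= 0) or obs.sum() >= 1.0:
                partial = True
                continue
            try:
                prob = RecoveryProblem(problem.geometry, problem.windows, obs)
                res = recover_source(prob, starts=[base.position],
                                     r_max_factor=r_max_factor)
            except NoSolutionError:
                partial = True
                continue
            pts.append(res.position)
    pts = np.asarray(pts)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
        area = float(hull.volume)
    except (QhullError, ValueError):
        verts = pts
        area = 0.0
    return UncertaintyRegion(points=pts, hull_vertices=verts, area=area,
                             eta=problem.eta, partial=partial)


def distance_flux_map(
    geom: Geometry,
    windows: WindowSet,
    p1_values,
    p3_values,
    *,
    ref_point=None,
    margin: float = 1e-3,
    r_max_factor: float = 50.0,
):
    """Distance to the recovered source over a grid of flux pairs.

    For three windows the admissible flux pairs ``(P1, P3)`` fill the open
    simplex ``P1, P3 > 0, P1 + P3 < 1``; each admissible cell is inverted to
    a source position and mapped to its distance from ``ref_point`` (the
    window centroid by default).  Returns ``(P1_grid, P3_grid, distances)``
    with inadmissible or unsolvable cells masked.
    """
    if windows.n_windows != 3:
        raise ConfigurationError("distance_flux_map requires exactly three windows")
    if ref_point is None:
        ref_point = (np.zeros(2) if isinstance(geom, ExteriorDisk)
                     else windows.centers.mean(axis=0))
    ref_point = np.asarray(ref_point, dtype=float)
    p1_values = np.asarray(p1_values, dtype=float)
    p3_values = np.asarray(p3_values, dtype=float)
    P1, P3 = np.meshgrid(p1_values, p3_values, indexing="ij")
    dist = np.full(P1.shape, np.nan)
    last_good = None
    for i in range(P1.shape[0]):
        for j in range(P1.shape[1]):
            p1, p3 = P1[i, j], P3[i, j]
            if p1 < margin or p3 < margin or p1 + p3 > 1.0 - margin:
                continue
            obs = np.array([p1, 1.0 - p1 - p3])
            try:
                prob = RecoveryProblem(geom, windows, obs)
                starts = [last_good] if last_good is not None else None
                try:
                    res = recover_source(prob, starts=starts,
                                         r_max_factor=r_max_factor)
                except NoSolutionError:
                    if starts is not None:
                        res = recover_source(prob, r_max_factor=r_max_factor)
                    else:
                        raise
            except NoSolutionError:
                last_good = None
                continue
            last_good = res.position
            dist[i, j] = np.hypot(*(res.position - ref_point))
    return P1, P3, np.ma.masked_invalid(dist)


def recover_two_windows(problem: RecoveryProblem) -> tuple[LocusCurve, int]:
    """Two-window inversion: the locus curve plus a direction indicator.

    Returns the locus of source positions with ``P_2 = 1 - alpha`` (where
    ``alpha`` is the observed flux of window 1) and the index of the window
    receiving the larger flux -- the side the source lies on.
    """
    if problem.windows.n_windows != 2:
        raise ConfigurationError("recover_two_windows requires exactly two windows")
    alpha = float(problem.observed[0])
    curve = source_locus_curve(problem.geometry, problem.windows, 1.0 - alpha)
    direction = 0 if alpha > 0.5 else 1
    return curve, direction
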