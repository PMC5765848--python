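"""Closed-form Green's functions and boundary exit densities.

Two families of kernels, both obtained by the method of images:

* **Neumann Green's functions** of the Laplacian for the half-plane and the
  exterior of a disk.  These are the outer solutions of the matched
  asymptotics: ``G`` has a ``-(1/2pi) ln`` singularity at the source and zero
  normal derivative on the reflecting boundary.
* **Exit densities** (harmonic measures) on artificial absorbing boundaries:
  a circle in free space, a half-circle against a reflecting line, and a
  cross-section of a semi-infinite strip.  These drive the injection and
  re-injection steps of the hybrid simulator.

The circle exit density is a wrapped Cauchy distribution in the angle; the
half-circle and strip densities are its mirror-folded images, so all three
are sampled exactly by inverse-CDF transforms followed by folding (no
rejection step is needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DomainError, SingularInputError
from .geometry import as_point

__all__ = [
    "green_neumann_halfplane",
    "green_neumann_exterior_disk",
    "green_semistrip",
    "exit_pdf_full_space",
    "exit_pdf_half_space",
    "exit_pdf_semistrip",
    "FullSpaceExitPdf",
    "HalfSpaceExitPdf",
    "SemiStripExitPdf",
    "sample_exit_point",
    "wrapped_cauchy_sample",
]

_SINGULAR_TOL = 1e-12
_TWO_PI = 2.0 * np.pi


def _check_not_coincident(d2: float) -> None:
    if d2 < _SINGULAR_TOL**2:
        raise SingularInputError("evaluation point coincides with the source point")


def green_neumann_halfplane(x, x0) -> float:
    """Neumann Green's function of the half-plane bounded by the line x = 0.

    ``G(x, x0) = -(1/2pi) (ln|x - x0| + ln|x - x0_bar|)`` with ``x0_bar`` the
    mirror image of ``x0`` across the boundary line.  The normal derivative
    vanishes on the line.  Both points must lie on the same (closed) side of
    the boundary; window centres on the line itself are allowed.
    """
    x = as_point(x)
    x0 = as_point(x0)
    if x[0] * x0[0] < -_SINGULAR_TOL:
        raise DomainError("x and x0 lie on opposite sides of the boundary line")
    d2 = float((x - x0) @ (x - x0))
    _check_not_coincident(d2)
    x0m = np.array([-x0[0], x0[1]])
    d2m = float((x - x0m) @ (x - x0m))
    _check_not_coincident(d2m)
    return -(np.log(d2) + np.log(d2m)) / (4.0 * np.pi)


def green_neumann_exterior_disk(x, x0, R: float) -> float:
    """Neumann Green's function for the exterior of a disk of radius ``R``.

    ``G(x, x0) = -(1/2pi)(ln|x - x0| + ln|(R^2/|x|^2) x - x0|)``; its radial
    derivative vanishes on the circle ``|x| = R``.  Points on the circle are
    allowed (window centres); points strictly inside raise ``DomainError``.
    """
    if not (R > 0):
        raise DomainError("R must be positive")
    x = as_point(x)
    x0 = as_point(x0)
    rx2 = float(x @ x)
    r02 = float(x0 @ x0)
    tol = 1e-9 * R
    if np.sqrt(rx2) < R - tol or np.sqrt(r02) < R - tol:
        raise DomainError("both points must lie outside (or on) the disk")
    d2 = float((x - x0) @ (x - x0))
    _check_not_coincident(d2)
    ximg = (R**2 / rx2) * x
    d2i = float((ximg - x0) @ (ximg - x0))
    _check_not_coincident(d2i)
    return -(np.log(d2) + np.log(d2i)) / (4.0 * np.pi)


def green_semistrip(x1: float, x2: float, y1: float, y2: float, width: float) -> float:
    """Green's function of the semi-strip ``{u > 0, 0 < v < width}``.

    Absorbing on the cross-section ``u = 0``, reflecting on the lateral walls
    ``v = 0`` and ``v = width``.  Arguments are the coordinates ``(x1, x2)``
    of the evaluation point and ``(y1, y2)`` of the source, with ``x1, y1``
    the distances from the absorbing end.  Closed form (image sum of the
    Fourier series) with ``omega = pi / width``::

        G = min(x1, y1)/width - (1/4pi) [ ln h(u, x2+y2) + ln h(u, x2-y2)
                                        - ln h(v, x2+y2) - ln h(v, x2-y2) ]

    where ``h(q, s) = 1 - 2 q cos(omega s) + q^2``, ``u = exp(-omega |x1-y1|)``
    and ``v = exp(-omega (x1+y1))``.  Vanishes at ``y1 = 0``; the normal
    derivative vanishes on the walls.
    """
    if not (width > 0):
        raise DomainError("strip width must be positive")
    for name, u, lo, hi in (
        ("x1", x1, 0.0, np.inf),
        ("y1", y1, 0.0, np.inf),
        ("x2", x2, 0.0, width),
        ("y2", y2, 0.0, width),
    ):
        if not (lo <= u <= hi):
            raise DomainError(f"{name}={u!r} outside the semi-strip")
    if abs(x1 - y1) < _SINGULAR_TOL and abs(x2 - y2) < _SINGULAR_TOL:
        raise SingularInputError("evaluation point coincides with the source point")
    om = np.pi / width
    u = np.exp(-om * abs(x1 - y1))
    v = np.exp(-om * (x1 + y1))
    cp = np.cos(om * (x2 + y2))
    cm = np.cos(om * (x2 - y2))

    def h(q, c):
        return 1.0 - 2.0 * q * c + q * q

    val = min(x1, y1) / width - (
        np.log(h(u, cp)) + np.log(h(u, cm)) - np.log(h(v, cp)) - np.log(h(v, cm))
    ) / (4.0 * np.pi)
    return float(val)


# ---------------------------------------------------------------------------
# exit densities (harmonic measures on artificial boundaries)
# ---------------------------------------------------------------------------

def _poisson_kernel(rho, dtheta):
    """Exterior Poisson kernel (1/2pi)(rho^2-1)/(rho^2-2 rho cos + 1), rho>1."""
    rho = np.asarray(rho, dtype=float)
    return (rho**2 - 1.0) / (_TWO_PI * (rho**2 - 2.0 * rho * np.cos(dtheta) + 1.0))


def exit_pdf_full_space(r, dtheta, Re: float):
    """First-hit density on the circle of radius ``Re`` seen from radius ``r``.

    Density in the exit angle relative to the source angle (``dtheta``,
    2pi-periodic); equals a wrapped Cauchy distribution with parameter
    ``q = Re / r`` and integrates to one over a full period.
    """
    r = np.asarray(r, dtype=float)
    if not (Re > 0):
        raise DomainError("Re must be positive")
    if np.any(r <= Re):
        raise DomainError("source radius r must exceed the absorbing radius Re")
    return _poisson_kernel(r / Re, dtheta)


def exit_pdf_half_space(r, theta, theta_src, Re: float):
    """First-hit density on a half-circle against a reflecting line.

    The absorbing half-circle of radius ``Re`` is centred on the reflecting
    boundary line; angles ``theta`` (exit) and ``theta_src`` (source) are
    measured from the boundary axis and lie in ``[0, pi]``.  The density is
    the mirror-folded Poisson kernel ``K(theta - theta_src) +
    K(theta + theta_src)`` and integrates to one over ``[0, pi]``.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    theta_src = np.asarray(theta_src, dtype=float)
    if not (Re > 0):
        raise DomainError("Re must be positive")
    if np.any(r <= Re):
        raise DomainError("source radius r must exceed the absorbing radius Re")
    if np.any((theta < 0) | (theta > np.pi)) or np.any((theta_src < 0) | (theta_src > np.pi)):
        raise DomainError("angles must lie in [0, pi]")
    rho = r / Re
    return _poisson_kernel(rho, theta - theta_src) + _poisson_kernel(rho, theta + theta_src)


def exit_pdf_semistrip(x2, y1, y2, width: float):
    """First-hit density on the cross-section of a semi-infinite strip.

    The strip occupies ``{u > 0, 0 < v < width}`` with reflecting walls; the
    cross-section ``u = 0`` absorbs.  ``y1 > 0`` is the source distance from
    the absorbing end, ``y2`` its lateral coordinate and ``x2`` the exit
    coordinate.  With ``omega = pi / width``::

        p(x2) = sinh(omega y1) / (2 width) *
                [ 1/(cosh(omega y1) - cos(omega (x2+y2)))
                + 1/(cosh(omega y1) - cos(omega (x2-y2))) ]

    the accordion-folded Cauchy density of the straight-wall problem;
    absorption is certain so it integrates to one over ``(0, width)``.
    """
    x2 = np.asarray(x2, dtype=float)
    if not (width > 0):
        raise DomainError("strip width must be positive")
    if not (y1 > 0):
        raise DomainError("source distance y1 must be positive")
    if not (0 <= y2 <= width):
        raise DomainError("source lateral coordinate y2 outside the strip")
    if np.any((x2 < 0) | (x2 > width)):
        raise DomainError("exit coordinate x2 outside the strip")
    om = np.pi / width
    sh = np.sinh(om * y1)
    ch = np.cosh(om * y1)
    return sh / (2.0 * width) * (
        1.0 / (ch - np.cos(om * (x2 + y2))) + 1.0 / (ch - np.cos(om * (x2 - y2)))
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def wrapped_cauchy_sample(q, u):
    """Inverse-CDF sample of the centred wrapped Cauchy angle.

    ``q`` in (0, 1) is the concentration parameter (``Re / r`` for the circle
    exit problem); ``u`` uniform in (0, 1).  Returns angles in ``(-pi, pi]``.
    """
    q = np.asarray(q, dtype=float)
    u = np.asarray(u, dtype=float)
    return 2.0 * np.arctan(((1.0 - q) / (1.0 + q)) * np.tan(np.pi * (u - 0.5)))


@dataclass(frozen=True)
class FullSpaceExitPdf:
    """Exit density on a full circle of radius ``Re`` from source radius ``r``.

    ``theta_src`` is the polar angle of the source; samples are absolute exit
    angles.  ``boundary_measure`` is the angle interval length (2pi).
    """

    Re: float
    r: float
    theta_src: float = 0.0
    tag: str = field(default="full_space", init=False, repr=False)
    sampling: str = field(default="inverse_cdf", init=False, repr=False)

    def __post_init__(self):
        if not (self.r > self.Re > 0):
            raise DomainError("require r > Re > 0")

    @property
    def q(self) -> float:
        return self.Re / self.r

    def pdf(self, theta):
        return exit_pdf_full_space(self.r, np.asarray(theta) - self.theta_src, self.Re)

    def sample(self, rng: np.random.Generator, size=None):
        u = rng.random(size)
        th = self.theta_src + wrapped_cauchy_sample(self.q, u)
        return np.mod(th, _TWO_PI)

    def point(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.stack([self.Re * np.cos(theta), self.Re * np.sin(theta)], axis=-1)


def _fold_half(phi):
    """Fold angles into [0, pi] by reflection across the boundary axis."""
    phi = np.mod(phi, _TWO_PI)
    return np.where(phi > np.pi, _TWO_PI - phi, phi)


@dataclass(frozen=True)
class HalfSpaceExitPdf:
    """Exit density on a half-circle against a reflecting line.

    Angles from the boundary axis, in ``[0, pi]``.  Sampling draws the
    unfolded wrapped Cauchy angle and reflects it into the domain, which is
    exact because the density is the folded Poisson kernel.
    """

    Re: float
    r: float
    theta_src: float
    tag: str = field(default="half_space", init=False, repr=False)
    sampling: str = field(default="inverse_cdf_folded", init=False, repr=False)

    def __post_init__(self):
        if not (self.r > self.Re > 0):
            raise DomainError("require r > Re > 0")
        if not (0.0 <= self.theta_src <= np.pi):
            raise DomainError("theta_src must lie in [0, pi]")

    @property
    def q(self) -> float:
        return self.Re / self.r

    def pdf(self, theta):
        return exit_pdf_half_space(self.r, theta, self.theta_src, self.Re)

    def sample(self, rng: np.random.Generator, size=None):
        u = rng.random(size)
        return _fold_half(self.theta_src + wrapped_cauchy_sample(self.q, u))


def _fold_interval(s, width):
    """Accordion-fold real coordinates into [0, width] (reflections at both ends)."""
    s = np.mod(np.asarray(s, dtype=float), 2.0 * width)
    return np.where(s > width, 2.0 * width - s, s)


@dataclass(frozen=True)
class SemiStripExitPdf:
    """Exit density on the absorbing cross-section of a semi-infinite strip.

    Sampling draws from the straight-wall Cauchy hit density and accordion-
    folds it into the strip, which is exact by the method of images.
    """

    width: float
    y1: float
    y2: float
    tag: str = field(default="semi_strip", init=False, repr=False)
    sampling: str = field(default="inverse_cdf_folded", init=False, repr=False)

    def __post_init__(self):
        if not (self.width > 0 and self.y1 > 0 and 0 <= self.y2 <= self.width):
            raise DomainError("require width > 0, y1 > 0, 0 <= y2 <= width")

    def pdf(self, x2):
        return exit_pdf_semistrip(x2, self.y1, self.y2, self.width)

    def sample(self, rng: np.random.Generator, size=None):
        u = rng.random(size)
        s = self.y2 + self.y1 * np.tan(np.pi * (u - 0.5))
        return _fold_interval(s, self.width)


ExitPdf = Callable  # duck-typed: any of the three classes above


def sample_exit_point(pdf, rng: np.random.Generator, size=None):
    """Draw boundary coordinates from an exit density (seeded RNG contract)."""
    return pdf.sample(rng, size=size)
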