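"""Numba-compiled trajectory loops for the hybrid simulator.

One kernel per geometry.  Each trajectory alternates between

1. exact analytic placement on the inner artificial boundary (inverse-CDF
   sampling of the geometry's exit density, folded where a reflecting wall
   or strip wall is present), and
2. Euler Brownian stepping inside the working region, with segment-crossing
   absorption tests on the windows, specular reflection elsewhere on the
   obstacle, and exact re-injection whenever the outer boundary is crossed.

Step lengths are distance-scaled: the root-mean-square displacement per step
is ``delta0`` (the window-resolving value) near the obstacle and grows like
a quarter of the obstacle distance up to ``delta_cap`` in the bulk, which is
admissible because re-injection from any point outside the inner boundary is
exact regardless of how far the step overshoots the outer boundary.

Kernels return ``(counts, mean_steps, mean_reinjections)``; a negative
``mean_steps`` signals that a trajectory exceeded the re-injection cap.
"""

import math

import numpy as np
from numba import njit

_TWO_PI = 2.0 * math.pi
_SQRT1_2 = 0.7071067811865476


@njit(cache=True)
def _wc_sample(gen, q):
    """Centred wrapped-Cauchy angle with concentration q = Re/r."""
    u = gen.random()
    return 2.0 * math.atan((1.0 - q) / (1.0 + q) * math.tan(math.pi * (u - 0.5)))


@njit(cache=True)
def _fold_half(phi):
    """Fold an angle into [0, pi] (reflection across the boundary axis)."""
    phi = phi % _TWO_PI
    if phi < 0.0:
        phi += _TWO_PI
    if phi > math.pi:
        phi = _TWO_PI - phi
    return phi


@njit(cache=True)
def _fold_interval(s, width):
    """Accordion-fold a real coordinate into [0, width]."""
    s = s % (2.0 * width)
    if s < 0.0:
        s += 2.0 * width
    if s > width:
        s = 2.0 * width - s
    return s


@njit(cache=True)
def _clip_step(d, lo, hi):
    if d < lo:
        return lo
    if d > hi:
        return hi
    return d


@njit(cache=True)
def run_halfplane(n, gen, sx, sy, win_y, half_eps, re, ro, delta0, delta_cap,
                  max_reinj):
    """Two-or-more windows on the boundary line of the half-plane x > 0.

    ``sx`` must be nonnegative (caller mirrors the source into the canonical
    side; window heights are unaffected).  Angles on the injection
    half-circle are measured from the +y boundary axis.
    """
    nw = win_y.size
    counts = np.zeros(nw, np.int64)
    ro2 = ro * ro
    tot_steps = 0.0
    tot_reinj = 0.0
    for _ in range(n):
        r0 = math.hypot(sx, sy)
        if r0 > re:
            phi = _fold_half(math.atan2(sx, sy) + _wc_sample(gen, re / r0))
            x = re * math.sin(phi)
            y = re * math.cos(phi)
        else:
            x = sx
            y = sy
        reinj = 0
        absorbed = -1
        while absorbed < 0:
            sig = _clip_step(0.25 * x, delta0, delta_cap) * _SQRT1_2
            nx = x + sig * gen.standard_normal()
            ny = y + sig * gen.standard_normal()
            tot_steps += 1.0
            if nx <= 0.0:
                denom = x - nx
                if denom > 0.0:
                    yc = y + (x / denom) * (ny - y)
                else:
                    yc = y
                for k in range(nw):
                    if abs(yc - win_y[k]) <= half_eps:
                        absorbed = k
                        break
                if absorbed >= 0:
                    break
                nx = -nx
            else:
                # Brownian-bridge wall touch on a non-crossing step: the true
                # path may still have reached the line; probability
                # exp(-x1 x2 / (D dt)) with D dt = sig^2 / 2.
                ddt = 0.5 * sig * sig
                if x * nx < 28.0 * ddt:
                    if gen.random() < math.exp(-x * nx / ddt):
                        u = x / (x + nx)
                        yt = (y + u * (ny - y)
                              + sig * math.sqrt(u * (1.0 - u)) * gen.standard_normal())
                        for k in range(nw):
                            if abs(yt - win_y[k]) <= half_eps:
                                absorbed = k
                                break
                        if absorbed >= 0:
                            break
            if nx * nx + ny * ny > ro2:
                r = math.hypot(nx, ny)
                phi = _fold_half(math.atan2(nx, ny) + _wc_sample(gen, re / r))
                x = re * math.sin(phi)
                y = re * math.cos(phi)
                reinj += 1
                if reinj > max_reinj:
                    return counts, -1.0, -1.0
            else:
                x = nx
                y = ny
        counts[absorbed] += 1
        tot_reinj += reinj
    return counts, tot_steps / n, tot_reinj / n


@njit(cache=True)
def _resolve_disk_crossing(px, py, nx, ny, R, win_ang, half_arc):
    """Absorb or specularly reflect a step segment against the obstacle disk.

    Returns (absorbed_index, nx, ny); absorbed_index is -1 when the particle
    survives, in which case (nx, ny) is the (possibly reflected) endpoint,
    guaranteed outside the disk.
    """
    nw = win_ang.size
    for _ in range(16):
        dx = nx - px
        dy = ny - py
        a = dx * dx + dy * dy
        if a <= 0.0:
            break
        b = 2.0 * (px * dx + py * dy)
        c = px * px + py * py - R * R
        disc = b * b - 4.0 * a * c
        if disc <= 0.0:
            break
        sq = math.sqrt(disc)
        t = (-b - sq) / (2.0 * a)
        if t < -1e-12 or t > 1.0:
            break
        if t < 0.0:
            t = 0.0
        hx = px + t * dx
        hy = py + t * dy
        ang = math.atan2(hy, hx)
        for k in range(nw):
            dang = ang - win_ang[k]
            while dang > math.pi:
                dang -= _TWO_PI
            while dang < -math.pi:
                dang += _TWO_PI
            if abs(dang) <= half_arc:
                return k, hx, hy
        # specular reflection of the segment remainder about the tangent
        nrmx = hx / R
        nrmy = hy / R
        vx = nx - hx
        vy = ny - hy
        dot = vx * nrmx + vy * nrmy
        vx -= 2.0 * dot * nrmx
        vy -= 2.0 * dot * nrmy
        px = hx * (1.0 + 1e-12)
        py = hy * (1.0 + 1e-12)
        nx = px + vx
        ny = py + vy
    rn = math.hypot(nx, ny)
    if rn < R:
        s = R * (1.0 + 1e-9) / rn
        nx *= s
        ny *= s
    return -1, nx, ny


@njit(cache=True)
def _disk_touch(gen, x, y, nx, ny, R, sig, win_ang, half_arc):
    """Brownian-bridge touch test against the obstacle circle.

    Flat-wall approximation in the obstacle distance (valid for steps short
    against the radius): touch probability exp(-d1 d2 / (D dt)); the touch
    angle is the segment interpolation at the expected touch time plus a
    tangential bridge fluctuation.  Returns the absorbed window index or -1.
    """
    d1 = math.hypot(x, y) - R
    d2 = math.hypot(nx, ny) - R
    if d1 < 0.0:
        d1 = 0.0
    if d2 < 0.0:
        d2 = 0.0
    ddt = 0.5 * sig * sig
    if d1 * d2 >= 28.0 * ddt:
        return -1
    if gen.random() >= math.exp(-d1 * d2 / ddt):
        return -1
    u = 0.5 if d1 + d2 <= 0.0 else d1 / (d1 + d2)
    tx = x + u * (nx - x)
    ty = y + u * (ny - y)
    ang = (math.atan2(ty, tx)
           + sig * math.sqrt(u * (1.0 - u)) / R * gen.standard_normal())
    for k in range(win_ang.size):
        dang = ang - win_ang[k]
        while dang > math.pi:
            dang -= _TWO_PI
        while dang < -math.pi:
            dang += _TWO_PI
        if abs(dang) <= half_arc:
            return k
    return -1


@njit(cache=True)
def run_disk(n, gen, sx, sy, win_ang, half_arc, R, re, ro, delta0, delta_cap,
             max_reinj):
    """Windows as arcs on the obstacle disk |x| = R in free space."""
    nw = win_ang.size
    counts = np.zeros(nw, np.int64)
    ro2 = ro * ro
    tot_steps = 0.0
    tot_reinj = 0.0
    for _ in range(n):
        r0 = math.hypot(sx, sy)
        if r0 > re:
            th = math.atan2(sy, sx) + _wc_sample(gen, re / r0)
            x = re * math.cos(th)
            y = re * math.sin(th)
        else:
            x = sx
            y = sy
        reinj = 0
        absorbed = -1
        while absorbed < 0:
            r = math.hypot(x, y)
            sig = _clip_step(0.25 * (r - R), delta0, delta_cap) * _SQRT1_2
            nx = x + sig * gen.standard_normal()
            ny = y + sig * gen.standard_normal()
            tot_steps += 1.0
            absorbed, nx, ny = _resolve_disk_crossing(x, y, nx, ny, R,
                                                      win_ang, half_arc)
            if absorbed >= 0:
                break
            absorbed = _disk_touch(gen, x, y, nx, ny, R, sig, win_ang, half_arc)
            if absorbed >= 0:
                break
            if nx * nx + ny * ny > ro2:
                rn = math.hypot(nx, ny)
                th = math.atan2(ny, nx) + _wc_sample(gen, re / rn)
                x = re * math.cos(th)
                y = re * math.sin(th)
                reinj += 1
                if reinj > max_reinj:
                    return counts, -1.0, -1.0
            else:
                x = nx
                y = ny
        counts[absorbed] += 1
        tot_reinj += reinj
    return counts, tot_steps / n, tot_reinj / n


@njit(cache=True)
def run_strip(n, gen, sx, sy, win_ang, half_arc, R, a, de, do, delta0,
              delta_cap, max_reinj):
    """Windows on a disk centred in the strip |y| < a with reflecting walls.

    Injection and re-injection place the particle on the cross-section
    ``|x| = de`` (same side as the source / escape point) via the exact
    semi-strip exit density; escape occurs at ``|x| > do``.  Wall collisions
    are handled by exact Gaussian folding.
    """
    nw = win_ang.size
    counts = np.zeros(nw, np.int64)
    W = 2.0 * a
    tot_steps = 0.0
    tot_reinj = 0.0
    for _ in range(n):
        if abs(sx) > de:
            side = 1.0 if sx > 0.0 else -1.0
            y1 = abs(sx) - de
            u = gen.random()
            x2 = _fold_interval(sy + a + y1 * math.tan(math.pi * (u - 0.5)), W)
            x = side * de
            y = x2 - a
        else:
            x = sx
            y = sy
        reinj = 0
        absorbed = -1
        while absorbed < 0:
            r = math.hypot(x, y)
            sig = _clip_step(0.25 * (r - R), delta0, delta_cap) * _SQRT1_2
            nx = x + sig * gen.standard_normal()
            ny = y + sig * gen.standard_normal()
            tot_steps += 1.0
            # reflecting walls: exact folding of the Gaussian endpoint
            while ny > a or ny < -a:
                if ny > a:
                    ny = 2.0 * a - ny
                else:
                    ny = -2.0 * a - ny
            absorbed, nx, ny = _resolve_disk_crossing(x, y, nx, ny, R,
                                                      win_ang, half_arc)
            if absorbed >= 0:
                break
            absorbed = _disk_touch(gen, x, y, nx, ny, R, sig, win_ang, half_arc)
            if absorbed >= 0:
                break
            while ny > a or ny < -a:
                if ny > a:
                    ny = 2.0 * a - ny
                else:
                    ny = -2.0 * a - ny
            if abs(nx) > do:
                side = 1.0 if nx > 0.0 else -1.0
                y1 = abs(nx) - de
                u = gen.random()
                x2 = _fold_interval(ny + a + y1 * math.tan(math.pi * (u - 0.5)), W)
                x = side * de
                y = x2 - a
                reinj += 1
                if reinj > max_reinj:
                    return counts, -1.0, -1.0
            else:
                x = nx
                y = ny
        counts[absorbed] += 1
        tot_reinj += reinj
    return counts, tot_steps / n, tot_reinj / n
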