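"""Continuous 2-D torus geometry.

All agents live on a square periodic field of side ``L`` (meters); every
distance and direction in the simulator is the shortest-path ("torus")
version, so no border effects exist anywhere.

Headings follow a compass convention: 0 degrees points along +y
("north") and angles increase clockwise, so 90 degrees points along +x.
All public functions are numba-compiled scalar kernels; they are cheap
to call from Python and are composed inside the jitted simulation loop.
"""

import math

import numpy as np
from numba import njit

__all__ = [
    "wrap_coord",
    "wrap",
    "torus_delta",
    "torus_distance",
    "bearing",
    "angle_difference",
    "within_view",
    "displace",
]


@njit(cache=True)
def wrap_coord(x, L):
    """Map a single raw coordinate into [0, L) by modular arithmetic."""
    return x % L


@njit(cache=True)
def wrap(x, y, L):
    """Wrap a raw coordinate pair onto the torus.

    Raises ValueError for non-finite coordinates or a non-positive
    field length.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("non-finite coordinate")
    if L <= 0.0:
        raise ValueError("field length must be positive")
    return x % L, y % L


@njit(cache=True)
def torus_delta(a, b, L):
    """Shortest signed displacement from a to b along one axis.

    The result lies in [-L/2, L/2).
    """
    return (b - a + 0.5 * L) % L - 0.5 * L


@njit(cache=True)
def torus_distance(ax, ay, bx, by, L):
    """Shortest-path Euclidean distance between two wrapped points."""
    return math.hypot(torus_delta(ax, bx, L), torus_delta(ay, by, L))


@njit(cache=True)
def bearing(ax, ay, bx, by, L):
    """Compass bearing of the shortest torus displacement a -> b.

    Returns NaN for coincident points (the direction is undefined and
    the caller must substitute a uniform random heading).
    """
    dx = torus_delta(ax, bx, L)
    dy = torus_delta(ay, by, L)
    if dx == 0.0 and dy == 0.0:
        return np.nan
    return math.degrees(math.atan2(dx, dy)) % 360.0


@njit(cache=True)
def angle_difference(a, b):
    """Absolute circular difference between two angles, in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


@njit(cache=True)
def within_view(ox, oy, observer_heading, tx, ty, view_angle, max_range, L):
    """Range-and-cone visibility test.

    True iff the target is within ``max_range`` (torus distance) and the
    bearing to it deviates from the observer's heading by at most
    ``view_angle / 2`` (boundary inclusive, so ``view_angle = 360``
    reduces to a pure range test).  A coincident target is visible.
    """
    if torus_distance(ox, oy, tx, ty, L) > max_range:
        return False
    if view_angle >= 360.0:
        return True
    b = bearing(ox, oy, tx, ty, L)
    if np.isnan(b):
        return True
    return angle_difference(b, observer_heading) <= 0.5 * view_angle


@njit(cache=True)
def displace(x, y, heading, d, L):
    """Move a wrapped point d meters along a compass heading and rewrap."""
    r = math.radians(heading)
    return (x + d * math.sin(r)) % L, (y + d * math.cos(r)) % L
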