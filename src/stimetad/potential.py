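"""The two-dimensional Wolfe–Quapp model potential.

The Wolfe–Quapp surface is a quartic two-state potential widely used to
benchmark enhanced-sampling and rate-inference methods, because its two
wells are connected by a diagonal channel that a single Cartesian
coordinate describes only imperfectly — making it a natural testbed for
good versus suboptimal collective variables.

We work with the "modified" Wolfe–Quapp quartic

    U(u, v) = u^4 + v^4 - 2 u^2 - 4 v^2 + u v - 0.3 u - 0.1 v

expressed in a lab frame obtained by a fixed rotation and isotropic
dilation chosen such that the global minimum sits at
(x, y) = (1.564, -1.334) nm and the second, shallower minimum falls
inside the region x < -1.4 nm ∧ y > 1.0 nm used as the first-passage
target.  Energies are in units of k_B T (at the simulation temperature)
and distances in nm.  The barrier from the global minimum to the saddle
is ~6.78 k_B T, which at T = 300 K, m = 40 a.u. and friction
0.01 fs^-1 puts the unbiased mean first-passage time in the
100-ns range.

A ``scale`` factor multiplies the whole surface; ``scale < 1`` produces a
depth-reduced variant with proportionally smaller barriers, convenient for
brute-force validation runs where the full barrier would make unbiased
trajectories prohibitively long.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from numba import njit


class Position2D(NamedTuple):
    """A point in the 2D lab frame, in nm."""

    x: float
    y: float


# Canonical-frame stationary points of U (root-polished to double precision).
_CANON_GLOBAL_MIN = (1.1740560572097627, -1.4770870591140515)
_CANON_SECOND_MIN = (-1.1241017554091357, 1.4852742781258919)
_CANON_SADDLE = (-0.08119930548385872, -0.022655727573970965)

#: Global minimum of the lab-frame potential; also the standard start point.
START = Position2D(1.564, -1.334)

# Lab frame = canonical frame rotated by phi and dilated by s, with (phi, s)
# fixed by requiring the canonical global minimum to map exactly onto START.
_S = math.hypot(*START) / math.hypot(*_CANON_GLOBAL_MIN)
_PHI = math.atan2(START.y, START.x) - math.atan2(
    _CANON_GLOBAL_MIN[1], _CANON_GLOBAL_MIN[0]
)
# A maps lab -> canonical coordinates: A = R(-phi) / s.
_A00 = math.cos(_PHI) / _S
_A01 = math.sin(_PHI) / _S
_A10 = -math.sin(_PHI) / _S
_A11 = math.cos(_PHI) / _S


def _to_lab(uv: tuple[float, float]) -> Position2D:
    u, v = uv
    det = _A00 * _A11 - _A01 * _A10
    return Position2D((_A11 * u - _A01 * v) / det, (_A00 * v - _A10 * u) / det)


#: Second (shallower) local minimum, inside the first-passage target region.
SECOND_MIN = _to_lab(_CANON_SECOND_MIN)
#: Saddle point between the two wells.
SADDLE = _to_lab(_CANON_SADDLE)

GLOBAL_MIN = START


@njit(cache=True)
def _canon_energy(u: float, v: float) -> float:
    return u**4 + v**4 - 2.0 * u * u - 4.0 * v * v + u * v - 0.3 * u - 0.1 * v


@njit(cache=True)
def wq_energy(x: float, y: float, scale: float = 1.0) -> float:
    """Potential energy in k_B T at lab-frame point (x, y) nm."""
    u = _A00 * x + _A01 * y
    v = _A10 * x + _A11 * y
    return scale * _canon_energy(u, v)


@njit(cache=True)
def wq_gradient(x: float, y: float, scale: float = 1.0) -> tuple[float, float]:
    """Gradient dV/d(x, y) in k_B T / nm (chain rule through the frame map)."""
    u = _A00 * x + _A01 * y
    v = _A10 * x + _A11 * y
    gu = 4.0 * u**3 - 4.0 * u + v - 0.3
    gv = 4.0 * v**3 - 8.0 * v + u - 0.1
    gx = _A00 * gu + _A10 * gv
    gy = _A01 * gu + _A11 * gv
    return scale * gx, scale * gy


def potential_energy(p: Position2D, scale: float = 1.0) -> float:
    """Wolfe–Quapp energy (k_B T) at a lab-frame position."""
    return float(wq_energy(p[0], p[1], scale))


def potential_gradient(p: Position2D, scale: float = 1.0) -> np.ndarray:
    """Analytic gradient (k_B T / nm) of the lab-frame potential."""
    gx, gy = wq_gradient(p[0], p[1], scale)
    return np.array([gx, gy])


#: Barrier height (k_B T) from the global minimum to the saddle.
BARRIER_KBT = potential_energy(SADDLE) - potential_energy(GLOBAL_MIN)


def good_cv_direction() -> np.ndarray:
    """Unit vector of the reference ("good") collective variable.

    Points from the global minimum toward the second minimum, i.e. along the
    interwell axis, so the CV cleanly separates the two metastable states.
    Projections onto rotations of this vector define the family of
    progressively worse CVs.
    """
    d = np.array([SECOND_MIN.x - GLOBAL_MIN.x, SECOND_MIN.y - GLOBAL_MIN.y])
    return d / np.linalg.norm(d)
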