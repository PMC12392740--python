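"""Implicit spherical condensate: potential, force, and volume bookkeeping.

The condensate is a spherical region of radius ``R_c`` pinned at the box
center.  Inside, a subunit gains a flat energy ``-eps_c``; outside, the
potential relaxes to zero over a length ``1/alpha_C``:

    u_c(r) = -eps_c                                          r <  R_c
    u_c(r) = -eps_c (2 e^{-a x} - e^{-2 a x}),  x = r - R_c  r >= R_c

with ``a = alpha_C``.  The exterior profile is a (shifted) Morse tail: it
is continuous at ``R_c``, monotonically rises to zero, and its gradient is
bounded by ``alpha_C * eps_c / 2``, which keeps forces at the boundary
well-behaved.  The field couples once per subunit at its center of mass,
so an n-subunit cluster gains ``n * eps_c`` by partitioning into the
condensate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CondensateSpec", "condensate_potential", "condensate_force", "volumes"]

DEFAULT_ALPHA_C = 10.0  # inverse length, in units of 1/l0 (or 1/sigma)


class GeometryError(ValueError):
    """Condensate does not fit the requested box."""


@dataclass(frozen=True)
class CondensateSpec:
    """The implicit condensate field.

    Parameters
    ----------
    R_c:
        Condensate radius (length units).
    eps_c:
        Well depth (kT); 0 disables the field entirely.
    alpha_C:
        Exterior decay rate (inverse length); should satisfy
        ``alpha_C * R_c >> 1`` so the interface is thin compared to the
        droplet.
    center:
        Field center; the default pins the condensate at the box origin.
    """

    R_c: float
    eps_c: float = 0.0
    alpha_C: float = DEFAULT_ALPHA_C
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.R_c <= 0:
            raise ValueError("R_c must be positive")
        if self.alpha_C <= 0:
            raise ValueError("alpha_C must be positive")
        if self.eps_c < 0:
            raise ValueError("eps_c must be non-negative")
        if self.alpha_C * self.R_c < 10:
            warnings.warn(
                "alpha_C * R_c < 10: condensate interface is not thin "
                "compared to the droplet radius",
                stacklevel=2,
            )

    @staticmethod
    def from_volume_ratio(V_r: float, L: float, eps_c: float = 0.0,
                          alpha_C: float = DEFAULT_ALPHA_C) -> "CondensateSpec":
        """Condensate with volume ratio ``V_r = V_c / V_bg`` in a box of
        edge ``L`` (so ``V_c = L^3 V_r / (1 + V_r)``)."""
        if V_r <= 0:
            raise ValueError("V_r must be positive")
        V_c = L**3 * V_r / (1.0 + V_r)
        R_c = (3.0 * V_c / (4.0 * math.pi)) ** (1.0 / 3.0)
        return CondensateSpec(R_c=R_c, eps_c=eps_c, alpha_C=alpha_C)


def condensate_potential(spec: CondensateSpec, r) -> float | np.ndarray:
    """Field energy at distance ``r`` from the condensate center.

    Vectorized over ``r``; raises for negative distances.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("distance must be non-negative")
    x = np.maximum(r_arr - spec.R_c, 0.0)
    e = np.exp(-spec.alpha_C * x)
    u = -spec.eps_c * (2.0 * e - e * e)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(u)
    return u


def condensate_force(spec: CondensateSpec, position: np.ndarray) -> np.ndarray:
    """Radial force ``-du_c/dr r_hat`` at a world position (zero inside)."""
    p = np.asarray(position, dtype=float) - np.asarray(spec.center)
    r = float(np.linalg.norm(p))
    if r <= spec.R_c or r == 0.0:
        return np.zeros(3)
    x = r - spec.R_c
    e = math.exp(-spec.alpha_C * x)
    dudr = 2.0 * spec.alpha_C * spec.eps_c * (e - e * e)  # >= 0
    return -dudr * p / r


def volumes(spec: CondensateSpec, L: float) -> tuple[float, float, float]:
    """Condensate, background, and ratio volumes ``(V_c, V_bg, V_r)`` for a
    cubic box of edge ``L``.  Requires the droplet to fit in the box."""
    if 2.0 * spec.R_c >= L:
        raise GeometryError("condensate diameter exceeds box edge")
    V_c = 4.0 / 3.0 * math.pi * spec.R_c**3
    V_bg = L**3 - V_c
    return V_c, V_bg, V_c / V_bg
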