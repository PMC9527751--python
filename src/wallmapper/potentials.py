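"""Lennard-Jones 12-6 and 9-3 potentials and the combining rules used to
map atomistic surfaces onto structureless walls.

Units are fixed package-wide: energies in kcal/mol, lengths in nm.

The 9-3 wall form used throughout is the one implemented by common MD
engines for flat walls,

    E(z) = eps * [ (2/15) (sigma/z)**9 - (sigma/z)**3 ],

which is the 12-6 potential integrated over a uniform half-space of
particles.  Its zero crossing sits at (2/15)**(1/6) * sigma ~= 0.715 sigma
rather than at sigma, and its well is ~5% deeper than eps.  Both facts
drive the adjusted sigma combining rule below: cross sigma parameters are
obtained by averaging the *zero-crossing distances* (contact distances) of
the two sides, not the raw sigma parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LJ93_ZERO_FACTOR",
    "LJPair",
    "WallParams",
    "CrossParams",
    "lj126_energy",
    "lj93_energy",
    "lj93_force",
    "lj93_characteristics",
    "combine_sigma126",
    "combine_sigma93",
    "combine_epsilon",
]

#: (2/15)**(1/6): the 9-3 zero crossing in units of sigma (~0.71506).
LJ93_ZERO_FACTOR: float = (2.0 / 15.0) ** (1.0 / 6.0)


@dataclass(frozen=True)
class LJPair:
    """Like-like LJ parameters of one atom type.

    Parameters
    ----------
    epsilon : float
        Well depth, kcal/mol.  Must be >= 0 (zero is allowed for e.g.
        water hydrogens, which then cannot be used as probes).
    sigma : float
        Length parameter, nm.  Must be > 0.
    """

    epsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.epsilon >= 0.0):
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class WallParams:
    """Fitted wall parameters (eps_ww, sigma_ww) describing a material.

    sigma_ww lives on the 12-6 contact-distance scale: for an ideally flat
    single-element surface the parameterization returns the sigma of the
    constituent atoms.
    """

    eps_ww: float
    sigma_ww: float
    material_label: str = ""

    def __post_init__(self) -> None:
        if not (self.eps_ww >= 0.0):
            raise ValueError(f"eps_ww must be >= 0, got {self.eps_ww}")
        if not (self.sigma_ww > 0.0):
            raise ValueError(f"sigma_ww must be > 0, got {self.sigma_ww}")

    @property
    def zero_crossing(self) -> float:
        """z at which the 9-3 wall potential crosses zero, nm."""
        return LJ93_ZERO_FACTOR * self.sigma_ww


@dataclass(frozen=True)
class CrossParams:
    """Cross atom-wall 9-3 parameters with standard errors."""

    eps_iw: float
    sigma_iw: float
    eps_iw_se: float = 0.0
    sigma_iw_se: float = 0.0

    def __post_init__(self) -> None:
        if not (self.eps_iw >= 0.0):
            raise ValueError(f"eps_iw must be >= 0, got {self.eps_iw}")
        if not (self.sigma_iw > 0.0):
            raise ValueError(f"sigma_iw must be > 0, got {self.sigma_iw}")
        if self.eps_iw_se < 0.0 or self.sigma_iw_se < 0.0:
            raise ValueError("standard errors must be >= 0")


def _check_positive_distance(value, name: str):
    import numpy as np

    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError(f"{name} must be > 0")
    return arr


def lj126_energy(r, p: LJPair):
    """Standard 12-6 pair energy 4*eps*[(sigma/r)^12 - (sigma/r)^6].

    ``r`` may be a scalar or array of distances (nm); returns kcal/mol.
    Zero at r = sigma, minimum -eps at r = 2**(1/6) sigma.
    """
    r = _check_positive_distance(r, "r")
    x6 = (p.sigma / r) ** 6
    out = 4.0 * p.epsilon * (x6 * x6 - x6)
    return float(out) if out.ndim == 0 else out


def lj93_energy(z, p: LJPair):
    """9-3 wall energy eps*[(2/15)(sigma/z)^9 - (sigma/z)^3] at height z (nm)."""
    z = _check_positive_distance(z, "z")
    x3 = (p.sigma / z) ** 3
    out = p.epsilon * ((2.0 / 15.0) * x3 ** 3 - x3)
    return float(out) if out.ndim == 0 else out


def lj93_force(z, p: LJPair):
    """-dE/dz of the 9-3 wall potential, kcal/mol/nm (positive = repulsive)."""
    z = _check_positive_distance(z, "z")
    x3 = (p.sigma / z) ** 3
    # dE/dz = eps * [ -9*(2/15) sigma^9 z^-10 + 3 sigma^3 z^-4 ]
    out = p.epsilon * (9.0 * (2.0 / 15.0) * x3 ** 3 - 3.0 * x3) / z
    return float(out) if out.ndim == 0 else out


def lj93_characteristics(p: LJPair) -> dict:
    """Analytic characteristics of the 9-3 wall potential.

    Returns ``zero_crossing`` ((2/15)^(1/6) sigma), ``z_min`` (stationary
    point, (2/5)^(1/6) sigma) and ``depth`` (|E(z_min)|), all from closed
    forms of the 9-3 expression.
    """
    zero_crossing = LJ93_ZERO_FACTOR * p.sigma
    # stationary point: d/dz = 0  ->  (sigma/z)^6 = 15/(9*2/15)... solve:
    # 9*(2/15) x^9/z = 3 x^3/z  ->  x^6 = 5/2  ->  z = (2/5)^(1/6) sigma
    z_min = (2.0 / 5.0) ** (1.0 / 6.0) * p.sigma
    depth = -lj93_energy(z_min, p) if p.epsilon > 0 else 0.0
    return {"zero_crossing": zero_crossing, "z_min": z_min, "depth": depth}


def combine_sigma126(sigma_a: float, sigma_b: float) -> float:
    """Lorentz arithmetic-mean rule for 12-6 pair sigmas (nm)."""
    if sigma_a <= 0.0 or sigma_b <= 0.0:
        raise ValueError("sigma values must be > 0")
    return 0.5 * (sigma_a + sigma_b)


def combine_sigma93(sigma_ii: float, sigma_ww: float) -> float:
    """Adjusted arithmetic-mean rule for the atom-wall 9-3 sigma.

    Because the 9-3 potential crosses zero at 0.715 sigma while the 12-6
    crosses at sigma, the mean producing the zero crossing of the cross
    potential is taken with the atom's sigma rescaled to the 9-3 crossing
    position:

        0.715 sigma_iw = (0.715 sigma_ii + sigma_ww) / 2,

    i.e. ``sigma_iw = (f*sigma_ii + sigma_ww) / (2 f)`` with
    f = (2/15)**(1/6).  Strictly increasing in each argument and, under
    this convention (atom sigma on the 12-6 scale, wall sigma on the
    crossing scale), symmetric in the two contact lengths being averaged.
    """
    if sigma_ii <= 0.0 or sigma_ww <= 0.0:
        raise ValueError("sigma values must be > 0")
    return 0.5 * (LJ93_ZERO_FACTOR * sigma_ii + sigma_ww) / LJ93_ZERO_FACTOR


def combine_epsilon(eps_ii: float, eps_ww: float) -> float:
    """Berthelot geometric-mean rule eps_iw = sqrt(eps_ii * eps_ww)."""
    if eps_ii < 0.0 or eps_ww < 0.0:
        raise ValueError("epsilon values must be >= 0")
    return math.sqrt(eps_ii * eps_ww)
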