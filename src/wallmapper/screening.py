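"""Asymptotic-regression screening model linking wall parameters to
interfacial solute density.

The model is

    rho_int(eps_ww, sigma_ww) = a - (a - rho_vac) * exp(-c * eps_ww * sigma_ww)

with ``a`` the maximum (plateau) interfacial density for the film size the
grid was simulated at, ``rho_vac`` the interfacial density of the film in
contact with vacuum (the eps -> 0 limit, kept as a free fitted parameter),
and ``c`` the rate at which density rises with wall strength.  Densities
are g/cm^3, eps_ww kcal/mol, sigma_ww nm and c mol kcal^-1 nm^-1.

The canonical parameter set fitted to the 18-point (eps_ww, sigma_ww)
simulation grid for a 3.1 nm, 296.7 g/kg glycine film is exposed as
:data:`CANONICAL_MODEL`; with it the heptane/tridecane/graphite wall
parameters of :data:`wallmapper.data.MATERIAL_WALLS` predict interfacial
densities of 0.45, 0.52 and 0.63 g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .potentials import WallParams

__all__ = [
    "ScreeningModel",
    "DensityGridPoint",
    "CANONICAL_MODEL",
    "predict_rho_int",
    "fit_screening_model",
]


@dataclass(frozen=True)
class ScreeningModel:
    """Parameters of the asymptotic regression model."""

    a: float  # plateau interfacial density, g/cm^3
    rho_vac: float  # vacuum-contact interfacial density, g/cm^3
    c: float  # rise rate, mol kcal^-1 nm^-1

    def __post_init__(self) -> None:
        if not (self.a > self.rho_vac):
            raise ValueError("require a > rho_vac")
        if self.rho_vac < 0.0:
            raise ValueError("require rho_vac >= 0")
        if not (self.c > 0.0):
            raise ValueError("require c > 0")


@dataclass(frozen=True)
class DensityGridPoint:
    """One simulated (eps_ww, sigma_ww, rho_int) grid point."""

    eps_ww: float
    sigma_ww: float
    rho_int: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.eps_ww, self.sigma_ww, self.rho_int]).all():
            raise ValueError("grid point values must be finite")
        if self.rho_int < 0.0:
            raise ValueError("rho_int must be >= 0")


#: Canonical fit to the wall-parameter simulation grid (3.1 nm, 296.7 g/kg
#: film): a = 0.63 g/cm^3, rho_vac = 0.08 g/cm^3, c = 1.1 mol kcal^-1 nm^-1
#: (equivalently 0.11 per kcal/mol per angstrom).
CANONICAL_MODEL = ScreeningModel(a=0.63, rho_vac=0.08, c=1.1)


def predict_rho_int(model: ScreeningModel, wall: WallParams) -> float:
    """Interfacial solute density (g/cm^3) predicted for a wall.

    Bounded in [rho_vac, a); monotone non-decreasing in eps_ww and
    sigma_ww; tends to rho_vac as eps_ww -> 0.
    """
    x = model.c * wall.eps_ww * wall.sigma_ww
    return model.a - (model.a - model.rho_vac) * float(np.exp(-x))


def _model_fn(X, a, rho_vac, c):
    eps, sigma = X
    return a - (a - rho_vac) * np.exp(-c * eps * sigma)


def fit_screening_model(
    points: Iterable[DensityGridPoint] | Sequence[tuple],
) -> tuple[ScreeningModel, dict]:
    """Joint nonlinear least-squares fit of the model to grid points.

    Accepts DensityGridPoint instances or plain (eps_ww, sigma_ww,
    rho_int) triples.  Requires >= 4 points spanning at least two distinct
    eps_ww values.  Returns the fitted model plus diagnostics (residual
    norm, per-parameter standard errors).
    """
    pts = [
        p if isinstance(p, DensityGridPoint) else DensityGridPoint(*p)
        for p in points
    ]
    if len(pts) < 4:
        raise ValueError(f"need >= 4 grid points, got {len(pts)}")
    eps = np.array([p.eps_ww for p in pts])
    sigma = np.array([p.sigma_ww for p in pts])
    rho = np.array([p.rho_int for p in pts])
    if np.unique(eps).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct eps_ww values")

    a0 = float(rho.max())
    r0 = max(float(rho.min()), 0.0)
    c0 = 1.0 / max(float(np.mean(eps * sigma)), 1e-6)
    try:
        popt, pcov = curve_fit(
            _model_fn,
            (eps, sigma),
            rho,
            p0=(a0 * 1.05 + 1e-3, r0 * 0.95, c0),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(
            f"screening-model fit did not converge (initial guess "
            f"a={a0:.3g}, rho_vac={r0:.3g}, c={c0:.3g})"
        ) from exc
    a, rho_vac, c = (float(v) for v in popt)
    resid = rho - _model_fn((eps, sigma), *popt)
    perr = np.sqrt(np.diag(pcov))
    model = ScreeningModel(a=a, rho_vac=max(rho_vac, 0.0), c=c)
    diagnostics = {
        "residual_norm": float(np.linalg.norm(resid)),
        "stderr": {"a": float(perr[0]), "rho_vac": float(perr[1]), "c": float(perr[2])},
        "n_points": len(pts),
    }
    return model, diagnostics
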