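"""Map an atomistic slab onto 9-3 wall parameters.

The procedure: place a probe atom at height z above the surface plane,
sum its 12-6 interactions with every slab atom (with lateral periodic
images added shell by shell until converged), scan z to map the
potential-energy curve, fit the 9-3 wall form to the curve, repeat on a
6 x 6 lateral grid of sites spanning one periodic cell and average, then
regress the combining rules across a set of probe atom types to extract
the material's (eps_ww, sigma_ww).

The probe sums are open lattice sums converged to an explicit tolerance
rather than truncated at a fixed pair cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .potentials import (
    LJ93_ZERO_FACTOR,
    CrossParams,
    LJPair,
    WallParams,
)
from .slab import Slab

__all__ = [
    "PotentialCurve",
    "ParameterizationResult",
    "probe_curve",
    "fit_lj93",
    "parameterize_probe",
    "derive_wall_params",
    "parameterize_surface",
]


@dataclass
class PotentialCurve:
    """z-scanned probe-surface energy at one lateral site.

    z_grid is measured from the slab surface plane (nm, strictly
    increasing); energy in kcal/mol.
    """

    z_grid: np.ndarray
    energy: np.ndarray
    xy_site: tuple[float, float]

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.z_grid.ndim != 1 or np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        if not np.isfinite(self.energy).all():
            raise ValueError("energies must be finite")


@dataclass
class ParameterizationResult:
    """Full surface parameterization: per-probe cross parameters and the
    regressed wall parameters, with fit diagnostics."""

    per_probe: dict[str, CrossParams]
    wall: WallParams
    fit_diagnostics: dict = field(default_factory=dict)


def _reduced_slab_arrays(slab: Slab):
    """Fold the slab to its primitive lateral cell when known.

    Returns (xy (N,2), z (N,), eps (N,), sigma (N,), cell) where cell is
    the lateral period used for image sums.  Folding wraps atoms into the
    primitive cell and removes the exact duplicates produced by lateral
    replication of a periodic structure.
    """
    xy = slab.positions[:, :2]
    z = slab.positions[:, 2]
    eps = np.array([slab.lj_table[t].epsilon for t in slab.type_labels])
    sig = np.array([slab.lj_table[t].sigma for t in slab.type_labels])
    cell = slab.cell
    if slab.primitive_cell is not None:
        px, py = slab.primitive_cell
        nx, ny = slab.cell[0] / px, slab.cell[1] / py
        if abs(nx - round(nx)) < 1e-9 and abs(ny - round(ny)) < 1e-9:
            wrapped = np.column_stack([xy[:, 0] % px, xy[:, 1] % py])
            key = np.round(
                np.column_stack([wrapped, z, eps, sig]), 6
            )
            _, idx = np.unique(key, axis=0, return_index=True)
            expected = len(xy) / (round(nx) * round(ny))
            if abs(len(idx) - expected) / expected < 0.01:
                return wrapped[idx], z[idx], eps[idx], sig[idx], (px, py)
    return xy, z, eps, sig, cell


def probe_curve(
    slab: Slab,
    probe: LJPair,
    xy: tuple[float, float],
    z_range: tuple[float, float] = (0.1, 1.5),
    z_step: float = 0.01,
    image_tol: float = 1e-4,
    max_shells: int = 200,
) -> PotentialCurve:
    """Scan the total probe-slab 12-6 energy along z at one lateral site.

    z is measured from ``slab.surface_z``.  Cross pair parameters use the
    arithmetic-mean sigma and geometric-mean epsilon rules.  Lateral
    periodic images are added in square shells until a full shell changes
    no grid energy by more than ``image_tol`` kcal/mol.
    """
    if z_range[0] <= 0 or z_range[1] <= z_range[0]:
        raise ValueError("z_range must be positive with z_max > z_min")
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    if probe.epsilon == 0.0:
        raise ValueError(
            "probe has zero LJ epsilon and no dispersion interaction; "
            "it cannot be used for parameterization"
        )

    axy, az, aeps, asig, cell = _reduced_slab_arrays(slab)
    n_z = int(round((z_range[1] - z_range[0]) / z_step)) + 1
    z_grid = z_range[0] + z_step * np.arange(n_z)
    z_abs = slab.surface_z + z_grid

    if z_grid[0] + slab.surface_z <= az.max():
        raise ValueError("probe scan starts inside the slab")

    eps_pair = np.sqrt(aeps * probe.epsilon)
    sig_pair = 0.5 * (asig + probe.sigma)
    c12 = 4.0 * eps_pair * sig_pair ** 12
    c6 = 4.0 * eps_pair * sig_pair ** 6

    dz2 = (az[:, None] - z_abs[None, :]) ** 2  # (N, M)
    energy = np.zeros(n_z)

    def shell_energy(shell: int) -> np.ndarray:
        if shell == 0:
            offsets = np.array([[0.0, 0.0]])
        else:
            idx = []
            for i in range(-shell, shell + 1):
                for j in range(-shell, shell + 1):
                    if max(abs(i), abs(j)) == shell:
                        idx.append((i, j))
            offsets = np.asarray(idx, dtype=float)
        offsets = offsets * [cell[0], cell[1]]
        total = np.zeros(n_z)
        for off in offsets:
            s2 = (axy[:, 0] + off[0] - xy[0]) ** 2 + (
                axy[:, 1] + off[1] - xy[1]
            ) ** 2
            r2 = s2[:, None] + dz2
            inv6 = 1.0 / r2 ** 3
            total += np.sum(inv6 * (c12[:, None] * inv6 - c6[:, None]), axis=0)
        return total

    energy += shell_energy(0)
    converged = False
    for shell in range(1, max_shells + 1):
        delta = shell_energy(shell)
        energy += delta
        if np.max(np.abs(delta)) < image_tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"lateral image sum did not converge within {max_shells} shells "
            f"(cell={cell}, last shell max |dU| = {np.max(np.abs(delta)):.2e})"
        )
    return PotentialCurve(z_grid=z_grid, energy=energy, xy_site=tuple(xy))


def _lj93(z, eps, sigma):
    x3 = (sigma / z) ** 3
    return eps * ((2.0 / 15.0) * x3 ** 3 - x3)


def fit_lj93(
    curve: PotentialCurve,
    tail_cut: float = 1e-4,
) -> tuple[CrossParams, dict]:
    """Nonlinear least-squares fit of the 9-3 wall form to a scanned curve.

    The fitting window runs from the repulsive shoulder (first z where the
    energy falls below +|well depth|) out to where the magnitude of the
    energy drops below ``tail_cut`` kcal/mol (or the end of the scan),
    with uniform weights.  Initial guesses: eps from the well depth, sigma
    from the zero crossing divided by 0.715.

    Returns the fitted cross parameters (standard errors zero here; they
    come from site-to-site averaging) and diagnostics including the RMS
    residual over the window.
    """
    z, u = curve.z_grid, curve.energy
    umin = float(u.min())
    if umin >= 0.0:
        raise ValueError("curve has no attractive well; cannot fit 9-3 form")
    eps0 = -umin

    inside = np.flatnonzero(u < eps0)
    start = int(inside[0])
    small = np.flatnonzero((np.arange(len(z)) > np.argmin(u)) & (np.abs(u) < tail_cut))
    stop = int(small[0]) + 1 if len(small) else len(z)
    zw, uw = z[start:stop], u[start:stop]
    if len(zw) < 4:
        raise ValueError("fitting window has fewer than 4 points")

    # zero crossing between the shoulder and the minimum
    imin = int(np.argmin(uw))
    sign = np.flatnonzero(uw[: imin + 1] <= 0.0)
    if len(sign):
        k = int(sign[0])
        if k > 0:
            z0, z1, u0, u1 = zw[k - 1], zw[k], uw[k - 1], uw[k]
            zc = z0 + (0.0 - u0) * (z1 - z0) / (u1 - u0)
        else:
            zc = zw[0]
        sigma0 = zc / LJ93_ZERO_FACTOR
    else:
        sigma0 = zw[imin] / (2.0 / 5.0) ** (1.0 / 6.0)

    try:
        popt, pcov = curve_fit(
            _lj93, zw, uw, p0=(eps0, sigma0), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"9-3 fit did not converge (initial guess eps={eps0:.4g}, "
            f"sigma={sigma0:.4g}, window {zw[0]:.3f}-{zw[-1]:.3f} nm)"
        ) from exc
    eps_fit, sigma_fit = float(popt[0]), float(popt[1])
    resid = uw - _lj93(zw, *popt)
    diag = {
        "rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        "window": (float(zw[0]), float(zw[-1])),
        "n_points": len(zw),
    }
    return CrossParams(eps_iw=eps_fit, sigma_iw=sigma_fit), diag


def parameterize_probe(
    slab: Slab,
    probe: LJPair,
    grid: tuple[int, int] = (6, 6),
    z_range: tuple[float, float] = (0.1, 1.5),
    z_step: float = 0.01,
    image_tol: float = 1e-4,
) -> tuple[CrossParams, dict]:
    """Site-averaged cross parameters for one probe type.

    Runs the z-scan and 9-3 fit at a uniform ``grid`` of lateral sites
    spanning one periodic cell (the primitive cell when the slab records
    one) and returns the mean (eps_iw, sigma_iw) with standard errors
    std / sqrt(n_sites).
    """
    _, _, _, _, cell = _reduced_slab_arrays(slab)
    nx, ny = grid
    if nx < 1 or ny < 1:
        raise ValueError("grid must be at least 1x1")
    xs = (np.arange(nx) + 0.5) / nx * cell[0]
    ys = (np.arange(ny) + 0.5) / ny * cell[1]

    eps_vals, sig_vals, resids = [], [], []
    for x in xs:
        for y in ys:
            try:
                curve = probe_curve(
                    slab, probe, (x, y), z_range, z_step, image_tol
                )
                cp, diag = fit_lj93(curve)
            except (ValueError, RuntimeError) as exc:
                raise RuntimeError(
                    f"site ({x:.3f}, {y:.3f}) nm failed: {exc}"
                ) from exc
            eps_vals.append(cp.eps_iw)
            sig_vals.append(cp.sigma_iw)
            resids.append(diag["rms_residual"])

    n = len(eps_vals)
    eps_arr, sig_arr = np.array(eps_vals), np.array(sig_vals)
    eps_se = float(eps_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    sig_se = float(sig_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    result = CrossParams(
        eps_iw=float(eps_arr.mean()),
        sigma_iw=float(sig_arr.mean()),
        eps_iw_se=eps_se,
        sigma_iw_se=sig_se,
    )
    diag = {
        "n_sites": n,
        "rms_residual_mean": float(np.mean(resids)),
        "eps_iw_sites": eps_arr.tolist(),
        "sigma_iw_sites": sig_arr.tolist(),
    }
    return result, diag


def derive_wall_params(
    probe_set: dict[str, tuple[LJPair, CrossParams]],
    material_label: str = "",
    weighted: bool = False,
) -> tuple[WallParams, dict]:
    """Regress the combining rules across probe types to get wall params.

    The epsilon rule eps_iw = sqrt(eps_ii * eps_ww) is fitted to the
    (eps_ii, eps_iw) points and the adjusted sigma rule
    0.715 sigma_iw = (0.715 sigma_ii + sigma_ww)/2 to the
    (sigma_ii, sigma_iw) points, each with the wall parameter as the
    single unknown (ordinary least squares by default; ``weighted`` uses
    1/se^2 weights where available).
    """
    if len(probe_set) < 2:
        raise ValueError("need >= 2 probe types with distinct parameters")
    eps_ii = np.array([p.epsilon for p, _ in probe_set.values()])
    sig_ii = np.array([p.sigma for p, _ in probe_set.values()])
    eps_iw = np.array([c.eps_iw for _, c in probe_set.values()])
    sig_iw = np.array([c.sigma_iw for _, c in probe_set.values()])
    if np.all(eps_ii == 0.0):
        raise ValueError("all probe epsilons are zero")

    if weighted:
        w_eps = np.array(
            [1.0 / max(c.eps_iw_se, 1e-12) ** 2 for _, c in probe_set.values()]
        )
        w_sig = np.array(
            [1.0 / max(c.sigma_iw_se, 1e-12) ** 2 for _, c in probe_set.values()]
        )
    else:
        w_eps = w_sig = np.ones_like(eps_ii)

    # eps_iw = sqrt(eps_ww) * sqrt(eps_ii): linear in sqrt(eps_ww)
    x = np.sqrt(eps_ii)
    sqrt_eps_ww = float(np.sum(w_eps * x * eps_iw) / np.sum(w_eps * x * x))
    eps_ww = sqrt_eps_ww ** 2

    # 0.715 sigma_iw = (0.715 sigma_ii + sigma_ww)/2: linear in sigma_ww
    resp = LJ93_ZERO_FACTOR * (2.0 * sig_iw - sig_ii)
    sigma_ww = float(np.sum(w_sig * resp) / np.sum(w_sig))

    eps_resid = eps_iw - sqrt_eps_ww * x
    sig_resid = sig_iw - 0.5 * (
        LJ93_ZERO_FACTOR * sig_ii + sigma_ww
    ) / LJ93_ZERO_FACTOR
    wall = WallParams(
        eps_ww=eps_ww, sigma_ww=sigma_ww, material_label=material_label
    )
    diag = {
        "eps_rule_rms": float(np.sqrt(np.mean(eps_resid ** 2))),
        "sigma_rule_rms": float(np.sqrt(np.mean(sig_resid ** 2))),
        "n_probes": len(probe_set),
    }
    return wall, diag


def parameterize_surface(
    slab: Slab,
    probes: dict[str, LJPair],
    grid: tuple[int, int] = (6, 6),
    z_range: tuple[float, float] = (0.1, 1.5),
    z_step: float = 0.01,
    image_tol: float = 1e-4,
    material_label: str = "",
    weighted: bool = False,
) -> ParameterizationResult:
    """Full pipeline: per-probe site-averaged fits, then the combining-rule
    regression.  Probes with zero epsilon (no LJ interaction) are rejected."""
    per_probe: dict[str, CrossParams] = {}
    diagnostics: dict = {"per_probe": {}}
    pairs: dict[str, tuple[LJPair, CrossParams]] = {}
    for name, probe in probes.items():
        if probe.epsilon == 0.0:
            raise ValueError(
                f"probe {name!r} has zero LJ epsilon and cannot be included"
            )
        cp, diag = parameterize_probe(
            slab, probe, grid, z_range, z_step, image_tol
        )
        per_probe[name] = cp
        pairs[name] = (probe, cp)
        diagnostics["per_probe"][name] = diag
    wall, wdiag = derive_wall_params(
        pairs, material_label=material_label, weighted=weighted
    )
    diagnostics["combining_rules"] = wdiag
    return ParameterizationResult(
        per_probe=per_probe, wall=wall, fit_diagnostics=diagnostics
    )
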