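"""Interfacial analysis operators for particle trajectories.

Density profiles along the surface normal, interfacial-zone densities,
P2 bond-orientation profiles, layer definitions, residency-constrained
lateral diffusion, residence-time distributions, bond-vector
autocorrelation decay, and finite-film-thickness extrapolation.

Conventions: distances nm, times ps (residence and decay times reported
in ns), mass densities g/cm^3, diffusion coefficients 1e-9 m^2/s.  The
interfacial zone starts at the 9-3 wall's zero crossing z = 0.715
sigma_ww so that walls of different sigma are compared on an equal
footing.  A molecule's reference site for layer membership is its bond
midpoint when it has a bond vector, else its single particle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .potentials import WallParams
from .trajectory import Trajectory

__all__ = [
    "DensityProfile",
    "LayerDefinition",
    "MSDResult",
    "ACFResult",
    "ResidenceDistribution",
    "ExtrapolationResult",
    "density_profile",
    "interfacial_density",
    "detect_bulk_boundary",
    "p2_profile",
    "define_layers",
    "layer_msd_xy",
    "diffusion_coefficient",
    "residence_times",
    "bond_acf",
    "extrapolate_infinite_thickness",
]

AMU_PER_NM3_TO_G_PER_CM3 = 1.66053907e-3
#: nm^2/ps -> 1e-9 m^2/s
NM2_PS_TO_1E9_M2_S = 1.0e3


@dataclass
class DensityProfile:
    """Time-averaged mass density vs z, per species (g/cm^3)."""

    bin_centers: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float

    def species_density(self, species) -> np.ndarray:
        """Density of one species, or the sum over an iterable of species."""
        if isinstance(species, str):
            return self.densities[species]
        return np.sum([self.densities[s] for s in species], axis=0)


@dataclass(frozen=True)
class LayerDefinition:
    z_lo: float
    z_hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.z_lo < self.z_hi):
            raise ValueError("require z_lo < z_hi")

    @property
    def width(self) -> float:
        return self.z_hi - self.z_lo


@dataclass
class MSDResult:
    lags: np.ndarray  # ps
    msd_xy: np.ndarray  # nm^2
    counts: np.ndarray  # origin-lag pairs per lag
    fit_window: tuple[float, float] | None = None
    D: float | None = None  # 1e-9 m^2/s
    D_se: float | None = None


@dataclass
class ACFResult:
    lags: np.ndarray  # ps
    acf: np.ndarray
    counts: np.ndarray
    decay_time: float | None  # ns; None if 1/e never reached


@dataclass
class ResidenceDistribution:
    residence_times: np.ndarray  # ns, one per visit
    censored: np.ndarray  # bool, visit truncated by trajectory ends
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def mean(self, include_censored: bool = False) -> float:
        sel = np.ones(len(self.residence_times), bool)
        if not include_censored:
            sel &= ~self.censored
        if not sel.any():
            return math.nan
        return float(self.residence_times[sel].mean())


@dataclass
class ExtrapolationResult:
    slope: float  # g/cm^3 * nm
    intercept: float  # infinite-thickness interfacial density, g/cm^3
    intercept_se: float
    thicknesses: np.ndarray
    rho_int: np.ndarray


# ---------------------------------------------------------------------------


def density_profile(
    traj: Trajectory,
    bin_width: float = 0.02,
    species: list[str] | None = None,
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Time-averaged mass-density profile along z, one curve per species.

    The integral of each curve times the lateral area recovers that
    species' mean total mass (conservation is exact by construction).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    labels = np.asarray(traj.topology.species)
    wanted = sorted(set(labels)) if species is None else list(species)
    if not wanted or not set(wanted) & set(labels):
        raise ValueError("empty species selection")

    z = traj.positions[:, :, 2]
    if z_range is None:
        z_range = (float(z.min()), float(z.max()))
    lo = math.floor(z_range[0] / bin_width) * bin_width
    n_bins = max(int(math.ceil((z_range[1] - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    area = traj.box[0] * traj.box[1]
    vol = area * bin_width * traj.n_frames

    densities = {}
    for sp in wanted:
        sel = labels == sp
        if not sel.any():
            densities[sp] = np.zeros(n_bins)
            continue
        m = traj.topology.masses[sel]
        zs = z[:, sel].ravel()
        w = np.tile(m, traj.n_frames)
        hist, _ = np.histogram(zs, bins=edges, weights=w)
        densities[sp] = hist / vol * AMU_PER_NM3_TO_G_PER_CM3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(bin_centers=centers, densities=densities, bin_width=bin_width)


def _zone_mean(profile: DensityProfile, rho: np.ndarray, z_lo: float, z_hi: float) -> float:
    """Mean of a binned profile over [z_lo, z_hi] with partial-bin overlap
    weights."""
    h = profile.bin_width
    lo_edges = profile.bin_centers - h / 2.0
    hi_edges = profile.bin_centers + h / 2.0
    overlap = np.clip(np.minimum(hi_edges, z_hi) - np.maximum(lo_edges, z_lo), 0.0, h)
    if overlap.sum() < (z_hi - z_lo) - h:
        raise ValueError(
            f"zone [{z_lo:.3f}, {z_hi:.3f}] nm is not covered by the profile "
            f"[{lo_edges[0]:.3f}, {hi_edges[-1]:.3f}] nm"
        )
    return float(np.sum(rho * overlap) / np.sum(overlap))


def interfacial_density(
    profile: DensityProfile,
    wall: WallParams,
    species,
    width: float = 1.0,
) -> float:
    """Mean solute density over the 1 nm zone starting at the wall's zero
    crossing 0.715 sigma_ww (g/cm^3)."""
    z_lo = wall.zero_crossing
    rho = profile.species_density(species)
    return _zone_mean(profile, rho, z_lo, z_lo + width)


def detect_bulk_boundary(
    profile: DensityProfile,
    species,
    wall: WallParams | None = None,
    smoothing_window: int = 5,
    derivative_tol: float = 0.1,
) -> tuple[LayerDefinition, float]:
    """Locate where the density profile flattens into bulk.

    The species profile is smoothed with a centered moving average of
    ``smoothing_window`` bins, differentiated numerically, and the
    boundary is the first z (at or beyond the zone start) where
    |d rho/dz| stays below ``derivative_tol`` (g/cm^3 per nm) for a full
    smoothing window.  Returns the interfacial LayerDefinition and the
    mean solute density over it (rho_int_star).
    """
    rho = profile.species_density(species)
    z = profile.bin_centers
    w = max(int(smoothing_window), 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(rho, kernel, mode="same")
    deriv = np.gradient(smooth, z)

    z_start = wall.zero_crossing if wall is not None else float(z[0])
    start_idx = int(np.searchsorted(z, z_start))
    flat = np.abs(deriv) < derivative_tol
    boundary_idx = None
    for i in range(max(start_idx, w // 2), len(z) - w + 1):
        if flat[i : i + w].all():
            boundary_idx = i
            break
    if boundary_idx is None:
        raise ValueError(
            "no density plateau found: |d rho/dz| never stays below "
            f"{derivative_tol} for {w} consecutive bins"
        )
    z_b = float(z[boundary_idx])
    if z_b <= z_start:
        z_b = z_start + profile.bin_width
    layer = LayerDefinition(z_lo=z_start, z_hi=z_b, label="interfacial")
    return layer, _zone_mean(profile, rho, layer.z_lo, layer.z_hi)


def p2_profile(
    traj: Trajectory,
    bond_pairs: np.ndarray | None = None,
    bin_width: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile of the bond-orientation order parameter P2 vs z.

    P2 = (3 cos^2 theta - 1)/2 with theta the angle between each bond
    vector and the z axis, averaged per bin of the bond midpoint z:
    1 for bonds normal to the surface, -0.5 for bonds lying in the
    surface plane, 0 for isotropic orientations.  Returns (bin_centers,
    p2); bins with no bonds hold NaN.
    """
    v = traj.bond_vectors(bond_pairs)
    norms = np.linalg.norm(v, axis=2)
    if np.any(norms <= 1e-12):
        raise ValueError("zero-length bond vector encountered")
    cos2 = (v[:, :, 2] / norms) ** 2
    p2 = 1.5 * cos2 - 0.5
    zmid = traj.bond_midpoints(bond_pairs)[:, :, 2].ravel()
    p2 = p2.ravel()

    lo = math.floor(zmid.min() / bin_width) * bin_width
    n_bins = max(int(math.ceil((zmid.max() - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.searchsorted(edges, zmid, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=p2, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, prof


def define_layers(
    profile: DensityProfile,
    wall: WallParams,
    species,
    min_prominence: float = 0.0,
) -> list[LayerDefinition]:
    """First and second interfacial layers from the solute profile.

    The first layer runs from the wall zero crossing to the density
    minimum between the first and second solute peaks; the second layer
    is the adjacent window of equal width.  Requires at least two peaks
    beyond the zone start.
    """
    rho = profile.species_density(species)
    z = profile.bin_centers
    z0 = wall.zero_crossing
    sel = z >= z0
    peaks, _ = signal.find_peaks(rho[sel], prominence=min_prominence or None)
    if len(peaks) < 2:
        raise ValueError(
            f"need >= 2 solute density peaks beyond z = {z0:.3f} nm, "
            f"found {len(peaks)}"
        )
    zs, rs = z[sel], rho[sel]
    i0, i1 = peaks[0], peaks[1]
    imin = i0 + int(np.argmin(rs[i0 : i1 + 1]))
    z_min = float(zs[imin])
    width = z_min - z0
    return [
        LayerDefinition(z_lo=z0, z_hi=z_min, label="first"),
        LayerDefinition(z_lo=z_min, z_hi=z_min + width, label="second"),
    ]


# ---------------------------------------------------------------------------
# residency bookkeeping


def _reference_sites(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-molecule reference trajectory.

    Returns (xy (F, M, 2) unwrapped, z (F, M), molecule index array).
    Molecules with a bond use the bond midpoint; single-particle
    molecules use their particle.  Unwrapping is lateral only.
    """
    top = traj.topology
    mol_ids = np.unique(top.molecule_ids)
    bond_mol = (
        top.molecule_ids[top.bond_pairs[:, 0]] if top.bond_pairs.size else np.array([], int)
    )
    uxy = traj.unwrapped_xy()
    z_all = traj.positions[:, :, 2]
    if top.bond_pairs.size:
        v_mid_z = traj.bond_midpoints()[:, :, 2]
        a, b = traj.topology.bond_pairs[:, 0], traj.topology.bond_pairs[:, 1]
        mid_xy = 0.5 * (uxy[:, a] + uxy[:, b])
    xy_cols, z_cols = [], []
    for m in mol_ids:
        hits = np.flatnonzero(bond_mol == m)
        if hits.size:
            j = hits[0]
            xy_cols.append(mid_xy[:, j])
            z_cols.append(v_mid_z[:, j])
        else:
            j = int(np.flatnonzero(top.molecule_ids == m)[0])
            xy_cols.append(uxy[:, j])
            z_cols.append(z_all[:, j])
    return (
        np.stack(xy_cols, axis=1),
        np.stack(z_cols, axis=1),
        mol_ids,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) frame slices."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _msd_fft_1d(x: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Multi-time-origin MSD of one coordinate series via FFT, all origins."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real
    sq = x * x
    css = np.cumsum(sq)
    total = css[-1]
    msd = np.empty(max_lag + 1)
    counts = np.arange(n, n - max_lag - 1, -1)
    msd[0] = 0.0
    for lag in range(1, max_lag + 1):
        # sum over origins i of x_i^2 + x_{i+lag}^2 - 2 x_i x_{i+lag}
        msd[lag] = (total - css[lag - 1]) + css[n - lag - 1] - 2.0 * acf[lag]
    return msd, counts


def layer_msd_xy(
    traj: Trajectory,
    layer: LayerDefinition,
    max_lag: float,
) -> MSDResult:
    """Residency-constrained lateral mean-squared displacement.

    Multi-time-origin MSD over x and y only, averaging over exactly
    those origin-lag pairs during which the molecule's reference site
    remains continuously inside the layer.  Coordinates are unwrapped
    laterally; z is never wrapped.
    """
    dt = traj.dt
    max_lag_frames = int(round(max_lag / dt))
    if max_lag_frames >= traj.n_frames:
        raise ValueError("max_lag must be shorter than the trajectory span")
    xy, z, _ = _reference_sites(traj)
    inside = (z >= layer.z_lo) & (z < layer.z_hi)

    sums = np.zeros(max_lag_frames + 1)
    counts = np.zeros(max_lag_frames + 1, dtype=float)
    for m in range(xy.shape[1]):
        for start, stop in _runs(inside[:, m]):
            run_len = stop - start
            if run_len < 2:
                continue
            L = min(max_lag_frames, run_len - 1)
            for k in range(2):
                msd_k, cnt = _msd_fft_1d(xy[start:stop, m, k], L)
                sums[: L + 1] += msd_k
                if k == 0:
                    counts[: L + 1] += cnt
    if counts[1:].sum() == 0:
        raise ValueError("no molecule resides in the layer long enough")
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    msd[0] = 0.0
    lags = dt * np.arange(max_lag_frames + 1)
    return MSDResult(lags=lags, msd_xy=msd, counts=counts)


def diffusion_coefficient(
    msd: MSDResult,
    fit_window: tuple[float, float] | None = None,
    n_dim: int = 2,
) -> MSDResult:
    """Einstein-relation diffusion coefficient from an MSD curve.

    Least-squares slope of MSD vs lag over ``fit_window`` (ps); the
    default window is 10-30% of the maximum lag, a near-origin region
    where the MSD is linear.  D = slope / (2 n_dim), reported in
    1e-9 m^2/s with the standard error of the slope propagated.  A
    curvature flag is attached when the window's two halves give slopes
    differing by more than 25% (ballistic or saturating regions).
    """
    if fit_window is None:
        t_max = float(msd.lags[-1])
        fit_window = (0.1 * t_max, 0.3 * t_max)
    sel = (msd.lags >= fit_window[0]) & (msd.lags <= fit_window[1])
    sel &= np.isfinite(msd.msd_xy)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 MSD points in the fit window")
    t, y = msd.lags[sel], msd.msd_xy[sel]
    fit = stats.linregress(t, y)
    D = fit.slope / (2.0 * n_dim) * NM2_PS_TO_1E9_M2_S
    D_se = fit.stderr / (2.0 * n_dim) * NM2_PS_TO_1E9_M2_S

    mid = len(t) // 2
    curved = False
    if mid >= 2 and len(t) - mid >= 2:
        s1 = stats.linregress(t[:mid], y[:mid]).slope
        s2 = stats.linregress(t[mid:], y[mid:]).slope
        ref = max(abs(fit.slope), 1e-300)
        curved = abs(s2 - s1) / ref > 0.25
    out = MSDResult(
        lags=msd.lags,
        msd_xy=msd.msd_xy,
        counts=msd.counts,
        fit_window=fit_window,
        D=float(D),
        D_se=float(D_se),
    )
    out.curvature_flag = curved
    return out


def residence_times(
    traj: Trajectory,
    layer: LayerDefinition,
    n_hist_bins: int = 20,
) -> ResidenceDistribution:
    """Per-visit durations of continuous layer occupancy (ns).

    A visit lasting k consecutive frames contributes k * dt, so the sum
    of all visit durations equals the total frames-in-layer occupancy.
    Visits truncated by either trajectory end are flagged censored (they
    appear in the histogram but are excluded from means by default).
    """
    dt = traj.dt
    _, z, _ = _reference_sites(traj)
    inside = (z >= layer.z_lo) & (z < layer.z_hi)
    durations, censored = [], []
    n_frames = inside.shape[0]
    for m in range(inside.shape[1]):
        for start, stop in _runs(inside[:, m]):
            durations.append((stop - start) * dt * 1e-3)  # ps -> ns
            censored.append(start == 0 or stop == n_frames)
    durations = np.asarray(durations)
    censored = np.asarray(censored, bool)
    if durations.size:
        edges = np.linspace(0.0, float(durations.max()), n_hist_bins + 1)
        hist, _ = np.histogram(durations, bins=edges)
    else:
        edges, hist = np.array([0.0, 1.0]), np.array([0])
    return ResidenceDistribution(
        residence_times=durations,
        censored=censored,
        hist_edges=edges,
        hist_counts=hist,
    )


def _acf_fft_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    return np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1].real


def bond_acf(
    traj: Trajectory,
    layer: LayerDefinition | None,
    max_lag: float,
    bond_pairs: np.ndarray | None = None,
) -> ACFResult:
    """Multi-time-origin autocorrelation of the molecular bond vector.

    Averages the normalized dot product of each bond's unit vector with
    itself a lag apart, restricted (when ``layer`` is given) to origin-
    lag pairs whose molecule stays continuously inside the layer.  The
    decay time is the lag at which the ACF first falls to 1/e, linearly
    interpolated between samples, in ns; None when the crossing is not
    reached within ``max_lag``.
    """
    dt = traj.dt
    max_lag_frames = int(round(max_lag / dt))
    if max_lag_frames >= traj.n_frames:
        raise ValueError("max_lag must be shorter than the trajectory span")
    v = traj.bond_vectors(bond_pairs)
    norms = np.linalg.norm(v, axis=2, keepdims=True)
    if np.any(norms <= 1e-12):
        raise ValueError("zero-length bond vector encountered")
    u = v / norms
    zmid = traj.bond_midpoints(bond_pairs)[:, :, 2]
    if layer is None:
        inside = np.ones(zmid.shape, bool)
    else:
        inside = (zmid >= layer.z_lo) & (zmid < layer.z_hi)

    sums = np.zeros(max_lag_frames + 1)
    counts = np.zeros(max_lag_frames + 1)
    for b in range(u.shape[1]):
        for start, stop in _runs(inside[:, b]):
            run_len = stop - start
            if run_len < 1:
                continue
            L = min(max_lag_frames, run_len - 1)
            seg = u[start:stop, b, :]
            acf = np.zeros(L + 1)
            for k in range(3):
                acf += _acf_fft_1d(seg[:, k], L)
            sums[: L + 1] += acf
            counts[: L + 1] += np.arange(run_len, run_len - L - 1, -1)
    if counts[0] == 0:
        raise ValueError("no bond ever resides in the layer")
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    lags = dt * np.arange(max_lag_frames + 1)

    target = 1.0 / math.e
    decay = None
    below = np.flatnonzero(acf[: max_lag_frames + 1] <= target)
    below = below[below > 0]
    if below.size:
        i = int(below[0])
        t0, t1, a0, a1 = lags[i - 1], lags[i], acf[i - 1], acf[i]
        if a0 == a1:
            decay = float(t1) * 1e-3
        else:
            decay = float(t0 + (a0 - target) * (t1 - t0) / (a0 - a1)) * 1e-3
    return ACFResult(lags=lags, acf=acf, counts=counts, decay_time=decay)


def extrapolate_infinite_thickness(
    films: list[tuple[float, float]],
) -> ExtrapolationResult:
    """Extrapolate interfacial densities of finite films to 1/L -> 0.

    Ordinary least squares of rho_int against the inverse film thickness;
    the intercept estimates the interfacial density of an infinitely
    thick film (a true bulk reservoir).
    """
    L = np.array([f[0] for f in films], float)
    rho = np.array([f[1] for f in films], float)
    if len(L) < 2 or np.unique(L).size < 2:
        raise ValueError("need >= 2 films with distinct thicknesses")
    x = 1.0 / L
    if np.unique(x).size == 2 and len(x) == 2:
        slope = (rho[1] - rho[0]) / (x[1] - x[0])
        intercept, se = rho[0] - slope * x[0], 0.0
    else:
        fit = stats.linregress(x, rho)
        slope, intercept = fit.slope, fit.intercept
        se = fit.intercept_stderr
    return ExtrapolationResult(
        slope=float(slope),
        intercept=float(intercept),
        intercept_se=float(se),
        thicknesses=L,
        rho_int=rho,
    )
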