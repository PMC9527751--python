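"""Synthetic solution-film trajectories with known ground truth.

Replaces molecular dynamics for testing the analyzers: non-interacting
labeled particles and rigid two-site dumbbells evolve by overdamped
(Brownian) dynamics in the external field of a 9-3 wall, with a
reflective upper film boundary standing in for the liquid-vacuum
surface.  Because the particles do not interact, the equilibrium density
is the Boltzmann profile exp(-U(z)/kT) in closed form, translational and
rotational diffusivities are inputs, and the bond-vector ACF decays as
exp(-2 D_rot t) — every analyzer has an exact oracle.

Inertia is deliberately absent: the analyzers only consume positions and
orientations, and temperature enters only through the Boltzmann factor
and the noise amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .potentials import (
    LJPair,
    WallParams,
    combine_epsilon,
    combine_sigma93,
    lj93_energy,
    lj93_force,
)
from .trajectory import Topology, Trajectory

__all__ = ["SimConfig", "GroundTruth", "wall_field", "simulate", "sample_boltzmann"]

KCAL_PER_MOL_PER_K = 1.9872041e-3  # Boltzmann constant, kcal/(mol K)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a synthetic film simulation.

    Diffusivities: ``d_trans`` in 1e-9 m^2/s (= nm^2/ns), ``d_rot`` in
    1/ns.  ``box`` is (lx, ly, film thickness H), nm.  The 9-3 field
    acting on every particle is built from ``wall`` and ``solute`` via
    the package combining rules.  ``dt`` ps, trajectory frames written
    every ``stride`` steps.
    """

    n_particles: int = 200
    n_dumbbells: int = 0
    d_trans: float = 0.5
    d_rot: float = 2.0
    temperature: float = 298.0
    wall: WallParams = field(
        default_factory=lambda: WallParams(8.2, 0.18, "tridecane")
    )
    solute: LJPair = field(default_factory=lambda: LJPair(0.11, 0.30))
    box: tuple[float, float, float] = (3.45, 3.45, 3.1)
    dt: float = 0.5
    n_steps: int = 2000
    seed: int = 0
    stride: int = 1
    bond_length: float = 0.15
    particle_mass: float = 75.07

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1 or self.stride < 1:
            raise ValueError("dt, n_steps and stride must be positive")
        if self.d_trans <= 0 or self.d_rot < 0:
            raise ValueError("diffusivities must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if min(self.box) <= 0:
            raise ValueError("box lengths must be positive")
        if self.n_particles + self.n_dumbbells < 1:
            raise ValueError("need at least one particle or dumbbell")

    @property
    def kT(self) -> float:
        return KCAL_PER_MOL_PER_K * self.temperature

    @property
    def d_trans_nm2_ps(self) -> float:
        return self.d_trans * 1e-3

    @property
    def d_rot_per_ps(self) -> float:
        return self.d_rot * 1e-3


@dataclass
class GroundTruth:
    """Closed-form expectations for a SimConfig."""

    z_grid: np.ndarray
    density: np.ndarray  # equilibrium z-pdf, normalized, 1/nm
    d_trans: float  # 1e-9 m^2/s
    d_rot: float  # 1/ns
    acf_decay_time: float | None  # ns, 1/(2 d_rot)

    def zone_occupancy(self, z_lo: float, z_hi: float) -> float:
        """Equilibrium probability of z in [z_lo, z_hi] by quadrature."""
        sel = (self.z_grid >= z_lo) & (self.z_grid <= z_hi)
        return float(np.trapezoid(self.density[sel], self.z_grid[sel]))


def wall_field(config: SimConfig) -> LJPair:
    """Effective solute-wall 9-3 pair from the combining rules."""
    if config.wall.eps_ww == 0.0:
        return LJPair(0.0, combine_sigma93(config.solute.sigma, config.wall.sigma_ww))
    return LJPair(
        combine_epsilon(config.solute.epsilon, config.wall.eps_ww),
        combine_sigma93(config.solute.sigma, config.wall.sigma_ww),
    )


def _z_floor(pair: LJPair) -> float:
    # below this height the 9-3 repulsion exceeds ~100 kT for any sane
    # config; used only as a numerical reflection guard
    return 0.3 * pair.sigma


def _equilibrium_pdf(config: SimConfig, n_grid: int = 4000):
    pair = wall_field(config)
    H = config.box[2]
    z = np.linspace(_z_floor(pair), H, n_grid)
    if pair.epsilon > 0.0:
        u = lj93_energy(z, pair)
    else:
        u = np.zeros_like(z)
    w = np.exp(-(u - u.min()) / config.kT)
    norm = np.trapezoid(w, z)
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("equilibrium density is not normalizable for this config")
    return z, w / norm


def _make_topology(config: SimConfig) -> Topology:
    species, masses, mols, bonds = [], [], [], []
    for i in range(config.n_particles):
        species.append("S")
        masses.append(config.particle_mass)
        mols.append(i)
    for j in range(config.n_dumbbells):
        mol = config.n_particles + j
        k = len(species)
        for _ in range(2):
            species.append("D")
            masses.append(config.particle_mass / 2.0)
            mols.append(mol)
        bonds.append((k, k + 1))
    return Topology(
        species=species,
        masses=np.array(masses),
        molecule_ids=np.array(mols),
        bond_pairs=np.array(bonds, int).reshape(-1, 2),
    )


def _random_unit_vectors(rng, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _assemble(config, times, centers_frames, orient_frames) -> Trajectory:
    frames = []
    half = 0.5 * config.bond_length
    for c, u in zip(centers_frames, orient_frames):
        single = c[: config.n_particles]
        if config.n_dumbbells:
            dumb = c[config.n_particles :]
            sites = np.empty((2 * config.n_dumbbells, 3))
            sites[0::2] = dumb - half * u
            sites[1::2] = dumb + half * u
            frames.append(np.vstack([single, sites]))
        else:
            frames.append(single)
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        box=(config.box[0], config.box[1]),
        topology=_make_topology(config),
    )


def sample_boltzmann(
    config: SimConfig, n_frames: int = 1
) -> tuple[Trajectory, GroundTruth]:
    """Independent exact-equilibrium frames.

    z is drawn by inverse-CDF sampling of exp(-U(z)/kT) on a fine grid,
    x and y uniformly over the lateral box, dumbbell orientations
    isotropically.  Frames are statistically independent (times are a
    nominal 1 ps apart), so only static analyzers should consume them.
    """
    rng = np.random.default_rng(config.seed)
    z_grid, pdf = _equilibrium_pdf(config)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(z_grid))])
    cdf /= cdf[-1]
    n_mol = config.n_particles + config.n_dumbbells

    centers_frames, orient_frames, times = [], [], []
    for f in range(n_frames):
        u01 = rng.random(n_mol)
        z = np.interp(u01, cdf, z_grid)
        xy = rng.random((n_mol, 2)) * [config.box[0], config.box[1]]
        centers_frames.append(np.column_stack([xy, z]))
        orient_frames.append(
            _random_unit_vectors(rng, config.n_dumbbells)
            if config.n_dumbbells
            else None
        )
        times.append(float(f))
    gt = GroundTruth(
        z_grid=z_grid,
        density=pdf,
        d_trans=config.d_trans,
        d_rot=config.d_rot,
        acf_decay_time=(1.0 / (2.0 * config.d_rot) if config.d_rot > 0 else None),
    )
    return _assemble(config, times, centers_frames, orient_frames), gt


def simulate(config: SimConfig) -> tuple[Trajectory, GroundTruth]:
    """Overdamped Langevin (Euler-Maruyama) dynamics in the 9-3 field.

    Translational step: dr = (D/kT) F dt + sqrt(2 D dt) xi with the force
    acting along z only; lateral coordinates are periodic, the top of the
    film is reflective, and a reflective floor guards the steep repulsive
    wall.  Dumbbell orientations diffuse on the sphere with rotational
    diffusivity D_rot.  Initial positions are drawn from the exact
    equilibrium distribution, so the trajectory is stationary from the
    first frame.  Identical (seed, config) gives bitwise-identical
    output.
    """
    pair = wall_field(config)
    D = config.d_trans_nm2_ps
    step_scale = math.sqrt(2.0 * D * config.dt)
    zc = pair.sigma * (2.0 / 15.0) ** (1.0 / 6.0)
    if step_scale > 0.25 * zc:
        raise ValueError(
            f"dt too large: rms step {step_scale:.3g} nm exceeds a quarter "
            f"of the wall zero crossing {zc:.3g} nm"
        )
    rng = np.random.default_rng(config.seed)
    z_grid, pdf = _equilibrium_pdf(config)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(z_grid))])
    cdf /= cdf[-1]

    n_mol = config.n_particles + config.n_dumbbells
    pos = np.empty((n_mol, 3))
    pos[:, 2] = np.interp(rng.random(n_mol), cdf, z_grid)
    pos[:, :2] = rng.random((n_mol, 2)) * [config.box[0], config.box[1]]
    u = _random_unit_vectors(rng, config.n_dumbbells) if config.n_dumbbells else None

    H = config.box[2]
    z_floor = _z_floor(pair)
    mobility_dt = D / config.kT * config.dt
    rot_scale = (
        math.sqrt(2.0 * config.d_rot_per_ps * config.dt) if config.n_dumbbells else 0.0
    )

    centers_frames = [pos.copy()]
    orient_frames = [u.copy() if u is not None else None]
    times = [0.0]
    for step in range(1, config.n_steps + 1):
        noise = rng.standard_normal((n_mol, 3)) * step_scale
        pos += noise
        if pair.epsilon > 0.0:
            zsafe = np.clip(pos[:, 2] - noise[:, 2], z_floor, None)
            pos[:, 2] += mobility_dt * lj93_force(zsafe, pair)
        # lateral wrap, reflective normal boundaries
        pos[:, 0] %= config.box[0]
        pos[:, 1] %= config.box[1]
        z = pos[:, 2]
        z[:] = np.where(z > H, 2.0 * H - z, z)
        z[:] = np.where(z < z_floor, 2.0 * z_floor - z, z)
        z[:] = np.clip(z, z_floor, H)
        if u is not None and config.d_rot > 0:
            xi = rng.standard_normal((config.n_dumbbells, 3)) * rot_scale
            xi -= np.sum(xi * u, axis=1, keepdims=True) * u  # tangential
            u = u + xi
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        if step % config.stride == 0:
            centers_frames.append(pos.copy())
            orient_frames.append(u.copy() if u is not None else None)
            times.append(step * config.dt)

    gt = GroundTruth(
        z_grid=z_grid,
        density=pdf,
        d_trans=config.d_trans,
        d_rot=config.d_rot,
        acf_decay_time=(1.0 / (2.0 * config.d_rot) if config.d_rot > 0 else None),
    )
    return _assemble(config, times, centers_frames, orient_frames), gt
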