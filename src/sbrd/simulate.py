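"""Forward Brownian dynamics in spherocylinders with reflecting boundaries.

Point particles take Gaussian steps (variance 2*D*dt per axis) inside a
capsule-shaped compartment; steps that cross the wall are specularly
reflected without loss of path length. Stroboscopic displacement sampling at
a fixed lag (default 15 steps of 0.1 ms = 1.5 ms) reproduces the observable
of single-molecule displacement mapping. Optional spherical regions give the
compartment spatially varying dynamics (slow poles, binding regions,
confined species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import RegionMode, Spherocylinder, SphericalRegion

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate",
    "sample_displacements",
    "simulate_smdm_displacements",
    "displacements_frame",
]


@dataclass
class SimulationConfig:
    """Parameters of one forward simulation.

    Defaults reproduce the stroboscopic acquisition: 0.1 ms integration steps
    over 2 s with displacement sampling every 15 steps (1.5 ms lag).
    """

    D_input: float
    n_particles: int
    shape: Spherocylinder
    dt: float = 1e-4
    total_time: float = 2.0
    lag_steps: int = 15
    regions: tuple[SphericalRegion, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.D_input <= 0:
            raise ValueError("D_input must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    @property
    def lag_time(self) -> float:
        return self.lag_steps * self.dt


@dataclass
class Trajectory:
    particle_id: int
    positions: np.ndarray  # (n_steps + 1, 3)
    species: str = "A"


def _species_mask(
    positions: np.ndarray, regions: Sequence[SphericalRegion]
) -> np.ndarray | None:
    """Particles starting inside a species-mode region belong to that species
    and stay confined to it; returns region index per particle (-1 = bulk)."""
    tag = None
    for i, reg in enumerate(regions):
        if reg.mode is RegionMode.SPECIES:
            if tag is None:
                tag = np.full(positions.shape[0], -1)
            tag[reg.inside(positions) & (tag == -1)] = i
    return tag


def _step_batch(
    pos: np.ndarray,
    shape: Spherocylinder,
    regions: Sequence[SphericalRegion],
    species_tag: np.ndarray | None,
    D_bulk: float,
    dt: float,
    noise: np.ndarray,
) -> np.ndarray:
    """Advance all particles by one step with reflection and region dynamics.

    The diffusion coefficient of a step is that of the region containing the
    step's start point (first-order accurate at 0.1 ms steps).
    """
    D = np.full(pos.shape[0], D_bulk)
    for i, reg in enumerate(regions):
        if reg.mode is RegionMode.INTERACTION:
            D[reg.inside(pos)] = reg.D_inside
        elif reg.mode is RegionMode.IMPERMEABLE:
            D[reg.inside(pos)] = reg.D_inside
        elif reg.mode is RegionMode.SPECIES and species_tag is not None:
            D[species_tag == i] = reg.D_inside
    prop = pos + np.sqrt(2.0 * D * dt)[:, None] * noise
    new = shape.reflect_steps(pos, prop)
    # hard spherical walls: impermeable regions reflect from both sides,
    # species-mode regions confine their own species
    for i, reg in enumerate(regions):
        if reg.mode is RegionMode.IMPERMEABLE:
            sel = np.arange(pos.shape[0])
        elif reg.mode is RegionMode.SPECIES and species_tag is not None:
            sel = np.flatnonzero(species_tag == i)
        else:
            continue
        if sel.size:
            new[sel] = _reflect_sphere_wall(pos[sel], new[sel], reg, shape)
    return new


def _reflect_sphere_wall(
    p0: np.ndarray, p1: np.ndarray, reg: SphericalRegion, shape: Spherocylinder
) -> np.ndarray:
    """Reflect segments off a spherical wall (impermeable from both sides)."""
    c = np.asarray(reg.center)
    r2 = reg.radius**2
    out = p1.copy()
    side0 = np.sum((p0 - c) ** 2, axis=1) < r2
    for _ in range(8):
        side1 = np.sum((out - c) ** 2, axis=1) < r2
        crossed = side0 != side1
        if not np.any(crossed):
            break
        a, b = p0[crossed], out[crossed]
        lo = np.zeros(a.shape[0])
        hi = np.ones(a.shape[0])
        inside0 = side0[crossed]
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            m_in = np.sum((a + mid[:, None] * (b - a) - c) ** 2, axis=1) < r2
            flipped = m_in != inside0
            hi = np.where(flipped, mid, hi)
            lo = np.where(flipped, lo, mid)
        hit = a + hi[:, None] * (b - a)
        n = hit - c
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        w = b - hit
        out[crossed] = hit + w - 2.0 * np.sum(w * n, axis=1, keepdims=True) * n
    # keep inside the capsule too (rare double interaction)
    bad = ~shape.contains(out)
    if np.any(bad):
        out[bad] = shape.reflect_steps(p0[bad], out[bad])
    return out


def simulate(config: SimulationConfig, starts: np.ndarray | None = None) -> list[Trajectory]:
    """Run the forward simulation, returning full trajectories.

    Initial positions are uniform in 3D inside the compartment (rejection
    sampling) unless ``starts`` is given. Sub-streams per particle are not
    needed: a single seeded generator drives a fixed vectorized iteration
    order, which makes seeded runs bit-reproducible.
    """
    if config.shape.volume() <= 0:
        raise ValueError("zero-volume shape")
    rng = np.random.default_rng(config.seed)
    if starts is None:
        pos = config.shape.sample_uniform(config.n_particles, rng)
    else:
        pos = np.array(starts, dtype=float)
    n_steps = config.n_steps
    traj = np.empty((config.n_particles, n_steps + 1, 3))
    traj[:, 0] = pos
    tag = _species_mask(pos, config.regions)
    for k in range(n_steps):
        noise = rng.standard_normal(pos.shape)
        pos = _step_batch(pos, config.shape, config.regions, tag, config.D_input, config.dt, noise)
        traj[:, k + 1] = pos
    species = np.full(config.n_particles, "A", dtype=object)
    if tag is not None:
        species[tag >= 0] = [f"region{t}" for t in tag[tag >= 0]]
    return [Trajectory(i, traj[i], species[i]) for i in range(config.n_particles)]


def sample_displacements(trajs: Sequence[Trajectory], lag_steps: int, dt: float = 1e-4) -> pd.DataFrame:
    """Stroboscopic displacement sampling.

    Positions are read out every ``lag_steps`` steps and consecutive readouts
    paired, giving floor(n_steps / lag_steps) displacements per particle.
    Consecutive pairs span disjoint time intervals, so Brownian increments
    are independent. Each displacement carries the 2D-projected start/end,
    the planar distance r and the lag t.
    """
    frames = []
    t = lag_steps * dt
    for tr in trajs:
        n = tr.positions.shape[0]
        if lag_steps > n - 1:
            raise ValueError("lag_steps exceeds trajectory length")
        samp = tr.positions[::lag_steps]
        frames.append(
            pd.DataFrame(
                {
                    "x0": samp[:-1, 0],
                    "y0": samp[:-1, 1],
                    "x1": samp[1:, 0],
                    "y1": samp[1:, 1],
                    "particle": tr.particle_id,
                    "species": tr.species,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["x0", "y0", "x1", "y1", "particle", "species"]
    )
    out["r"] = np.hypot(out["x1"] - out["x0"], out["y1"] - out["y0"])
    out["t"] = t
    return out


def simulate_smdm_displacements(
    config: SimulationConfig,
    starts: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Memory-lean path: simulate and keep only the stroboscopic readouts.

    Equivalent to ``sample_displacements(simulate(config), lag_steps)`` but
    stores positions only at the sampling lag, which matters for long runs
    with many particles.
    """
    if config.shape.volume() <= 0:
        raise ValueError("zero-volume shape")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if starts is None:
        pos = config.shape.sample_uniform(config.n_particles, rng)
    else:
        pos = np.array(starts, dtype=float)
    tag = _species_mask(pos, config.regions)
    n_samples = config.n_steps // config.lag_steps + 1
    samp = np.empty((config.n_particles, n_samples, 3))
    samp[:, 0] = pos
    si = 1
    for k in range(1, (n_samples - 1) * config.lag_steps + 1):
        noise = rng.standard_normal(pos.shape)
        pos = _step_batch(pos, config.shape, config.regions, tag, config.D_input, config.dt, noise)
        if k % config.lag_steps == 0:
            samp[:, si] = pos
            si += 1
    t = config.lag_time
    x0 = samp[:, :-1, 0].ravel()
    y0 = samp[:, :-1, 1].ravel()
    x1 = samp[:, 1:, 0].ravel()
    y1 = samp[:, 1:, 1].ravel()
    df = pd.DataFrame({"x0": x0, "y0": y0, "x1": x1, "y1": y1})
    df["r"] = np.hypot(df["x1"] - df["x0"], df["y1"] - df["y0"])
    df["t"] = t
    return df


def displacements_frame(
    x0: np.ndarray, y0: np.ndarray, x1: np.ndarray, y1: np.ndarray, t: float
) -> pd.DataFrame:
    """Assemble a canonical displacement table (columns x0, y0, x1, y1, r, t)."""
    df = pd.DataFrame({"x0": x0, "y0": y0, "x1": x1, "y1": y1})
    df["r"] = np.hypot(df["x1"] - df["x0"], df["y1"] - df["y0"])
    df["t"] = t
    return df
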