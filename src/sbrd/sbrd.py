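"""Simulation-based Reconstructed Diffusion (SbRD).

The apparent diffusion coefficient measured from planar displacements in a
small compartment underestimates the true one: reflections at the wall
shorten observed displacements and the 2D projection discards the z
component of motion. SbRD inverts this bias per pixel (or per region) by
forward simulation: the observed displacement start points are re-embedded
in 3D (z drawn uniform over the local chord of the spherocylinder), short
Brownian simulations with reflecting walls are run from those starts at a
candidate diffusion coefficient, and the candidate is adjusted until the
simulated apparent coefficient matches the measured one. The matching
candidate is the confinement-corrected coefficient D_cc; the search is
repeated with fresh z assignments and simulation noise and the repeats are
averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import RegionLabel, Spherocylinder
from .smdm import DEFAULT_MIN_PER_PIXEL, PixelDiffusionMap, fit_region, region_of_displacements
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "SbRDConfig",
    "SbRDIterationTrace",
    "SbRDResult",
    "ConfinementCorrector",
    "assign_z",
    "simulate_pixel",
    "correct_pixel",
    "correct_map",
    "correct_region",
]


@dataclass
class SbRDConfig:
    """Tunables of the recursive correction.

    ``n_repeats`` whole searches are run per pixel, each with its own z
    assignment and Gaussian step noise held fixed during the search (common
    random numbers), and the minimizing candidates are averaged.
    """

    n_repeats: int = 10
    dt: float = 1e-4
    lag_steps: int = 15
    particle_multiplier: int = 1
    tol: float = 1e-3  # um^2/s, search tolerance on D
    bounds: tuple[float, float] = (1e-3, 200.0)
    seed: int | None = None
    # when the measured target came from the truncated (pairing-cutoff) PDF,
    # simulated displacements are fitted with the matching truncated
    # estimator so both sides of the recursion estimate the same quantity
    fit_r_max: float | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.bounds[0] <= 0 or self.bounds[1] <= self.bounds[0]:
            raise ValueError("bounds must be positive and increasing")

    @property
    def lag_time(self) -> float:
        return self.lag_steps * self.dt


@dataclass
class SbRDIterationTrace:
    candidates: list = field(default_factory=list)  # D_input^i
    outputs: list = field(default_factory=list)  # simulated D_output^i
    epsilon: list = field(default_factory=list)  # squared difference
    best: float = np.nan

    def record(self, d_in: float, d_out: float, target: float) -> None:
        self.candidates.append(float(d_in))
        self.outputs.append(float(d_out))
        self.epsilon.append(float((d_out - target) ** 2))

    @property
    def n_evaluations(self) -> int:
        return len(self.candidates)


@dataclass
class SbRDResult:
    """Corrected map plus diagnostics.

    ``D_cc`` is defined exactly on the pixels where the apparent-map fit
    succeeded; ``difference`` is corrected minus apparent, elementwise.
    """

    D_cc: np.ndarray
    difference: np.ndarray
    repeats: np.ndarray  # (n_repeats, ny, nx)
    D_app: np.ndarray
    region_summary: dict = field(default_factory=dict)


def assign_z(
    starts_xy: np.ndarray, shape: Spherocylinder, rng: np.random.Generator
) -> np.ndarray:
    """Re-embed planar starts in 3D: z ~ Uniform(-h/2, +h/2) with h the local
    chord. Starts marginally outside the outline (localization error) are
    projected to the nearest interior point, 1 nm inside."""
    xy = np.atleast_2d(np.asarray(starts_xy, dtype=float))
    xy = shape.project_inside(xy, inset=1e-3)
    h = shape.thickness(xy)
    z = rng.uniform(-0.5, 0.5, size=xy.shape[0]) * h
    return np.column_stack([xy, z])


def _simulate_forward(
    candidate_D: float,
    starts3d: np.ndarray,
    shape: Spherocylinder,
    noise: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Advance starts through len(noise) reflected steps; returns endpoints."""
    pos = starts3d
    scale = np.sqrt(2.0 * candidate_D * dt)
    for k in range(noise.shape[1]):
        pos = shape.reflect_steps(pos, pos + scale * noise[:, k, :])
    return pos


def simulate_pixel(
    candidate_D: float,
    starts3d: np.ndarray,
    shape: Spherocylinder,
    config: SbRDConfig,
    noise: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulated apparent coefficient for one candidate D.

    Runs ``lag_steps`` reflected Brownian steps from the given 3D starts,
    projects the endpoints, and applies the background-free Rayleigh MLE
    D = mean(r^2) / (4 t) to the planar displacements. With ``noise`` fixed
    (common random numbers) the result is deterministic and nondecreasing in
    the candidate.
    """
    if starts3d.shape[0] < 1:
        raise ValueError("simulate_pixel needs at least one start")
    if candidate_D <= 0:
        return 0.0
    if noise is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        noise = rng.standard_normal((starts3d.shape[0], config.lag_steps, 3))
    end = _simulate_forward(candidate_D, starts3d, shape, noise, config.dt)
    r2 = (end[:, 0] - starts3d[:, 0]) ** 2 + (end[:, 1] - starts3d[:, 1]) ** 2
    if config.fit_r_max is not None:
        from .smdm import fit_truncated_rayleigh

        return fit_truncated_rayleigh(np.sqrt(r2), config.lag_time, config.fit_r_max)
    return float(np.mean(r2) / (4.0 * config.lag_time))


def _search_matching_D(
    target: float,
    starts3d: np.ndarray,
    shape: Spherocylinder,
    config: SbRDConfig,
    noise: np.ndarray,
    trace: SbRDIterationTrace,
) -> float:
    """Find candidate D whose simulated apparent D matches the target.

    The squared difference (simulate(D) - target)^2 is minimized. Because
    the simulated output is monotone in D under common random numbers, the
    minimum is the root of simulate(D) - target, found by bracket expansion
    and Brent's method; bounded scalar minimization is the fallback when no
    sign change exists inside the bounds.
    """
    lo_b, hi_b = config.bounds
    target = float(target)

    def g(d: float) -> float:
        out = simulate_pixel(d, starts3d, shape, config, noise=noise)
        trace.record(d, out, target)
        return out - target

    # initialize at the apparent value: confinement means g(target) <= 0 almost always
    d0 = min(max(target, lo_b), hi_b)
    g0 = g(d0)
    if abs(g0) < config.tol:
        return d0
    if g0 < 0:
        lo, glo = d0, g0
        hi = d0
        for _ in range(60):
            hi = min(hi * 1.5, hi_b)
            ghi = g(hi)
            if ghi >= 0:
                return float(optimize.brentq(g, lo, hi, xtol=config.tol))
            lo, glo = hi, ghi
            if hi >= hi_b:
                break
        return hi_b
    lo = d0
    for _ in range(60):
        lo = max(lo / 1.5, lo_b)
        glo = g(lo)
        if glo <= 0:
            return float(optimize.brentq(g, lo, d0, xtol=config.tol))
        if lo <= lo_b:
            break
    return lo_b


def correct_pixel(
    D_smdm: float,
    starts_xy: np.ndarray,
    shape: Spherocylinder,
    config: SbRDConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[SbRDIterationTrace]]:
    """Confinement-corrected D for one pixel (or pooled region).

    Repeats the matching search ``n_repeats`` times with fresh z assignments
    and noise; returns the mean of the per-repeat minimizing candidates and
    the iteration traces.
    """
    if not np.isfinite(D_smdm) or D_smdm <= 0:
        raise ValueError("D_smdm must be positive")
    xy = np.atleast_2d(np.asarray(starts_xy, dtype=float))
    if xy.shape[0] == 0:
        raise ValueError("no starts for this pixel")
    if config.particle_multiplier > 1:
        xy = np.repeat(xy, config.particle_multiplier, axis=0)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    estimates = []
    traces = []
    for _ in range(config.n_repeats):
        starts3d = assign_z(xy, shape, rng)
        noise = rng.standard_normal((starts3d.shape[0], config.lag_steps, 3))
        trace = SbRDIterationTrace()
        try:
            d_cc = _search_matching_D(D_smdm, starts3d, shape, config, noise, trace)
        except Exception as exc:  # pragma: no cover - numeric edge cases
            logger.warning("SbRD repeat failed: %s", exc)
            continue
        trace.best = d_cc
        estimates.append(d_cc)
        traces.append(trace)
    if not estimates:
        return np.nan, traces
    return float(np.mean(estimates)), traces


def correct_map(
    shape: Spherocylinder,
    pixmap: PixelDiffusionMap,
    displacements: pd.DataFrame,
    config: SbRDConfig,
    frame_coords: bool = False,
) -> SbRDResult:
    """Apply the per-pixel correction across a fitted diffusion map.

    The displacement start points provide the simulation starts of their
    pixel. For dividing cells, attach the septum plane to ``shape`` before
    calling; the reflecting wall is then active in every simulation.
    """
    starts = displacements[["x0", "y0"]].to_numpy()
    if not frame_coords:
        starts = shape.billiard.to_frame(starts)
    ny, nx = pixmap.shape
    D_cc = np.full((ny, nx), np.nan)
    repeats = np.full((config.n_repeats, ny, nx), np.nan)
    rng = np.random.default_rng(config.seed)
    fitted = np.argwhere(pixmap.fitted_mask())
    for jy, jx in fitted:
        sel = (pixmap.pixel_of[:, 0] == jx) & (pixmap.pixel_of[:, 1] == jy)
        if not np.any(sel):
            continue
        d_app = pixmap.D[jy, jx]
        try:
            d_cc, traces = correct_pixel(d_app, starts[sel], shape, config, rng=rng)
        except ValueError:
            continue
        D_cc[jy, jx] = d_cc
        for ri, tr in enumerate(traces):
            repeats[ri, jy, jx] = tr.best
    diff = D_cc - pixmap.D
    return SbRDResult(D_cc, diff, repeats, pixmap.D.copy())


def correct_region(
    shape: Spherocylinder,
    displacements: pd.DataFrame,
    region: RegionLabel | Sequence[RegionLabel],
    config: SbRDConfig,
    r_max: float = 0.6,
    background: bool = True,
    min_n: int = DEFAULT_MIN_PER_PIXEL,
    frame_coords: bool = False,
    D_app: float | None = None,
) -> tuple[float, float]:
    """Region-level correction: pooled apparent fit, then the same recursion
    with the region's pooled starts. Returns (D_cc, D_app)."""
    b = shape.billiard
    if D_app is None:
        D_app, _, status = fit_region(
            b, displacements, region, r_max=r_max, min_n=min_n,
            background=background, frame_coords=frame_coords,
        )
        if status != "ok":
            return np.nan, np.nan
    wanted = {region} if isinstance(region, RegionLabel) else set(region)
    labels = region_of_displacements(b, displacements, frame_coords=frame_coords)
    sel = np.array([lab in wanted for lab in labels])
    starts = displacements.loc[sel, ["x0", "y0"]].to_numpy()
    if not frame_coords:
        starts = b.to_frame(starts)
    rng = np.random.default_rng(config.seed)
    if background and config.fit_r_max is None:
        from dataclasses import replace

        config = replace(config, fit_r_max=r_max)
    d_cc, _ = correct_pixel(D_app, starts, shape, config, rng=rng)
    return d_cc, float(D_app)


class ConfinementCorrector(BaseEstimator):
    """Estimator form of the SbRD correction for one cell.

    Parameters mirror :class:`SbRDConfig`; ``mode`` selects per-pixel map
    correction ("map") or pooled region correction ("regions").

    Attributes
    ----------
    result_ : SbRDResult (map mode)
    D_cc_center_, D_cc_poles_ : float (regions mode)
    ratio_ : float
        Corrected pole/center ratio (regions mode).
    """

    def __init__(
        self,
        mode: str = "regions",
        n_repeats: int = 10,
        dt: float = 1e-4,
        lag_steps: int = 15,
        bounds: tuple[float, float] = (1e-3, 200.0),
        tol: float = 1e-3,
        background: bool = True,
        r_max: float = 0.6,
        seed: int | None = None,
    ):
        self.mode = mode
        self.n_repeats = n_repeats
        self.dt = dt
        self.lag_steps = lag_steps
        self.bounds = bounds
        self.tol = tol
        self.background = background
        self.r_max = r_max
        self.seed = seed

    def _config(self) -> SbRDConfig:
        return SbRDConfig(
            n_repeats=self.n_repeats,
            dt=self.dt,
            lag_steps=self.lag_steps,
            bounds=self.bounds,
            tol=self.tol,
            seed=self.seed,
        )

    def fit(self, X, y=None, shape: Spherocylinder = None, pixmap: PixelDiffusionMap = None):
        """X: displacement DataFrame of one cell (lab-frame coordinates)."""
        if shape is None:
            raise ValueError("shape (Spherocylinder) is required")
        cfg = self._config()
        if self.mode == "map":
            if pixmap is None:
                raise ValueError("pixmap is required in map mode")
            self.result_ = correct_map(shape, pixmap, X, cfg)
            return self
        poles = (RegionLabel.POLE_LEFT, RegionLabel.POLE_RIGHT)
        self.D_cc_center_, self.D_app_center_ = correct_region(
            shape, X, RegionLabel.CENTER, cfg, r_max=self.r_max, background=self.background
        )
        self.D_cc_poles_, self.D_app_poles_ = correct_region(
            shape, X, poles, cfg, r_max=self.r_max, background=self.background
        )
        self.ratio_ = self.D_cc_poles_ / self.D_cc_center_
        return self
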