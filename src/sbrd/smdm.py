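"""Single-molecule displacement mapping (SMdM).

Localizations from consecutive stroboscopic frame pairs are matched into
displacements, binned into a 100 nm pixel grid per cell, and each pixel's
displacement distribution is fitted by maximum likelihood. Two displacement
PDFs are used:

- in vivo (with pairing-ambiguity background), on 0 <= r <= r_max::

      p(r, t) = [ (2r / 4Dt) exp(-r^2 / 4Dt) + k r ]
                / [ 1 - exp(-r_max^2 / 4Dt) + k r_max^2 / 2 ]

  with diffusion coefficient D and linear background density k. The
  denominator normalizes p to integrate to 1 on [0, r_max].

- simulated data (no background): the plain 2D Rayleigh form
  p(r, t) = (2r / 4Dt) exp(-r^2 / 4Dt), whose MLE is the closed form
  D = sum(r^2) / (4 n t).

Region-level fits pool all displacements starting in a cell region (poles or
center), and the diffusion-vs-complex-mass relation is summarized by the
power law D = alpha * M^beta.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .geometry import Billiard, RegionLabel

__all__ = [
    "Displacement",
    "PixelDiffusionMap",
    "PowerLawFit",
    "DisplacementDiffusionMLE",
    "PowerLawMassScaling",
    "pair_peaks",
    "filter_cell_displacements",
    "pdf_sim",
    "pdf_invivo",
    "fit_pdf_invivo",
    "fit_truncated_rayleigh",
    "fit_pdf_sim",
    "build_pixel_map",
    "fit_region",
    "fit_power_law",
    "region_of_displacements",
]

MIN_DISPLACEMENTS_PER_CELL = 2000
MAX_DISPLACEMENTS_PER_CELL = 20000
DEFAULT_R_MAX = 0.6  # um, the pairing cutoff doubles as the PDF truncation
DEFAULT_PIXEL_PITCH = 0.1  # um
DEFAULT_MIN_PER_PIXEL = 10


@dataclass(frozen=True)
class Displacement:
    """One stroboscopic pair: planar start/end, distance r, lag t."""

    start: tuple[float, float]
    end: tuple[float, float]
    r: float
    t: float


# ---------------------------------------------------------------------------
# pairing and filtering
# ---------------------------------------------------------------------------


def pair_peaks(
    peaks_a: np.ndarray, peaks_b: np.ndarray, r_max: float = DEFAULT_R_MAX, t: float = 1.5e-3
) -> pd.DataFrame:
    """Match every first-frame peak with all second-frame peaks within r_max.

    All candidate pairs are kept (assignment ambiguity is absorbed by the
    linear background term of the in-vivo PDF). Output is deterministic for
    sorted input and symmetric in the order of peaks within a frame.
    """
    a = np.atleast_2d(np.asarray(peaks_a, dtype=float))
    b = np.atleast_2d(np.asarray(peaks_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return pd.DataFrame(columns=["x0", "y0", "x1", "y1", "r", "t"])
    tree = cKDTree(b)
    pairs = tree.query_ball_point(a, r_max)
    ia = np.repeat(np.arange(a.shape[0]), [len(p) for p in pairs])
    ib = (
        np.concatenate([np.sort(np.asarray(p, dtype=int)) for p in pairs if p])
        if ia.size
        else np.empty(0, dtype=int)
    )
    df = pd.DataFrame(
        {
            "x0": a[ia, 0],
            "y0": a[ia, 1],
            "x1": b[ib, 0],
            "y1": b[ib, 1],
        }
    )
    df["r"] = np.hypot(df.x1 - df.x0, df.y1 - df.y0)
    df["t"] = t
    return df[df["r"] <= r_max].reset_index(drop=True)


def filter_cell_displacements(
    displacements: pd.DataFrame,
    min_n: int = MIN_DISPLACEMENTS_PER_CELL,
    max_n: int = MAX_DISPLACEMENTS_PER_CELL,
) -> bool:
    """Accept a cell only if its displacement count is within [min_n, max_n]."""
    n = len(displacements)
    return min_n <= n <= max_n


# ---------------------------------------------------------------------------
# displacement-PDF fits
# ---------------------------------------------------------------------------


def pdf_sim(r: np.ndarray, D: float, t: float) -> np.ndarray:
    """2D Rayleigh displacement PDF for simulated data (no background)."""
    r = np.asarray(r, dtype=float)
    four_dt = 4.0 * D * t
    return (2.0 * r / four_dt) * np.exp(-(r * r) / four_dt)


def pdf_invivo(r: np.ndarray, D: float, k: float, t: float, r_max: float = DEFAULT_R_MAX) -> np.ndarray:
    """Truncated displacement PDF with linear pairing-ambiguity background.

    Normalized to integrate to 1 on [0, r_max] for any (D, k, t, r_max).
    """
    r = np.asarray(r, dtype=float)
    four_dt = 4.0 * D * t
    norm = 1.0 - np.exp(-(r_max * r_max) / four_dt) + 0.5 * k * r_max * r_max
    return ((2.0 * r / four_dt) * np.exp(-(r * r) / four_dt) + k * r) / norm


def _nll_invivo(params: np.ndarray, r: np.ndarray, t: float, r_max: float) -> float:
    D, k = params
    four_dt = 4.0 * D * t
    dens = (2.0 * r / four_dt) * np.exp(-(r * r) / four_dt) + k * r
    norm = 1.0 - np.exp(-(r_max * r_max) / four_dt) + 0.5 * k * r_max * r_max
    if norm <= 0 or np.any(dens <= 0):
        return 1e12  # finite penalty keeps quasi-Newton line searches stable
    return -float(np.sum(np.log(dens)) - r.size * np.log(norm))


def fit_pdf_sim(displacements: pd.DataFrame | np.ndarray, t: float | None = None) -> float:
    """Background-free Rayleigh MLE: D = sum(r^2) / (4 n t) (closed form)."""
    if isinstance(displacements, pd.DataFrame):
        r = displacements["r"].to_numpy()
        if t is None:
            t = float(displacements["t"].iloc[0])
    else:
        r = np.asarray(displacements, dtype=float)
        if t is None:
            raise ValueError("t is required when passing raw r values")
    if r.size == 0:
        raise ValueError("no displacements to fit")
    return float(np.sum(r * r) / (4.0 * r.size * t))


def fit_truncated_rayleigh(
    r: np.ndarray, t: float, r_max: float = DEFAULT_R_MAX
) -> float:
    """Background-free MLE under the Rayleigh PDF truncated to [0, r_max].

    Solves the score equation exactly (Brent), correcting for the mass the
    truncation removes; reduces to sum(r^2)/(4 n t) as r_max -> infinity.
    """
    r = np.asarray(r, dtype=float)
    r = r[r <= r_max]
    if r.size == 0:
        raise ValueError("no displacements within r_max")
    n = r.size
    sum_r2_4t = float(np.sum(r * r)) / (4.0 * t)
    a = r_max * r_max / (4.0 * t)
    if sum_r2_4t == 0:
        return 0.0

    def score(D: float) -> float:
        u = math.exp(-a / D)
        return -n * D + sum_r2_4t + n * u * a / (1.0 - u)

    lo, hi = 1e-9, 1e5
    if score(hi) > 0:  # pathological: nearly all mass at the cutoff
        return sum_r2_4t / n
    return float(optimize.brentq(score, lo, hi, xtol=1e-10, rtol=1e-12))


def fit_pdf_invivo(
    displacements: pd.DataFrame | np.ndarray,
    t: float | None = None,
    r_max: float = DEFAULT_R_MAX,
    min_n: int = DEFAULT_MIN_PER_PIXEL,
) -> tuple[float, float, str]:
    """Truncated Rayleigh-plus-background MLE; returns (D, k, status).

    Status is "ok", "skipped" (fewer than ``min_n`` displacements) or
    "failed" (optimizer non-convergence). Multi-start: the moment estimate
    with k = 0, plus a median-based D (robust to background contamination)
    paired with moderate background levels, since the likelihood in (D, k)
    can trap a single descent at the k = 0 boundary.
    """
    if isinstance(displacements, pd.DataFrame):
        r = displacements["r"].to_numpy()
        if t is None:
            t = float(displacements["t"].iloc[0])
    else:
        r = np.asarray(displacements, dtype=float)
        if t is None:
            raise ValueError("t is required when passing raw r values")
    r = r[r <= r_max]
    if r.size < min_n:
        return np.nan, np.nan, "skipped"
    d_mom = max(float(np.sum(r * r) / (4.0 * r.size * t)), 1e-6)
    d_med = max(float(np.median(r)) ** 2 / (4.0 * t * math.log(2.0)), 1e-6)
    # k levels corresponding to ~5% and ~20% background mass
    k_of = lambda frac: 2.0 * frac / (r_max * r_max * (1.0 - frac))
    starts = [
        np.array([d_mom, 0.0]),
        np.array([d_med, k_of(0.05)]),
        np.array([d_med, k_of(0.20)]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll_invivo,
            x0=x0,
            args=(r, t, r_max),
            method="L-BFGS-B",
            bounds=[(1e-6, 1e4), (0.0, 1e6)],
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return np.nan, np.nan, "failed"
    return float(best.x[0]), float(best.x[1]), "ok"


class DisplacementDiffusionMLE(BaseEstimator):
    """Diffusion-coefficient MLE on a set of planar displacements.

    Parameters
    ----------
    background : bool
        If True, fit the truncated PDF with the linear background term
        (in-vivo data); if False, use the closed-form Rayleigh MLE
        (simulated data).
    r_max : float
        Truncation radius of the in-vivo PDF (the pairing cutoff), um.
    min_n : int
        Minimum number of displacements to attempt a fit.

    Attributes
    ----------
    D_ : float
        Fitted diffusion coefficient, um^2/s.
    k_ : float
        Fitted background density (background fits only), um^-2.
    status_ : str
        "ok", "skipped" or "failed".
    """

    def __init__(self, background: bool = True, r_max: float = DEFAULT_R_MAX, min_n: int = DEFAULT_MIN_PER_PIXEL):
        self.background = background
        self.r_max = r_max
        self.min_n = min_n

    def fit(self, X, y=None, t: float | None = None):
        """X: displacement DataFrame (columns r, t) or array of r values."""
        if self.background:
            self.D_, self.k_, self.status_ = fit_pdf_invivo(X, t=t, r_max=self.r_max, min_n=self.min_n)
        else:
            if (isinstance(X, pd.DataFrame) and len(X) < self.min_n) or (
                not isinstance(X, pd.DataFrame) and np.size(X) < self.min_n
            ):
                self.D_, self.k_, self.status_ = np.nan, np.nan, "skipped"
            else:
                self.D_ = fit_pdf_sim(X, t=t)
                self.k_ = 0.0
                self.status_ = "ok"
        return self


# ---------------------------------------------------------------------------
# pixel maps
# ---------------------------------------------------------------------------


@dataclass
class PixelDiffusionMap:
    """Per-cell grid of displacement sets and fitted (D, k) values.

    The grid lives in the billiard frame, anchored at the billiard's centre;
    a displacement belongs to the pixel containing its start point, with
    half-open pixel intervals [lo, hi).
    """

    origin: tuple[float, float]  # frame coordinates of pixel (0, 0) lower corner
    pixel_pitch: float
    D: np.ndarray  # (ny, nx), nan where not fitted
    k: np.ndarray
    n: np.ndarray  # displacement counts
    status: np.ndarray  # object array of fit statuses
    pixel_of: np.ndarray  # (n_disp, 2) integer (ix, iy) per displacement, -1 outside grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.D.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.D.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_pitch
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_pitch
        return xs, ys

    def fitted_mask(self) -> np.ndarray:
        return np.isfinite(self.D)


def build_pixel_map(
    billiard: Billiard,
    displacements: pd.DataFrame,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    min_n: int = DEFAULT_MIN_PER_PIXEL,
    r_max: float = DEFAULT_R_MAX,
    background: bool = True,
    frame_coords: bool = False,
) -> PixelDiffusionMap:
    """Bin displacements by start pixel and fit the displacement PDF per pixel.

    ``displacements`` carries lab-frame start/end coordinates unless
    ``frame_coords`` is set. Pixels with fewer than ``min_n`` displacements
    are skipped.
    """
    starts = displacements[["x0", "y0"]].to_numpy()
    if not frame_coords:
        starts = billiard.to_frame(starts)
    t = float(displacements["t"].iloc[0]) if len(displacements) else 1.5e-3
    half_l = billiard.length / 2.0
    r = billiard.radius
    cx, cy = billiard.center_frame
    nx = int(np.ceil(2 * half_l / pixel_pitch))
    ny = int(np.ceil(2 * r / pixel_pitch))
    origin = (cx - nx * pixel_pitch / 2.0, cy - ny * pixel_pitch / 2.0)
    ix = np.floor((starts[:, 0] - origin[0]) / pixel_pitch).astype(int)
    iy = np.floor((starts[:, 1] - origin[1]) / pixel_pitch).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    pixel_of = np.full((len(displacements), 2), -1, dtype=int)
    pixel_of[inside, 0] = ix[inside]
    pixel_of[inside, 1] = iy[inside]

    D = np.full((ny, nx), np.nan)
    k = np.full((ny, nx), np.nan)
    n = np.zeros((ny, nx), dtype=int)
    status = np.full((ny, nx), "skipped", dtype=object)
    rvals = displacements["r"].to_numpy()
    flat = iy * nx + ix
    flat[~inside] = -1
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    uniq, starts_idx = np.unique(sorted_flat, return_index=True)
    bounds = np.append(starts_idx, len(sorted_flat))
    for ui, f in enumerate(uniq):
        if f < 0:
            continue
        sel = order[bounds[ui] : bounds[ui + 1]]
        jy, jx = divmod(int(f), nx)
        n[jy, jx] = sel.size
        if sel.size < min_n:
            continue
        if background:
            d_hat, k_hat, st = fit_pdf_invivo(rvals[sel], t=t, r_max=r_max, min_n=min_n)
        else:
            d_hat, k_hat, st = fit_pdf_sim(rvals[sel], t=t), 0.0, "ok"
        D[jy, jx], k[jy, jx], status[jy, jx] = d_hat, k_hat, st
    return PixelDiffusionMap(origin, pixel_pitch, D, k, n, status, pixel_of)


# ---------------------------------------------------------------------------
# region fits
# ---------------------------------------------------------------------------


def region_of_displacements(billiard: Billiard, displacements: pd.DataFrame, frame_coords: bool = False) -> np.ndarray:
    """Region label per displacement from its start point; None if outside."""
    starts = displacements[["x0", "y0"]].to_numpy()
    if not frame_coords:
        starts = billiard.to_frame(starts)
    labels = np.empty(len(displacements), dtype=object)
    labels[:] = None
    ins = billiard.contains(starts)
    if np.any(ins):
        lab = np.empty(int(ins.sum()), dtype=object)
        lab[:] = RegionLabel.CENTER
        sx = starts[ins, 0]
        lab[sx < billiard.cx_left] = RegionLabel.POLE_LEFT
        lab[sx > billiard.cx_right] = RegionLabel.POLE_RIGHT
        labels[ins] = lab
    return labels


def fit_region(
    billiard: Billiard,
    displacements: pd.DataFrame,
    region: RegionLabel | Sequence[RegionLabel],
    r_max: float = DEFAULT_R_MAX,
    min_n: int = DEFAULT_MIN_PER_PIXEL,
    background: bool = True,
    frame_coords: bool = False,
) -> tuple[float, float, str]:
    """Pooled displacement-PDF fit over one region (or several, e.g. both poles)."""
    wanted = {region} if isinstance(region, RegionLabel) else set(region)
    labels = region_of_displacements(billiard, displacements, frame_coords=frame_coords)
    sel = np.array([lab in wanted for lab in labels])
    sub = displacements.loc[sel]
    if len(sub) < min_n:
        return np.nan, np.nan, "skipped"
    if background:
        return fit_pdf_invivo(sub, r_max=r_max, min_n=min_n)
    return fit_pdf_sim(sub), 0.0, "ok"


# ---------------------------------------------------------------------------
# diffusion vs complex mass
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    """D = alpha * M^beta across protein complexes of mass M (kDa)."""

    alpha: float
    beta: float
    masses: tuple[float, ...]
    D: tuple[float, ...]

    @property
    def viscosity_exponent(self) -> float:
        """Exponent of the perceived-viscosity power law eta ~ M^gamma.

        Einstein-Stokes predicts D ~ 1/(eta * R) with R ~ M^(1/3); a measured
        D ~ M^beta therefore implies eta ~ M^(-beta - 1/3).
        """
        return -self.beta - 1.0 / 3.0

    def predict(self, masses: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(masses, dtype=float) ** self.beta


def fit_power_law(points: Iterable[tuple[float, float]]) -> PowerLawFit:
    """Nonlinear least squares for D = alpha * M^beta over >= 3 (M, D) pairs."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("power-law fit requires at least 3 (mass, D) points")
    if np.any(pts <= 0):
        raise ValueError("masses and diffusion coefficients must be positive")
    m, d = pts[:, 0], pts[:, 1]
    # log-log regression provides the starting point for the NLS fit
    b0, loga0 = np.polyfit(np.log(m), np.log(d), 1)
    popt, _ = optimize.curve_fit(
        lambda x, a, b: a * x**b, m, d, p0=[np.exp(loga0), b0], maxfev=10000
    )
    return PowerLawFit(float(popt[0]), float(popt[1]), tuple(m), tuple(d))


class PowerLawMassScaling(BaseEstimator):
    """Estimator form of the diffusion-vs-mass power law.

    Attributes after fit: ``alpha_``, ``beta_``, ``viscosity_exponent_``.
    """

    def fit(self, X, y=None):
        """X: (n, 2) array of (complex mass kDa, D um^2/s), or X=masses with y=D."""
        if y is not None:
            X = np.column_stack([np.ravel(X), np.ravel(y)])
        fitres = fit_power_law(np.asarray(X, dtype=float))
        self.alpha_ = fitres.alpha
        self.beta_ = fitres.beta
        self.viscosity_exponent_ = fitres.viscosity_exponent
        self.result_ = fitres
        return self

    def predict(self, masses):
        return self.result_.predict(masses)
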