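"""Maximum-likelihood detection of cells as billiards in localization fields.

A field of view is first histogrammed and thresholded to separate cell point
clouds from background, each cloud is rotated to its principal axis for an
initial billiard guess, and the guess is refined by maximizing the mixture
likelihood

    p_i = ( h_i / V + 1 / N ) / 2

per localization, where h_i is the thickness of the candidate spherocylinder
at the point, V its volume and N the cloud size: a localization is equally
likely to be a fluorophore (density proportional to cell thickness, h/V) or
uniform noise (1/N). Abnormally long fits are re-analyzed as dividing pairs
with a joint two-billiard likelihood whose volume is corrected by the
cap-sphere intersection lens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator

from .geometry import (
    Billiard,
    GeometryError,
    RegionLabel,
    Spherocylinder,
    intersect_dividing,
    lens_volume,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "CellFit",
    "BilliardDetector",
    "background_filter",
    "initial_guess",
    "refine_mle",
    "refine_mle_dividing",
    "apply_shape_filters",
    "detect_cells",
]

MIN_LENGTH = 0.65  # um; shorter fits are discarded (cells cut by the FOV edge)
MAX_WIDTH = 1.5  # um; wider fits are discarded (noise or drift)
SPLIT_LENGTH = 3.0  # um; longer fits are re-analyzed as dividing pairs

_BOUNDS = {"length": (0.3, 6.0), "radius": (0.15, 1.0)}


@dataclass
class PointCloud:
    points: np.ndarray  # (n, 2) lab-frame um
    fov_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")


@dataclass
class CellFit:
    billiard: Billiard
    loglik: float
    n_points: int
    qc_flags: set = field(default_factory=set)
    divided: bool = False
    sibling: int | None = None
    new_pole_side: RegionLabel | None = None
    old_pole_side: RegionLabel | None = None
    cell_id: int | None = None

    @property
    def passed_qc(self) -> bool:
        return not self.qc_flags

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "billiard": self.billiard.to_dict(),
            "loglik": self.loglik,
            "n_points": self.n_points,
            "qc_flags": sorted(self.qc_flags),
            "divided": self.divided,
            "sibling": self.sibling,
            "new_pole_side": self.new_pole_side.value if self.new_pole_side else None,
            "old_pole_side": self.old_pole_side.value if self.old_pole_side else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellFit":
        return cls(
            billiard=Billiard.from_dict(d["billiard"]),
            loglik=d["loglik"],
            n_points=d["n_points"],
            qc_flags=set(d.get("qc_flags", [])),
            divided=d.get("divided", False),
            sibling=d.get("sibling"),
            new_pole_side=RegionLabel(d["new_pole_side"]) if d.get("new_pole_side") else None,
            old_pole_side=RegionLabel(d["old_pole_side"]) if d.get("old_pole_side") else None,
            cell_id=d.get("cell_id"),
        )


# ---------------------------------------------------------------------------
# background filtering
# ---------------------------------------------------------------------------


def background_filter(
    localizations: pd.DataFrame | np.ndarray, bin_size: float = 0.1, n_sigma: float = 1.0
) -> list[PointCloud]:
    """Histogram the field of view and keep points in above-background bins.

    Background is the median bin count; bins above median + n_sigma * SD (SD
    over all bins) are kept, and 8-connected groups of kept bins define the
    point clouds.
    """
    if isinstance(localizations, pd.DataFrame):
        pts = localizations[["x_um", "y_um"]].to_numpy()
    else:
        pts = np.atleast_2d(np.asarray(localizations, dtype=float))
    if pts.size == 0:
        logger.info("background_filter: empty localization table")
        return []
    x, y = pts[:, 0], pts[:, 1]
    nx = max(int(np.ceil((x.max() - x.min()) / bin_size)), 1)
    ny = max(int(np.ceil((y.max() - y.min()) / bin_size)), 1)
    hist, xe, ye = np.histogram2d(x, y, bins=[nx, ny])
    thresh = np.median(hist) + n_sigma * hist.std()
    keep = hist > thresh
    labels, n_lab = ndimage.label(keep, structure=np.ones((3, 3)))
    if n_lab == 0:
        logger.info("background_filter: no bins above threshold %.2f", thresh)
        return []
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, ny - 1)
    point_label = labels[ix, iy]
    clouds = []
    for lab in range(1, n_lab + 1):
        sel = point_label == lab
        if sel.sum() >= 3:
            clouds.append(PointCloud(pts[sel], fov_id=str(lab)))
    return clouds


# ---------------------------------------------------------------------------
# initial guess and MLE refinement
# ---------------------------------------------------------------------------


def initial_guess(cloud: PointCloud | np.ndarray) -> Billiard:
    """PCA-based billiard encompassing the point cloud.

    The cloud is rotated so its first principal axis is parallel to x;
    length, width and centre come from the rotated extents.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.atleast_2d(np.asarray(cloud, float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for an initial guess")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1e-30):
        raise ValueError("degenerate (collinear) point cloud")
    major = evecs[:, np.argmax(evals)]
    angle = math.atan2(major[1], major[0])
    if angle > math.pi / 2:
        angle -= math.pi
    elif angle < -math.pi / 2:
        angle += math.pi
    c, s = math.cos(-angle), math.sin(-angle)
    rot = pts @ np.array([[c, -s], [s, c]]).T
    length = float(rot[:, 0].max() - rot[:, 0].min())
    radius = float(rot[:, 1].max() - rot[:, 1].min()) / 2.0
    radius = min(max(radius, _BOUNDS["radius"][0]), _BOUNDS["radius"][1])
    length = max(length, 2 * radius)
    center_lab = np.array(
        [
            (pts[:, 0].max() + pts[:, 0].min()) / 2.0,
            (pts[:, 1].max() + pts[:, 1].min()) / 2.0,
        ]
    )
    # midrange in the rotated frame is more faithful for tilted clouds
    center_rot = np.array(
        [(rot[:, 0].max() + rot[:, 0].min()) / 2.0, (rot[:, 1].max() + rot[:, 1].min()) / 2.0]
    )
    c2, s2 = math.cos(angle), math.sin(angle)
    center_lab = np.array([[c2, -s2], [s2, c2]]) @ center_rot
    return Billiard.from_center(center_lab, length, radius, angle)


def _params_of(b: Billiard) -> np.ndarray:
    c = b.center_lab
    return np.array([c[0], c[1], b.length, b.radius, b.angle])


def _billiard_of(p: np.ndarray) -> Billiard:
    return Billiard.from_center((p[0], p[1]), max(p[2], 2 * p[3]), p[3], p[4])


def _nll_single(p: np.ndarray, pts: np.ndarray) -> float:
    b = _billiard_of(p)
    sc = Spherocylinder(b)
    h = sc.thickness(b.to_frame(pts))
    n = pts.shape[0]
    return -float(np.sum(np.log((h / sc.volume() + 1.0 / n) / 2.0)))


def refine_mle(
    cloud: PointCloud | np.ndarray, guess: Billiard | None = None, multistart: bool = True
) -> CellFit:
    """Refine a billiard by maximizing the thickness/noise mixture likelihood.

    Optimizes lab-frame centre, length, radius and angle with bounded
    quasi-Newton; a small multi-start around the guess dodges local optima.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.atleast_2d(np.asarray(cloud, float))
    if guess is None:
        guess = initial_guess(pts)
    p0 = _params_of(guess)
    span = max(guess.length, 1.0)
    bounds = [
        (p0[0] - span, p0[0] + span),
        (p0[1] - span, p0[1] + span),
        _BOUNDS["length"],
        _BOUNDS["radius"],
        (p0[4] - math.pi / 4, p0[4] + math.pi / 4),
    ]
    starts = [p0]
    if multistart:
        starts += [p0 * np.array([1, 1, 0.9, 0.9, 1]), p0 * np.array([1, 1, 1.1, 1.1, 1])]
    best = None
    for s in starts:
        s = np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(_nll_single, s, args=(pts,), method="L-BFGS-B", bounds=bounds)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.fun < best.fun:
            best = res
    flags: set = set()
    if best is None or not np.all(np.isfinite(best.x)):
        logger.warning("MLE refinement failed; returning initial guess")
        return CellFit(guess, -_nll_single(p0, pts), pts.shape[0], {"fit_failed"})
    fit = CellFit(_billiard_of(best.x), -best.fun, pts.shape[0], flags)
    return fit


def _nll_pair(p: np.ndarray, pts: np.ndarray) -> float:
    b1 = _billiard_of(p[:5])
    b2 = _billiard_of(p[5:])
    s1, s2 = Spherocylinder(b1), Spherocylinder(b2)
    h = s1.thickness(b1.to_frame(pts)) + s2.thickness(b2.to_frame(pts))
    caps1 = b1.cap_centers_lab()
    caps2 = b2.cap_centers_lab()
    d = np.linalg.norm(caps1[:, None] - caps2[None, :], axis=-1).min()
    v_int = lens_volume(b1.radius, b2.radius, d)
    v = s1.volume() + s2.volume() + v_int
    n = pts.shape[0]
    return -float(np.sum(np.log((h / v + 1.0 / n) / 2.0)))


def refine_mle_dividing(
    cloud: PointCloud | np.ndarray, b1: Billiard, b2: Billiard
) -> tuple[CellFit, CellFit]:
    """Joint MLE of two billiards over one cloud (a freshly divided pair).

    The mixture density uses the summed thicknesses normalized by
    V1 + V2 + V_intersection, V_intersection being the lens of the two
    adjacent cap spheres. The caps facing each other across the septum are
    labelled as the new poles, the distal caps as the old poles.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.atleast_2d(np.asarray(cloud, float))
    p0 = np.concatenate([_params_of(b1), _params_of(b2)])
    bounds = []
    for pb in (p0[:5], p0[5:]):
        span = 1.5
        bounds += [
            (pb[0] - span, pb[0] + span),
            (pb[1] - span, pb[1] + span),
            _BOUNDS["length"],
            _BOUNDS["radius"],
            (pb[4] - math.pi / 4, pb[4] + math.pi / 4),
        ]
    res = optimize.minimize(_nll_pair, p0, args=(pts,), method="L-BFGS-B", bounds=bounds)
    f1 = _billiard_of(res.x[:5])
    f2 = _billiard_of(res.x[5:])
    flags1: set = set()
    flags2: set = set()
    try:
        inter = intersect_dividing(f1, f2)
        new1 = RegionLabel.POLE_LEFT if inter.cap_index_1 == 0 else RegionLabel.POLE_RIGHT
        new2 = RegionLabel.POLE_LEFT if inter.cap_index_2 == 0 else RegionLabel.POLE_RIGHT
    except GeometryError:
        logger.warning("dividing caps never overlap; falling back to independent fits")
        c1 = refine_mle(pts, b1)
        c2 = refine_mle(pts, b2)
        c1.qc_flags.add("split_no_overlap")
        c2.qc_flags.add("split_no_overlap")
        return c1, c2
    total_len = f1.length + f2.length
    if total_len < SPLIT_LENGTH:
        flags1.add("manual_reject")
        flags2.add("manual_reject")
    other = {RegionLabel.POLE_LEFT: RegionLabel.POLE_RIGHT, RegionLabel.POLE_RIGHT: RegionLabel.POLE_LEFT}
    loglik = -res.fun
    cf1 = CellFit(f1, loglik, pts.shape[0], flags1, divided=True, new_pole_side=new1, old_pole_side=other[new1])
    cf2 = CellFit(f2, loglik, pts.shape[0], flags2, divided=True, new_pole_side=new2, old_pole_side=other[new2])
    return cf1, cf2


def apply_shape_filters(fit: CellFit) -> CellFit:
    """QC on fitted dimensions: too-short and too-wide cells are flagged for
    discard; abnormally long cells are flagged for dividing-pair re-analysis."""
    b = fit.billiard
    if b.length < MIN_LENGTH:
        fit.qc_flags.add("too_short")
    if b.width > MAX_WIDTH:
        fit.qc_flags.add("too_wide")
    if b.length > SPLIT_LENGTH:
        fit.qc_flags.add("split_candidate")
    return fit


def _split_guess(b: Billiard) -> tuple[Billiard, Billiard]:
    """Two half-length billiards along the long axis of an over-long fit."""
    half = b.length / 2.0
    cf = b.center_frame
    off = half / 2.0
    c1 = b.to_lab(np.array([cf[0] - off, cf[1]]))
    c2 = b.to_lab(np.array([cf[0] + off, cf[1]]))
    return (
        Billiard.from_center(c1, half, b.radius, b.angle),
        Billiard.from_center(c2, half, b.radius, b.angle),
    )


def detect_cells(
    localizations: pd.DataFrame | np.ndarray, bin_size: float = 0.1
) -> list[CellFit]:
    """Full detection pipeline: background filter, per-cloud MLE, shape QC,
    dividing-pair splitting. Returns every fit with its QC flags; callers
    keep ``passed_qc`` cells."""
    clouds = background_filter(localizations, bin_size=bin_size)
    fits: list[CellFit] = []
    for cloud in clouds:
        try:
            fit = apply_shape_filters(refine_mle(cloud))
        except ValueError:
            continue
        if "split_candidate" in fit.qc_flags:
            g1, g2 = _split_guess(fit.billiard)
            c1, c2 = refine_mle_dividing(cloud, g1, g2)
            c1 = apply_shape_filters(c1)
            c2 = apply_shape_filters(c2)
            c1.qc_flags.discard("split_candidate")
            c2.qc_flags.discard("split_candidate")
            c1.cell_id = len(fits)
            c2.cell_id = len(fits) + 1
            c1.sibling, c2.sibling = c2.cell_id, c1.cell_id
            fits += [c1, c2]
        else:
            fit.cell_id = len(fits)
            fits.append(fit)
    return fits


class BilliardDetector(BaseEstimator):
    """Estimator wrapper over the detection pipeline.

    Parameters
    ----------
    bin_size : float
        Histogram bin size for background filtering, um.

    Attributes
    ----------
    cells_ : list of CellFit
        All fitted cells with QC flags.
    n_cells_ : int
        Number of QC-passing cells.
    """

    def __init__(self, bin_size: float = 0.1):
        self.bin_size = bin_size

    def fit(self, X, y=None):
        """X: localization DataFrame (columns x_um, y_um) or (n, 2) array."""
        self.cells_ = detect_cells(X, bin_size=self.bin_size)
        self.n_cells_ = sum(c.passed_qc for c in self.cells_)
        return self

    def predict(self, X):
        """Assign each localization to the index of the QC-passing cell whose
        billiard contains it (-1 if none)."""
        pts = X[["x_um", "y_um"]].to_numpy() if isinstance(X, pd.DataFrame) else np.atleast_2d(X)
        out = np.full(pts.shape[0], -1, dtype=int)
        for i, c in enumerate(self.cells_):
            if not c.passed_qc:
                continue
            ins = c.billiard.contains(c.billiard.to_frame(pts))
            out[ins & (out == -1)] = i
        return out
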