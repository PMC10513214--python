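"""Billiard and spherocylinder geometry.

A rod-shaped bacterium projected onto the image plane is modelled as a
*billiard*: a 2D stadium, i.e. a rectangle of half-width ``radius`` capped by
two half-disks. Its 3D body of revolution about the long axis is a
*spherocylinder* (capsule), which is the compartment used for Brownian
simulation and for thickness/volume queries during cell fitting.

All coordinates are in micrometres. Each billiard owns a rotated frame whose
x-axis is the cell's long axis; ``angle`` rotates the billiard frame into the
lab frame. Points are converted with :meth:`Billiard.to_frame` /
:meth:`Billiard.to_lab`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Billiard",
    "Spherocylinder",
    "SphericalRegion",
    "RegionLabel",
    "RegionMode",
    "DividingIntersection",
    "GeometryError",
    "OutOfCellError",
    "intersect_dividing",
    "classify_region",
    "lens_volume",
]


class GeometryError(RuntimeError):
    """Raised when a geometric construction fails (e.g. reflection blow-up)."""


class OutOfCellError(ValueError):
    """Raised when a point expected inside a cell lies outside it."""


class RegionLabel(str, Enum):
    POLE_LEFT = "pole_left"
    POLE_RIGHT = "pole_right"
    CENTER = "center"


class RegionMode(str, Enum):
    IMPERMEABLE = "impermeable"
    INTERACTION = "interaction"
    SPECIES = "species"


def _rot(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class Billiard:
    """2D stadium cell outline.

    Parameters are expressed in the billiard's own rotated frame: the cap
    centres sit at ``(cx_left, cy)`` and ``(cx_right, cy)`` and the straight
    section spans between them. Total length ``L = (cx_right - cx_left) + 2 r``.
    """

    cx_left: float
    cx_right: float
    cy: float
    radius: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.cx_right < self.cx_left:
            raise ValueError("cx_right must be >= cx_left")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_center(
        cls, center_lab: Sequence[float], length: float, radius: float, angle: float = 0.0
    ) -> "Billiard":
        """Build from lab-frame centroid, total length, radius and orientation."""
        if length < 2 * radius:
            # degenerate rod: collapse straight section to zero (a sphere)
            length = 2 * radius
        cf = _rot(-angle) @ np.asarray(center_lab, dtype=float)
        half = length / 2.0 - radius
        return cls(cf[0] - half, cf[0] + half, cf[1], radius, angle)

    # -- derived quantities -------------------------------------------------

    @property
    def length(self) -> float:
        return (self.cx_right - self.cx_left) + 2 * self.radius

    @property
    def width(self) -> float:
        return 2 * self.radius

    @property
    def straight_length(self) -> float:
        return self.cx_right - self.cx_left

    @property
    def center_frame(self) -> np.ndarray:
        return np.array([(self.cx_left + self.cx_right) / 2.0, self.cy])

    @property
    def center_lab(self) -> np.ndarray:
        return _rot(self.angle) @ self.center_frame

    @property
    def area(self) -> float:
        return math.pi * self.radius**2 + self.width * self.straight_length

    # -- frames -------------------------------------------------------------

    def to_frame(self, points_lab: np.ndarray) -> np.ndarray:
        """Rotate lab-frame xy points into the billiard frame."""
        return np.asarray(points_lab, dtype=float) @ _rot(-self.angle).T

    def to_lab(self, points_frame: np.ndarray) -> np.ndarray:
        return np.asarray(points_frame, dtype=float) @ _rot(self.angle).T

    # -- queries (billiard-frame coordinates) -------------------------------

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """In-plane distance to the axis segment, for frame-coordinate points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        dx = np.clip(p[..., 0], self.cx_left, self.cx_right)
        return np.hypot(p[..., 0] - dx, p[..., 1] - self.cy)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.axis_distance(points) < self.radius

    def cap_centers_lab(self) -> np.ndarray:
        """Lab-frame coordinates of the two cap (pole) centres."""
        caps = np.array([[self.cx_left, self.cy], [self.cx_right, self.cy]])
        return self.to_lab(caps)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cx_left": self.cx_left,
            "cx_right": self.cx_right,
            "cy": self.cy,
            "radius": self.radius,
            "angle": self.angle,
            "center_lab": [float(v) for v in self.center_lab],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Billiard":
        return cls(d["cx_left"], d["cx_right"], d["cy"], d["radius"], d.get("angle", 0.0))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Billiard":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class SphericalRegion:
    """Spherical sub-compartment with its own dynamics (slow pole, binding site).

    ``mode`` selects how the simulator honours the region:

    - ``impermeable``: the sphere surface reflects from both sides; particles
      keep the diffusion coefficient of the side they started on
      (``D_inside`` inside).
    - ``interaction``: particles switch to ``D_inside`` while inside and revert
      on exit; the surface is permeable.
    - ``species``: particles initialised inside belong to a distinct species
      confined to the region at ``D_inside``; all others ignore the region.
    """

    center: tuple[float, float, float]
    radius: float
    mode: RegionMode = RegionMode.INTERACTION
    D_inside: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be positive")
        if self.D_inside <= 0:
            raise ValueError("D_inside must be positive")

    def inside(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.sum((p - np.asarray(self.center)) ** 2, axis=-1) < self.radius**2


@dataclass(frozen=True)
class Spherocylinder:
    """3D capsule: the billiard's body of revolution, symmetric about z = 0.

    An optional septum (a reflecting plane parallel to the z axis, used for
    dividing cells) may be attached: ``septum_point``/``septum_normal`` are 2D
    frame coordinates; the interior is the side the normal points away from,
    i.e. points with ``(p - point) . normal < 0`` are inside.
    """

    billiard: Billiard
    septum_point: tuple[float, float] | None = None
    septum_normal: tuple[float, float] | None = None

    _MAX_BOUNCES = 100

    @property
    def radius(self) -> float:
        return self.billiard.radius

    def with_septum(self, point: Sequence[float], normal: Sequence[float]) -> "Spherocylinder":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        return Spherocylinder(self.billiard, tuple(point), tuple(n))

    # -- scalar field: positive outside, negative inside --------------------

    def _outside_margin(self, points: np.ndarray) -> np.ndarray:
        """Signed distance-like margin; > 0 outside the compartment."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        b = self.billiard
        dx = p[..., 0] - np.clip(p[..., 0], b.cx_left, b.cx_right)
        dy = p[..., 1] - b.cy
        m = np.sqrt(dx * dx + dy * dy + p[..., 2] ** 2) - b.radius
        if self.septum_point is not None:
            q = np.asarray(self.septum_point)
            n = np.asarray(self.septum_normal)
            m = np.maximum(m, (p[..., 0] - q[0]) * n[0] + (p[..., 1] - q[1]) * n[1])
        return m

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self._outside_margin(points) < 0

    # -- thickness / volume -------------------------------------------------

    def thickness(self, points_xy: np.ndarray) -> np.ndarray:
        """Chord length of the body along z at in-plane point(s); 0 outside."""
        d = self.billiard.axis_distance(points_xy)
        h2 = self.billiard.radius**2 - d * d
        return 2.0 * np.sqrt(np.maximum(h2, 0.0))

    def volume(self) -> float:
        b = self.billiard
        return math.pi * b.radius**2 * b.straight_length + 4.0 / 3.0 * math.pi * b.radius**3

    # -- sampling -----------------------------------------------------------

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniform in 3D inside the compartment (rejection)."""
        b = self.billiard
        lo = np.array([b.cx_left - b.radius, b.cy - b.radius, -b.radius])
        hi = np.array([b.cx_right + b.radius, b.cy + b.radius, b.radius])
        out = np.empty((0, 3))
        while out.shape[0] < n:
            cand = rng.uniform(lo, hi, size=(max(2 * n, 128), 3))
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]

    def project_inside(self, points_xy: np.ndarray, inset: float = 1e-3) -> np.ndarray:
        """Move in-plane points that fall outside the billiard to the nearest
        interior point, ``inset`` micrometres inside the outline."""
        p = np.atleast_2d(np.asarray(points_xy, dtype=float)).copy()
        b = self.billiard
        if self.septum_point is not None:
            q = np.asarray(self.septum_point)
            n = np.asarray(self.septum_normal)
            over = (p[:, 0] - q[0]) * n[0] + (p[:, 1] - q[1]) * n[1]
            beyond = over > -inset
            if np.any(beyond):
                p[beyond] -= (over[beyond, None] + inset) * n[None, :]
        d = b.axis_distance(p)
        bad = d >= b.radius - inset
        if np.any(bad):
            ax = np.column_stack([np.clip(p[bad, 0], b.cx_left, b.cx_right), np.full(bad.sum(), b.cy)])
            v = p[bad] - ax
            nrm = np.linalg.norm(v, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            p[bad] = ax + v / nrm * (b.radius - inset)
        return p

    # -- reflection ---------------------------------------------------------

    def reflect_steps(self, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
        """Specularly reflect segments p0 -> p1 off the inner surface.

        Both arguments are (n, 3) arrays of frame coordinates with every p0
        strictly inside. Returns the endpoints after all reflections; path
        length along each polyline equals |p1 - p0|. The compartment
        (capsule, optionally cut by the septum plane) is convex, so each
        leg crosses the boundary at most once and the crossing is located by
        bisection on the outside-margin; specular reflection about the local
        surface normal then folds the remainder back inside.
        """
        a = np.atleast_2d(np.asarray(p0, dtype=float)).copy()
        b = np.atleast_2d(np.asarray(p1, dtype=float)).copy()
        for _ in range(self._MAX_BOUNCES):
            out = self._outside_margin(b) >= 0
            if not np.any(out):
                return b
            a_o, b_o = a[out], b[out]
            s, nrm = self._first_hit(a_o, b_o)
            hit = a_o + s[:, None] * (b_o - a_o)
            w = b_o - hit
            b[out] = hit + w - 2.0 * np.sum(w * nrm, axis=1, keepdims=True) * nrm
            a[out] = hit - 1e-12 * nrm  # nudge inward to avoid re-hitting the wall
        raise GeometryError(
            f"reflection did not converge within {self._MAX_BOUNCES} bounces "
            f"for {int(np.sum(self._outside_margin(b) >= 0))} point(s); "
            "step length is likely large compared to the compartment"
        )

    def reflect_step(self, p0: Sequence[float], p1: Sequence[float]) -> np.ndarray:
        """Single-segment convenience wrapper around :meth:`reflect_steps`."""
        p0 = np.asarray(p0, dtype=float)
        if not bool(self.contains(p0[None, :])[0]):
            raise OutOfCellError("reflect_step requires p0 strictly inside the shape")
        return self.reflect_steps(p0[None, :], np.asarray(p1, dtype=float)[None, :])[0]

    def _first_hit(self, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """First boundary crossing (parameter s and outward normal) for
        inside->outside segments, solved analytically per primitive.

        The capsule surface is pieced from the open cylinder (valid for hit
        x in [cx_left, cx_right]) and the two cap spheres (valid beyond the
        respective cap centre); the septum adds a plane. Convexity of the
        compartment means the earliest valid candidate is the true crossing.
        Falls back to bisection for segments where roundoff leaves no valid
        analytic candidate.
        """
        bl = self.billiard
        n_seg = a.shape[0]
        v = b - a
        s_best = np.full(n_seg, np.inf)

        # cylinder: |(y - cy, z) + s (vy, vz)| = r, exit root
        wy = a[:, 1] - bl.cy
        wz = a[:, 2]
        A = v[:, 1] ** 2 + v[:, 2] ** 2
        B = wy * v[:, 1] + wz * v[:, 2]
        C = wy * wy + wz * wz - bl.radius**2
        disc = B * B - A * C
        with np.errstate(invalid="ignore", divide="ignore"):
            s_cyl = (-B + np.sqrt(np.maximum(disc, 0.0))) / A
        hx = a[:, 0] + s_cyl * v[:, 0]
        ok = (disc > 0) & (A > 0) & (s_cyl > 0) & (hx >= bl.cx_left) & (hx <= bl.cx_right)
        s_best = np.where(ok, s_cyl, s_best)

        # cap spheres: take the exit (larger) root, valid past the cap centre
        A_s = np.sum(v * v, axis=1)
        for ki, cx in ((1, bl.cx_left), (2, bl.cx_right)):
            w0 = a - np.array([cx, bl.cy, 0.0])
            B_s = np.sum(w0 * v, axis=1)
            C_s = np.sum(w0 * w0, axis=1) - bl.radius**2
            disc_s = B_s * B_s - A_s * C_s
            with np.errstate(invalid="ignore", divide="ignore"):
                s_sph = (-B_s + np.sqrt(np.maximum(disc_s, 0.0))) / A_s
            hx = a[:, 0] + s_sph * v[:, 0]
            side = hx <= bl.cx_left if ki == 1 else hx >= bl.cx_right
            ok = (disc_s > 0) & (A_s > 0) & (s_sph > 0) & side & (s_sph < s_best)
            s_best = np.where(ok, s_sph, s_best)

        if self.septum_point is not None:
            q = np.asarray(self.septum_point)
            sn = np.asarray(self.septum_normal)
            denom = v[:, 0] * sn[0] + v[:, 1] * sn[1]
            num = (q[0] - a[:, 0]) * sn[0] + (q[1] - a[:, 1]) * sn[1]
            with np.errstate(invalid="ignore", divide="ignore"):
                s_sep = num / denom
            ok = (denom > 0) & (s_sep >= 0) & (s_sep < s_best)
            s_best = np.where(ok, s_sep, s_best)

        bad = ~np.isfinite(s_best) | (s_best > 1.0 + 1e-9)
        if np.any(bad):
            s_best[bad] = self._crossing(a[bad], b[bad])
        s_best = np.minimum(s_best, 1.0)
        hit = a + s_best[:, None] * v
        nrm = self._normal(hit)
        return s_best, nrm

    def _crossing(self, a: np.ndarray, b: np.ndarray, iters: int = 60) -> np.ndarray:
        """Bisection for the boundary crossing parameter on inside->outside segments."""
        lo = np.zeros(a.shape[0])
        hi = np.ones(a.shape[0])
        # guard: if a is (numerically) outside, treat crossing as immediate
        bad = self._outside_margin(a) >= 0
        hi[bad] = 0.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            m = self._outside_margin(a + mid[:, None] * (b - a)) >= 0
            hi = np.where(m, mid, hi)
            lo = np.where(m, lo, mid)
        return hi

    def _normal(self, hit: np.ndarray) -> np.ndarray:
        """Outward unit normal at boundary points (capsule wall or septum)."""
        bl = self.billiard
        ax = np.column_stack(
            [
                np.clip(hit[:, 0], bl.cx_left, bl.cx_right),
                np.full(hit.shape[0], bl.cy),
                np.zeros(hit.shape[0]),
            ]
        )
        v = hit - ax
        dist = np.linalg.norm(v, axis=1)
        capsule_margin = dist - bl.radius
        with np.errstate(invalid="ignore", divide="ignore"):
            n = v / np.where(dist[:, None] > 0, dist[:, None], 1.0)
        if self.septum_point is not None:
            q = np.asarray(self.septum_point)
            sn = np.asarray(self.septum_normal)
            sep_margin = (hit[:, 0] - q[0]) * sn[0] + (hit[:, 1] - q[1]) * sn[1]
            use_sep = sep_margin >= capsule_margin
            n[use_sep] = np.array([sn[0], sn[1], 0.0])
        return n

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"billiard": self.billiard.to_dict()}
        if self.septum_point is not None:
            d["septum_point"] = list(self.septum_point)
            d["septum_normal"] = list(self.septum_normal)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Spherocylinder":
        sp = d.get("septum_point")
        sn = d.get("septum_normal")
        return cls(
            Billiard.from_dict(d["billiard"]),
            tuple(sp) if sp is not None else None,
            tuple(sn) if sn is not None else None,
        )


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------


def classify_region(b: Billiard, points: np.ndarray) -> np.ndarray:
    """Label frame-coordinate points as pole_left / pole_right / center.

    The poles are the cap half-disks delimited by the cap-centre abscissae
    (the region boundary uses the billiard's radius). Points outside the
    billiard raise :class:`OutOfCellError`.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(b.contains(p)):
        raise OutOfCellError("point(s) outside the billiard cannot be classified")
    labels = np.empty(p.shape[0], dtype=object)
    labels[:] = RegionLabel.CENTER
    labels[p[:, 0] < b.cx_left] = RegionLabel.POLE_LEFT
    labels[p[:, 0] > b.cx_right] = RegionLabel.POLE_RIGHT
    return labels


# ---------------------------------------------------------------------------
# dividing-cell intersection
# ---------------------------------------------------------------------------


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the lens where two spheres of radii r1, r2 at distance d overlap."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2) or d < 1e-12:
        return 4.0 / 3.0 * math.pi * min(r1, r2) ** 3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2 * d * (r1 + r2) - 3 * (r1 * r1 + r2 * r2) + 6 * r1 * r2)
        / (12.0 * d)
    )


@dataclass(frozen=True)
class DividingIntersection:
    """Septum construction for a dividing cell pair (lab-frame coordinates)."""

    points: np.ndarray | None  # (2, 2) circle-circle intersection points, or None
    septum_point: np.ndarray  # a point on the septum line
    septum_direction: np.ndarray | None  # unit direction of the line, or None
    lens_volume: float
    cap_index_1: int  # which cap of billiard 1 is adjacent (0 = left, 1 = right)
    cap_index_2: int


def intersect_dividing(b1: Billiard, b2: Billiard) -> DividingIntersection:
    """Intersect the adjacent cap circles of two dividing-cell billiards.

    Returns the two circle-circle intersection points, the septum line through
    them, and the volume of the sphere-sphere lens of the two cap spheres.
    Raises :class:`GeometryError` when the adjacent caps do not overlap.
    """
    caps1 = b1.cap_centers_lab()
    caps2 = b2.cap_centers_lab()
    dists = np.linalg.norm(caps1[:, None, :] - caps2[None, :, :], axis=-1)
    i1, i2 = np.unravel_index(np.argmin(dists), dists.shape)
    c1, c2 = caps1[i1], caps2[i2]
    r1, r2 = b1.radius, b2.radius
    d = float(dists[i1, i2])
    if d >= r1 + r2:
        raise GeometryError(f"adjacent cap circles do not overlap (d={d:.3f} >= {r1 + r2:.3f})")
    vol = lens_volume(r1, r2, d)
    if d <= abs(r1 - r2) or d < 1e-12:
        # one circle inside the other (or coincident): no chord to define
        return DividingIntersection(None, 0.5 * (c1 + c2), None, vol, int(i1), int(i2))
    u = (c2 - c1) / d
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = math.sqrt(max(r1 * r1 - a * a, 0.0))
    mid = c1 + a * u
    perp = np.array([-u[1], u[0]])
    pts = np.vstack([mid + h * perp, mid - h * perp])
    return DividingIntersection(pts, mid, perp, vol, int(i1), int(i2))


def septum_spherocylinders(
    b1: Billiard, b2: Billiard
) -> tuple[Spherocylinder, Spherocylinder, DividingIntersection]:
    """Build the two daughter compartments with their shared reflecting septum.

    The septum is the plane through the cap-circle intersection points,
    parallel to z; it reflects for both daughters.
    """
    inter = intersect_dividing(b1, b2)
    shapes = []
    for b, other_cap in ((b1, inter.cap_index_2), (b2, inter.cap_index_1)):
        sc = Spherocylinder(b)
        # plane point/normal in this billiard's frame; normal points toward sibling
        pt = b.to_frame(inter.septum_point)
        center = b.center_frame
        if inter.septum_direction is not None:
            d_f = b.to_frame(inter.septum_direction)
            n = np.array([-d_f[1], d_f[0]])
        else:
            n = np.array([1.0, 0.0])
        if np.dot(center - pt, n) > 0:
            n = -n
        shapes.append(sc.with_septum(pt, n))
    return shapes[0], shapes[1], inter
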