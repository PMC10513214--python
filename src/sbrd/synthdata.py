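"""Synthetic SMdM datasets with known ground truth.

Generates localization tables in the same dialect the detection stage reads:
for each simulated cell, particle starts are drawn uniform in 3D inside the
spherocylinder, propagated by the forward Brownian simulator over one
stroboscopic lag, and the projected start/end positions are emitted as peaks
in consecutive frame pairs, optionally mixed with uniform background
localizations and Gaussian localization jitter. Every true parameter is
recorded so downstream error metrics need no re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Billiard, RegionLabel, SphericalRegion, Spherocylinder, septum_spherocylinders
from .simulate import SimulationConfig, simulate_smdm_displacements

__all__ = [
    "CellSpec",
    "SyntheticScene",
    "generate_scene",
    "generate_dividing_pair",
    "generate_mass_series",
]


@dataclass
class CellSpec:
    """One simulated cell: its outline, true diffusion field and data volume."""

    billiard: Billiard
    D: float
    n_displacements: int = 4000
    regions: tuple[SphericalRegion, ...] = ()
    # per-region-label D multipliers for pole-specific slowdowns (label -> factor)
    pole_factors: dict = field(default_factory=dict)
    shape: Spherocylinder | None = None  # override (e.g. septum for dividing cells)

    def spherocylinder(self) -> Spherocylinder:
        return self.shape if self.shape is not None else Spherocylinder(self.billiard)


@dataclass
class SyntheticScene:
    fov: tuple[float, float] = (10.0, 10.0)
    cells: list = field(default_factory=list)
    background_density: float = 0.0  # localizations per um^2 per frame pair
    lag: float = 1.5e-3
    dt: float = 1e-4
    localization_sigma: float = 0.0  # um, optional Gaussian jitter
    # on average one photoconverted molecule per cell per stroboscopic pulse pair
    peaks_per_frame_pair: int = 1
    seed: int | None = None


def _check_overlap(cells: Sequence[CellSpec]) -> None:
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            d = np.linalg.norm(a.billiard.center_lab - b.billiard.center_lab)
            if d < (a.billiard.length + b.billiard.length) / 4.0 and a.shape is None and b.shape is None:
                raise ValueError(
                    "cells overlap; build dividing pairs explicitly with generate_dividing_pair"
                )


def _simulate_cell_displacements(
    spec: CellSpec, scene: SyntheticScene, rng: np.random.Generator
) -> pd.DataFrame:
    """Start points uniform in 3D, one stroboscopic lag of reflected motion."""
    shape = spec.spherocylinder()
    b = spec.billiard
    lag_steps = int(round(scene.lag / scene.dt))
    starts = shape.sample_uniform(spec.n_displacements, rng)
    # spatially varying D: slow poles via per-label factors (step D taken at start)
    if spec.pole_factors:
        frame_xy = starts[:, :2]
        D = np.full(starts.shape[0], spec.D)
        sx = frame_xy[:, 0]
        for label, factor in spec.pole_factors.items():
            if label is RegionLabel.POLE_LEFT:
                D[sx < b.cx_left] *= factor
            elif label is RegionLabel.POLE_RIGHT:
                D[sx > b.cx_right] *= factor
            else:
                D[(sx >= b.cx_left) & (sx <= b.cx_right)] *= factor
        pos = starts.copy()
        for _ in range(lag_steps):
            noise = rng.standard_normal(pos.shape)
            prop = pos + np.sqrt(2.0 * D * scene.dt)[:, None] * noise
            pos = shape.reflect_steps(pos, prop)
        end = pos
        df = pd.DataFrame(
            {"x0": starts[:, 0], "y0": starts[:, 1], "x1": end[:, 0], "y1": end[:, 1]}
        )
    else:
        cfg = SimulationConfig(
            D_input=spec.D,
            n_particles=spec.n_displacements,
            shape=shape,
            dt=scene.dt,
            total_time=scene.lag,
            lag_steps=lag_steps,
            regions=spec.regions,
        )
        df = simulate_smdm_displacements(cfg, starts=starts, rng=rng)
    # billiard frame -> lab frame
    df[["x0", "y0"]] = b.to_lab(df[["x0", "y0"]].to_numpy())
    df[["x1", "y1"]] = b.to_lab(df[["x1", "y1"]].to_numpy())
    df["r"] = np.hypot(df.x1 - df.x0, df.y1 - df.y0)
    df["t"] = scene.lag
    return df


def generate_scene(scene: SyntheticScene) -> tuple[pd.DataFrame, dict]:
    """Emit the localization table and the ground-truth record.

    The table has columns x_um, y_um, frame, movie; displacements occupy
    consecutive frame pairs (2k, 2k+1). Background localizations are uniform
    Poisson over the field of view in every frame.
    """
    rng = np.random.default_rng(scene.seed)
    _check_overlap(scene.cells)
    rows = []
    truth_cells = []
    max_pairs = 0
    for ci, spec in enumerate(scene.cells):
        disp = _simulate_cell_displacements(spec, scene, rng)
        if scene.localization_sigma > 0:
            disp[["x0", "y0", "x1", "y1"]] += rng.normal(
                0.0, scene.localization_sigma, size=(len(disp), 4)
            )
        n_pairs = max(int(np.ceil(len(disp) / scene.peaks_per_frame_pair)), 1)
        max_pairs = max(max_pairs, n_pairs)
        # round-robin keeps simultaneous photoconversions per cell at the
        # configured level; pairing ambiguity then comes from the background
        pair_idx = np.arange(len(disp)) % n_pairs
        rows.append(
            pd.DataFrame(
                {
                    "x_um": disp["x0"],
                    "y_um": disp["y0"],
                    "frame": 2 * pair_idx,
                    "movie": 0,
                    "cell_truth": ci,
                }
            )
        )
        rows.append(
            pd.DataFrame(
                {
                    "x_um": disp["x1"],
                    "y_um": disp["y1"],
                    "frame": 2 * pair_idx + 1,
                    "movie": 0,
                    "cell_truth": ci,
                }
            )
        )
        truth_cells.append(
            {
                "billiard": spec.billiard.to_dict(),
                "D": spec.D,
                "n_displacements": spec.n_displacements,
                "pole_factors": {k.value: v for k, v in spec.pole_factors.items()},
                "regions": [
                    {"center": list(r.center), "radius": r.radius, "mode": r.mode.value, "D_inside": r.D_inside}
                    for r in spec.regions
                ],
            }
        )
    if scene.background_density > 0:
        n_frames = 2 * max(max_pairs, 1)
        lam = scene.background_density * scene.fov[0] * scene.fov[1]
        for f in range(n_frames):
            nb = rng.poisson(lam)
            if nb:
                rows.append(
                    pd.DataFrame(
                        {
                            "x_um": rng.uniform(0, scene.fov[0], nb),
                            "y_um": rng.uniform(0, scene.fov[1], nb),
                            "frame": f,
                            "movie": 0,
                            "cell_truth": -1,
                        }
                    )
                )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["x_um", "y_um", "frame", "movie", "cell_truth"])
    )
    table = table.sort_values(["frame", "x_um"], kind="stable").reset_index(drop=True)
    truth = {
        "fov": list(scene.fov),
        "lag": scene.lag,
        "dt": scene.dt,
        "background_density": scene.background_density,
        "localization_sigma": scene.localization_sigma,
        "seed": scene.seed,
        "cells": truth_cells,
    }
    return table, truth


def generate_dividing_pair(
    old_pole_D_deficit: float,
    D: float = 10.0,
    daughter_length: float = 1.8,
    radius: float = 0.45,
    overlap: float = 0.3,
    n_displacements: int = 3000,
    new_pole_deficit: float = 0.0,
    center: tuple[float, float] = (5.0, 5.0),
    angle: float = 0.0,
    seed: int | None = None,
) -> SyntheticScene:
    """Scene of two abutting daughters sharing a reflecting septum.

    Each daughter's distal (old) pole simulates at D * (1 - old_pole_D_deficit);
    the new poles at the septum at D * (1 - new_pole_deficit). Ground truth
    labels which side is which.
    """
    if not 0 <= old_pole_D_deficit < 1:
        raise ValueError("deficit must be in [0, 1)")
    off = daughter_length / 2.0 - overlap / 2.0
    c = np.asarray(center)
    axis = np.array([np.cos(angle), np.sin(angle)])
    b1 = Billiard.from_center(c - off * axis, daughter_length, radius, angle)
    b2 = Billiard.from_center(c + off * axis, daughter_length, radius, angle)
    s1, s2, _ = septum_spherocylinders(b1, b2)
    # daughter 1 lies on the left: its new pole faces right (the septum)
    f_old = 1.0 - old_pole_D_deficit
    f_new = 1.0 - new_pole_deficit
    cells = [
        CellSpec(b1, D, n_displacements, pole_factors={RegionLabel.POLE_LEFT: f_old, RegionLabel.POLE_RIGHT: f_new}, shape=s1),
        CellSpec(b2, D, n_displacements, pole_factors={RegionLabel.POLE_RIGHT: f_old, RegionLabel.POLE_LEFT: f_new}, shape=s2),
    ]
    return SyntheticScene(cells=cells, background_density=0.02, seed=seed)


def generate_mass_series(
    masses: Sequence[float],
    alpha: float,
    beta: float,
    billiard: Billiard | None = None,
    n_displacements: int = 4000,
    seed: int | None = None,
) -> list[SyntheticScene]:
    """One homogeneous scene per complex mass with true D = alpha * M^beta."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if billiard is None:
        billiard = Billiard.from_center((5.0, 5.0), 2.25, 0.45, 0.0)
    scenes = []
    for i, m in enumerate(masses):
        d_true = alpha * float(m) ** beta
        scenes.append(
            SyntheticScene(
                cells=[CellSpec(billiard, d_true, n_displacements)],
                seed=None if seed is None else seed + i,
            )
        )
    return scenes


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
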