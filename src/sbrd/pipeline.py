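"""End-to-end orchestration: synth -> detect -> pair -> smdm -> sbrd -> report.

A run is fully determined by its configuration and seed; the manifest
records per-stage counts (clouds found, cells kept or discarded by each
filter, pixels fitted or skipped) and the configuration hash so identical
runs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .detect import BilliardDetector
from .geometry import RegionLabel, Spherocylinder
from .sbrd import SbRDConfig, correct_region
from .smdm import (
    DEFAULT_PIXEL_PITCH,
    DEFAULT_R_MAX,
    fit_region,
    filter_cell_displacements,
    pair_peaks,
)
from .stats_report import summarize_ratios

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "pair_cell_displacements"]


@dataclass
class RunConfig:
    localizations: str | None = None  # input table; None requires synth config
    out_dir: str = "sbrd_run"
    bin_size: float = 0.1
    r_max: float = DEFAULT_R_MAX
    lag: float = 1.5e-3
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    min_per_pixel: int = 10
    min_per_cell: int = 2000
    max_per_cell: int = 20000
    n_repeats: int = 10
    background_fit: bool = True
    seed: int = 0
    run_sbrd: bool = True
    run_report: bool = True

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def pair_cell_displacements(
    localizations: pd.DataFrame, billiard, r_max: float = DEFAULT_R_MAX, lag: float = 1.5e-3
) -> pd.DataFrame:
    """Pair the peaks of one cell across consecutive stroboscopic frame pairs.

    Peaks belonging to the cell are those inside its billiard; frames are
    grouped in couples (2k, 2k+1).
    """
    pts = localizations[["x_um", "y_um"]].to_numpy()
    inside = billiard.contains(billiard.to_frame(pts))
    frames = localizations["frame"].to_numpy()[inside]
    xy = pts[inside]
    order = np.argsort(frames, kind="stable")
    frames, xy = frames[order], xy[order]
    uniq, starts = np.unique(frames, return_index=True)
    bounds = np.append(starts, frames.size)
    slices = {int(f): slice(starts[i], bounds[i + 1]) for i, f in enumerate(uniq)}
    parts = []
    for f in uniq:
        f = int(f)
        if f % 2 or f + 1 not in slices:
            continue
        a = xy[slices[f]]
        b = xy[slices[f + 1]]
        if not (a.size and b.size):
            continue
        # frames hold only a handful of peaks: brute-force pairwise distances
        d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
        ia, ib = np.nonzero(d <= r_max)
        if ia.size:
            parts.append(np.column_stack([a[ia], b[ib], d[ia, ib]]))
    if not parts:
        return pd.DataFrame(columns=["x0", "y0", "x1", "y1", "r", "t"])
    arr = np.vstack(parts)
    return pd.DataFrame(
        {"x0": arr[:, 0], "y0": arr[:, 1], "x1": arr[:, 2], "y1": arr[:, 3], "r": arr[:, 4], "t": lag}
    )


def run_pipeline(config: RunConfig, localizations: pd.DataFrame | None = None) -> Path:
    """Execute the staged analysis; returns the run directory.

    Writes cells.json, displacements per cell, the region summary CSV, the
    ratio report, and a manifest with per-stage counts.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if localizations is None:
        if config.localizations is None:
            raise ValueError("no input: provide a localization table or path")
        if not Path(config.localizations).exists():
            raise FileNotFoundError(config.localizations)
        localizations = io.read_localizations(config.localizations)

    det = BilliardDetector(bin_size=config.bin_size).fit(localizations)
    cells = det.cells_
    io.write_cells(cells, out / "cells.json")
    counts = {
        "localizations": int(len(localizations)),
        "cells_detected": len(cells),
        "too_short": sum("too_short" in c.qc_flags for c in cells),
        "too_wide": sum("too_wide" in c.qc_flags for c in cells),
        "split": sum(c.divided for c in cells),
        "rejected_other": sum(
            bool(c.qc_flags - {"too_short", "too_wide", "split_candidate"}) for c in cells
        ),
        "cells_kept": sum(c.passed_qc for c in cells),
    }

    region_rows = []
    sbrd_cfg = SbRDConfig(n_repeats=config.n_repeats, seed=config.seed)
    poles = (RegionLabel.POLE_LEFT, RegionLabel.POLE_RIGHT)
    counts["cells_displacement_filtered"] = 0
    for c in cells:
        if not c.passed_qc:
            continue
        disp = pair_cell_displacements(localizations, c.billiard, config.r_max, config.lag)
        if not filter_cell_displacements(disp, config.min_per_cell, config.max_per_cell):
            counts["cells_displacement_filtered"] += 1
            continue
        b = c.billiard
        d_app_c, _, st_c = fit_region(
            b, disp, RegionLabel.CENTER, r_max=config.r_max,
            min_n=config.min_per_pixel, background=config.background_fit,
        )
        d_app_p, _, st_p = fit_region(
            b, disp, poles, r_max=config.r_max,
            min_n=config.min_per_pixel, background=config.background_fit,
        )
        row = {
            "cell_id": c.cell_id,
            "n_displacements": len(disp),
            "D_app_center": d_app_c,
            "D_app_poles": d_app_p,
        }
        if config.run_sbrd and st_c == "ok" and st_p == "ok":
            shape = Spherocylinder(b)
            row["D_cc_center"], _ = correct_region(
                shape, disp, RegionLabel.CENTER, sbrd_cfg,
                r_max=config.r_max, background=config.background_fit, D_app=d_app_c,
            )
            row["D_cc_poles"], _ = correct_region(
                shape, disp, poles, sbrd_cfg,
                r_max=config.r_max, background=config.background_fit, D_app=d_app_p,
            )
        region_rows.append(row)
    regions = pd.DataFrame(region_rows)
    regions.to_csv(out / "regions.csv", index=False)

    if config.run_report and len(regions):
        summary = summarize_ratios(regions, out_dir=out / "report")
        summary.to_csv(out / "report" / "ratio_summary.csv", index=False)

    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "counts": counts,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
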