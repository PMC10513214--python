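"""File formats: localization tables, displacement sets, cells, maps.

Localizations: CSV/TSV with header columns x_um, y_um, frame, movie, or an
HDF5 file with a /localizations table. Displacements: HDF5 group
/displacements with columns x0, y0, x1, y1, r, t (or CSV). Cells: JSON list
of fitted-cell records. Maps: HDF5 groups /maps/D, /maps/k, /maps/n plus
grid metadata; SbRD output adds /sbrd/D_cc, /sbrd/diff, /sbrd/repeats.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .detect import CellFit
from .smdm import PixelDiffusionMap

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_displacements",
    "write_displacements",
    "read_cells",
    "write_cells",
    "write_maps",
    "read_maps",
    "write_sbrd",
]

_LOC_COLS = ["x_um", "y_um", "frame", "movie"]
_DISP_COLS = ["x0", "y0", "x1", "y1", "r", "t"]


def read_localizations(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            g = fh["localizations"]
            df = pd.DataFrame({c: g[c][:] for c in g.keys()})
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep)
    missing = [c for c in _LOC_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"localization table missing columns {missing}")
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            g = fh.create_group("localizations")
            for c in df.columns:
                g.create_dataset(c, data=df[c].to_numpy())
    else:
        df.to_csv(path, index=False)


def read_displacements(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            g = fh["displacements"]
            df = pd.DataFrame({c: g[c][:] for c in g.keys()})
    else:
        df = pd.read_csv(path)
    return df


def write_displacements(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            g = fh.create_group("displacements")
            for c in df.columns:
                g.create_dataset(c, data=df[c].to_numpy())
    else:
        df.to_csv(path, index=False)


def read_cells(path) -> list[CellFit]:
    with open(path) as fh:
        return [CellFit.from_dict(d) for d in json.load(fh)]


def write_cells(cells, path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in cells], fh, indent=1)


def write_maps(maps: dict[int, PixelDiffusionMap], path) -> None:
    """maps: cell_id -> PixelDiffusionMap."""
    with h5py.File(path, "w") as fh:
        for cid, m in maps.items():
            g = fh.create_group(f"maps/cell{cid}")
            g.create_dataset("D", data=m.D)
            g.create_dataset("k", data=m.k)
            g.create_dataset("n", data=m.n)
            g.create_dataset("pixel_of", data=m.pixel_of)
            g.attrs["origin"] = m.origin
            g.attrs["pixel_pitch"] = m.pixel_pitch


def read_maps(path) -> dict[int, PixelDiffusionMap]:
    out = {}
    with h5py.File(path, "r") as fh:
        for name, g in fh["maps"].items():
            cid = int(name.removeprefix("cell"))
            D = g["D"][:]
            status = np.where(np.isfinite(D), "ok", "skipped").astype(object)
            out[cid] = PixelDiffusionMap(
                tuple(g.attrs["origin"]),
                float(g.attrs["pixel_pitch"]),
                D,
                g["k"][:],
                g["n"][:],
                status,
                g["pixel_of"][:],
            )
    return out


def write_sbrd(results: dict, path) -> None:
    """results: cell_id -> SbRDResult."""
    with h5py.File(path, "w") as fh:
        for cid, r in results.items():
            g = fh.create_group(f"sbrd/cell{cid}")
            g.create_dataset("D_cc", data=r.D_cc)
            g.create_dataset("diff", data=r.difference)
            g.create_dataset("repeats", data=r.repeats)
            g.create_dataset("D_app", data=r.D_app)
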