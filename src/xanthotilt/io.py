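"""Reading and writing the on-disk formats used by both routes.

GUV image pairs travel as one 16-bit grayscale TIFF per channel with a JSON
geometry sidecar; umbrella windows as per-window CSV (step, z) plus a JSON
manifest; Raman cubes as NPZ with a wavenumber-axis CSV; membrane frames and
free-energy profiles as JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .membrane import MembraneFrame
from .synthetic import GuvGeometry, GuvImagePair, RamanCube
from .umbrella import FreeEnergyProfile, UmbrellaWindow

# ---------------------------------------------------------------------------
# GUV images
# ---------------------------------------------------------------------------


def write_guv_pair(pair: GuvImagePair, directory, stem: str = "guv") -> dict:
    """Write a channel pair as two 16-bit TIFFs plus a JSON geometry sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in (("vv", pair.i_vv), ("vh", pair.i_vh)):
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(p, np.clip(np.round(img), 0, 65535).astype(np.uint16))
        paths[name] = str(p)
    sidecar = directory / f"{stem}_geometry.json"
    meta = pair.geometry.to_dict()
    meta["detection_mode"] = pair.detection_mode
    sidecar.write_text(json.dumps(meta, indent=2))
    paths["geometry"] = str(sidecar)
    return paths


def read_guv_pair(vv_path, vh_path, geometry_path) -> GuvImagePair:
    i_vv = tifffile.imread(vv_path).astype(float)
    i_vh = tifffile.imread(vh_path).astype(float)
    meta = json.loads(Path(geometry_path).read_text())
    mode = meta.pop("detection_mode", "sum_channels")
    return GuvImagePair(i_vv, i_vh, GuvGeometry.from_dict(meta), mode)


# ---------------------------------------------------------------------------
# Umbrella windows
# ---------------------------------------------------------------------------


def write_windows(windows: Sequence[UmbrellaWindow], directory,
                  stem: str = "window") -> str:
    """Write per-window CSVs and a manifest JSON; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(windows):
        fname = f"{stem}_{i:02d}.csv"
        pd.DataFrame(
            {"step": np.arange(w.samples.size), "z": w.samples}
        ).to_csv(directory / fname, index=False)
        entries.append(
            {
                "file": fname,
                "center": w.center,
                "spring_k": w.spring_k,
                "temperature": w.temperature,
            }
        )
    manifest = directory / f"{stem}_manifest.json"
    manifest.write_text(json.dumps({"windows": entries}, indent=2))
    return str(manifest)


def _read_colvar(path: Path) -> np.ndarray:
    """Two-column time/colvar text with '#' comment lines, or a CSV with a z column."""
    txt = path.read_text()
    if path.suffix.lower() == ".csv" and "z" in txt.splitlines()[0]:
        return pd.read_csv(path)["z"].to_numpy(dtype=float)
    data = np.loadtxt(path, comments="#")
    return np.atleast_2d(data)[:, -1].astype(float)


def read_windows(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    windows = []
    for entry in meta["windows"]:
        samples = _read_colvar(manifest_path.parent / entry["file"])
        windows.append(
            UmbrellaWindow(
                center=float(entry["center"]),
                spring_k=float(entry["spring_k"]),
                samples=samples,
                temperature=float(entry.get("temperature", 320.0)),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Profiles, frames, Raman cubes
# ---------------------------------------------------------------------------


def write_profile(profile: FreeEnergyProfile, path) -> None:
    df = pd.DataFrame({"coordinate": profile.grid, "G": profile.values})
    df["stderr"] = profile.stderr if profile.stderr is not None else np.nan
    df.to_csv(path, index=False)


def read_profile(path, coordinate_kind: str = "z_distance") -> FreeEnergyProfile:
    df = pd.read_csv(path)
    stderr = df["stderr"].to_numpy() if "stderr" in df else None
    if stderr is not None and np.all(np.isnan(stderr)):
        stderr = None
    return FreeEnergyProfile(
        df["coordinate"].to_numpy(), df["G"].to_numpy(), stderr, coordinate_kind
    )


def write_frames(frames: Sequence[MembraneFrame], path) -> None:
    Path(path).write_text(json.dumps([f.to_dict() for f in frames]))


def read_frames(path) -> list[MembraneFrame]:
    return [MembraneFrame.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_raman_cube(cube: RamanCube, directory, stem: str = "raman") -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npz = directory / f"{stem}_cube.npz"
    np.savez_compressed(npz, data=cube.data)
    axis = directory / f"{stem}_wavenumbers.csv"
    pd.DataFrame({"wavenumber_cm1": cube.wavenumbers}).to_csv(axis, index=False)
    return {"cube": str(npz), "axis": str(axis)}


def read_raman_cube(cube_path, axis_path) -> RamanCube:
    data = np.load(cube_path)["data"]
    wn = pd.read_csv(axis_path)["wavenumber_cm1"].to_numpy(dtype=float)
    return RamanCube(data, wn)
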