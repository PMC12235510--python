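"""File I/O: Picasso-compatible localization HDF5 + YAML sidecars, TIFF movies.

Conventions
-----------
Localization coordinates are stored in **camera pixels** (x = column,
y = row, 0-based, pixel-center origin) with the pixel size recorded in the
YAML sidecar; physical thresholds elsewhere in the package are applied in nm
after multiplying by ``pixel_nm``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

#: canonical column order of the "locs" table
LOC_FIELDS = ["frame", "x", "y", "photons", "sx", "sy", "bg", "lpx", "lpy"]
REQUIRED_FIELDS = ["frame", "x", "y", "photons"]


@dataclass
class LocalizationTable:
    """Per-localization records plus acquisition metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per localization with at least ``frame, x, y, photons``
        (x, y in camera pixels).
    pixel_nm : float
        Camera pixel size in nm.
    n_frames : int
        Number of frames in the acquisition the table came from.
    """

    df: pd.DataFrame
    pixel_nm: float
    n_frames: int

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_FIELDS if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table missing required fields: {missing}")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x_nm(self) -> np.ndarray:
        return self.df["x"].to_numpy() * self.pixel_nm

    @property
    def y_nm(self) -> np.ndarray:
        return self.df["y"].to_numpy() * self.pixel_nm

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), self.pixel_nm, self.n_frames)


def _sidecar_path(path: str) -> str:
    root, _ = os.path.splitext(path)
    return root + ".yaml"


def write_locs(table: LocalizationTable, path: str) -> None:
    """Write a Picasso-compatible HDF5 "locs" dataset plus a YAML sidecar.

    Field order is deterministic (``LOC_FIELDS``); columns absent from the
    table are filled with zeros so downstream Picasso-style readers always
    see the full record. ``frame`` is stored as uint32, everything else as
    float64 so round trips are bit-exact.
    """
    n = len(table.df)
    dtype = [("frame", "u4")] + [(f, "f8") for f in LOC_FIELDS[1:]]
    rec = np.zeros(n, dtype=dtype)
    for name in LOC_FIELDS:
        if name in table.df.columns:
            rec[name] = table.df[name].to_numpy()
    with h5py.File(path, "w") as f:
        f.create_dataset("locs", data=rec)
    meta = {
        "Frames": int(table.n_frames),
        "Pixelsize": float(table.pixel_nm),
        "Localizations": int(n),
        "Generated by": "fluoropaint",
    }
    with open(_sidecar_path(path), "w") as f:
        yaml.safe_dump(meta, f)


def read_locs(path: str, pixel_nm: float | None = None,
              n_frames: int | None = None) -> LocalizationTable:
    """Read a Picasso-compatible localization file.

    The YAML sidecar supplies pixel size and frame count; without it both
    must be given explicitly (a warning is emitted). Missing optional
    columns are filled with NaN and reported via a warning.
    """
    try:
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise ValueError(f"{path}: no 'locs' dataset found")
            rec = f["locs"][()]
    except OSError as e:  # truncated / not an HDF5 file
        raise ValueError(f"{path}: cannot parse HDF5 localization file ({e})") from e

    df = pd.DataFrame({name: rec[name] for name in rec.dtype.names})
    missing = [c for c in REQUIRED_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: 'locs' dataset lacks required field(s) {missing}")
    absent = [c for c in LOC_FIELDS if c not in df.columns]
    if absent:
        warnings.warn(f"{path}: optional fields {absent} missing, filled with NaN")
        for c in absent:
            df[c] = np.nan
    df = df[LOC_FIELDS]

    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as f:
            meta = yaml.safe_load(f) or {}
        pixel_nm = pixel_nm if pixel_nm is not None else meta.get("Pixelsize")
        n_frames = n_frames if n_frames is not None else meta.get("Frames")
    else:
        warnings.warn(f"{path}: no YAML sidecar; pixel size / frame count must be supplied")
    if pixel_nm is None:
        raise ValueError(f"{path}: pixel size unknown (no sidecar); pass pixel_nm")
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    return LocalizationTable(df, float(pixel_nm), int(n_frames))


def write_movie(frames: np.ndarray, path: str) -> None:
    """Write a movie stack as multi-page 16-bit unsigned TIFF (ADU)."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint16))


def read_movie(path: str) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


@dataclass
class RunConfig:
    """Bundle of pipeline settings, YAML-serializable.

    The effective configuration of a run is echoed into its output
    directory so results stay reproducible.
    """

    camera: dict = field(default_factory=dict)
    dbscan: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    frc: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.__dict__, f)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)
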