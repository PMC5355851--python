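"""MRC2014 map/stack I/O and STAR particle-metadata tables.

Maps and image stacks are stored as MRC2014 with the voxel size in the header
(via ``mrcfile``).  Particle metadata uses STAR tables with the conventional
single-particle column names (``rlnAngleRot``/``Tilt``/``Psi`` for the ZYZ
Euler triplet, ``rlnOriginX``/``Y`` for shifts, defocus/voltage/Cs/amplitude
contrast for the CTF); ground-truth columns written by the simulator carry a
``vrx`` prefix.  STAR parsing is done with gemmi's CIF/STAR reader.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import mrcfile
import numpy as np
import pandas as pd

from .ctf import CTFParams
from .phantom import DensityMap
from .symmetry import Orientation

_MODE_BYTES = {0: 1, 1: 2, 2: 4, 6: 2, 12: 2}


# ---------------------------------------------------------------------------
# MRC

def write_mrc(path, data_or_map, voxel_size: float | None = None) -> None:
    """Write a 3D map or a 2D-image stack as MRC2014 (float32)."""
    if isinstance(data_or_map, DensityMap):
        data = data_or_map.data
        voxel_size = data_or_map.voxel_size
    else:
        data = np.asarray(data_or_map)
        if voxel_size is None:
            raise ValueError("voxel_size is required when writing a bare array")
    with mrcfile.new(str(path), overwrite=True) as f:
        f.set_data(data.astype(np.float32))
        f.voxel_size = voxel_size


def _validate_mrc_size(path) -> None:
    """Fail early, naming expected vs actual data length, on truncated files."""
    size = os.path.getsize(path)
    if size < 1024:
        raise ValueError(
            f"{path}: malformed MRC, header needs 1024 bytes but file has {size}")
    with open(path, "rb") as fh:
        head = fh.read(1024)
    nx, ny, nz, mode = np.frombuffer(head[:16], dtype="<i4")
    nsymbt = int(np.frombuffer(head[92:96], dtype="<i4")[0])
    if mode not in _MODE_BYTES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    expected = 1024 + nsymbt + int(nx) * int(ny) * int(nz) * _MODE_BYTES[int(mode)]
    if size < expected:
        raise ValueError(
            f"{path}: truncated MRC data block, expected {expected} bytes "
            f"({nx}x{ny}x{nz} mode {mode}) but file has {size}")


def read_mrc(path) -> DensityMap:
    """Read a cubic MRC map; raises a descriptive error on truncation."""
    _validate_mrc_size(path)
    with mrcfile.open(str(path), permissive=False) as f:
        data = np.asarray(f.data, dtype=np.float32).copy()
        voxel = float(f.voxel_size.x)
    return DensityMap(data, voxel)


def read_mrc_stack(path) -> tuple[np.ndarray, float]:
    """Read a 2D-image stack; returns (images, pixel size)."""
    _validate_mrc_size(path)
    with mrcfile.open(str(path), permissive=False) as f:
        data = np.asarray(f.data, dtype=np.float32).copy()
        voxel = float(f.voxel_size.x)
    if data.ndim == 2:
        data = data[None]
    return data, voxel


# ---------------------------------------------------------------------------
# STAR

def write_star(tables: dict[str, pd.DataFrame] | pd.DataFrame, path) -> None:
    """Write DataFrame(s) as STAR loop blocks (column order preserved)."""
    if isinstance(tables, pd.DataFrame):
        tables = {"particles": tables}
    doc = gemmi.cif.Document()
    for name, df in tables.items():
        block = doc.add_new_block(name)
        loop = block.init_loop("", [f"_{c}" for c in df.columns])
        for _, row in df.iterrows():
            loop.add_row([_format_star(v) for v in row])
    doc.write_file(str(path))


def _format_star(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6f}"
    s = str(v)
    return s if s and " " not in s else gemmi.cif.quote(s)


def read_star(path) -> dict[str, pd.DataFrame]:
    """Read every loop block of a STAR file into DataFrames (typed columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed STAR file: {exc}") from exc
    out: dict[str, pd.DataFrame] = {}
    for block in doc:
        for item in block:
            loop = item.loop
            if loop is None:
                continue
            cols = {}
            width = loop.width()
            flat = list(loop.values)
            for j, tag in enumerate(loop.tags):
                cols[tag.lstrip("_")] = _coerce(flat[j::width])
            out[block.name] = pd.DataFrame(cols)
    if not out:
        raise ValueError(f"{path}: no loop tables found in STAR file")
    return out


def _coerce(values: list[str]) -> list:
    try:
        ints = [int(v) for v in values]
        return ints
    except ValueError:
        pass
    try:
        return [float(v) for v in values]
    except ValueError:
        return [gemmi.cif.as_string(v) for v in values]


# ---------------------------------------------------------------------------
# metadata row conversions

def orientation_to_row(o: Orientation) -> dict:
    return {"rlnAngleRot": o.rot, "rlnAngleTilt": o.tilt, "rlnAnglePsi": o.psi,
            "rlnOriginX": o.dx, "rlnOriginY": o.dy}

def orientation_from_row(row) -> Orientation:
    missing = [k for k in ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
               if k not in row]
    if missing:
        raise ValueError(f"metadata row lacks orientation columns: {missing}")
    return Orientation(rot=float(row["rlnAngleRot"]),
                       tilt=float(row["rlnAngleTilt"]),
                       psi=float(row["rlnAnglePsi"]),
                       dx=float(row.get("rlnOriginX", 0.0)),
                       dy=float(row.get("rlnOriginY", 0.0)))

def ctf_to_row(c: CTFParams) -> dict:
    return {"rlnDefocusU": c.defocus_u, "rlnDefocusV": c.defocus_v,
            "rlnDefocusAngle": c.astig_angle, "rlnVoltage": c.voltage,
            "rlnSphericalAberration": c.cs,
            "rlnAmplitudeContrast": c.amplitude_contrast}

def ctf_from_row(row) -> CTFParams:
    missing = [k for k in ("rlnDefocusU", "rlnDefocusV", "rlnVoltage")
               if k not in row]
    if missing:
        raise ValueError(f"metadata row lacks CTF columns: {missing}")
    return CTFParams(voltage=float(row["rlnVoltage"]),
                     defocus_u=float(row["rlnDefocusU"]),
                     defocus_v=float(row["rlnDefocusV"]),
                     astig_angle=float(row.get("rlnDefocusAngle", 0.0)),
                     cs=float(row.get("rlnSphericalAberration", 2.0)),
                     amplitude_contrast=float(
                         row.get("rlnAmplitudeContrast", 0.1)))
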