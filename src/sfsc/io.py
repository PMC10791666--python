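"""File I/O: MRC2014 volumes/images, TIFF images, curve CSVs, configs.

Volumes and images travel as MRC2014 maps (via gemmi's CCP4/MRC support)
with the voxel size carried in the header's cell dimensions; 2-D images
may alternatively use TIFF (voxel size supplied by the caller).  Radial
curves serialize to self-describing CSVs with ``# key: value`` metadata
header lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import tifffile
import yaml

from .correlate import CorrelationCurve
from .grid import Measurement, RadialProfile

__all__ = [
    "read_volume",
    "write_volume",
    "write_curve",
    "read_curve",
    "read_config",
    "write_config",
]

CURVE_COLUMNS = ["shell", "frequency_inv_angstrom", "value", "n_indices", "flags"]


def read_volume(path: str | Path, voxel_size: float | None = None) -> Measurement:
    """Read a Measurement from an MRC2014 (.mrc/.map) or TIFF file.

    The MRC voxel size comes from the header (cell / grid size) and must
    be isotropic; a ``voxel_size`` argument overrides it and is required
    for TIFF input or when the header carries no usable size.  Depth-1 MRC
    grids are squeezed to 2-D images.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(str(path)), dtype=float)
        if voxel_size is None:
            raise ValueError("TIFF input requires an explicit voxel size")
        return Measurement(np.squeeze(data), voxel_size)

    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = ccp4.grid
    data = np.array(grid, copy=True).astype(float)
    sizes = []
    for n, cell_len in zip((grid.nu, grid.nv, grid.nw), (grid.unit_cell.a, grid.unit_cell.b, grid.unit_cell.c)):
        if n > 1:
            sizes.append(cell_len / n)
    if voxel_size is None:
        if not sizes or not all(s > 0 for s in sizes):
            raise ValueError(
                f"{path}: MRC header carries no voxel size; pass --voxel-size"
            )
        if max(sizes) - min(sizes) > 1e-4 * max(sizes):
            raise ValueError(f"{path}: anisotropic voxel size {sizes} is unsupported")
        voxel_size = float(sizes[0])
    data = np.squeeze(data)
    for ax, n in enumerate(data.shape):
        if n % 2 != 0:
            raise ValueError(
                f"{path}: axis {ax} has odd length {n}; the even/odd splitting "
                "requires even axis lengths"
            )
    return Measurement(data, voxel_size)


def write_volume(m: Measurement, path: str | Path) -> None:
    """Write a Measurement as an MRC2014 map (2-D data as a depth-1 grid)."""
    data = np.asarray(m.data, dtype=np.float32)
    if data.ndim == 1:
        data = data[np.newaxis, np.newaxis, :]
    elif data.ndim == 2:
        data = data[np.newaxis, :, :]
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(data))
    nx, ny, nz = data.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * m.voxel_size, ny * m.voxel_size, nz * m.voxel_size, 90, 90, 90
    )
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def _profile_frame(profile: RadialProfile) -> pd.DataFrame:
    flags = np.where(np.asarray(profile.defined),
                     np.where(profile.complete, "", "incomplete"),
                     "undefined")
    return pd.DataFrame({
        "shell": profile.shell,
        "frequency_inv_angstrom": profile.frequency,
        "value": profile.value,
        "n_indices": profile.n_indices,
        "flags": flags,
    })


def write_curve(
    curve: CorrelationCurve | RadialProfile,
    path: str | Path,
    extra_metadata: dict | None = None,
) -> None:
    """Serialize a curve as a self-describing CSV.

    Metadata (curve kind, corrections applied) is written as ``# key: value``
    header lines above the column header.
    """
    if isinstance(curve, CorrelationCurve):
        profile = curve.profile
        meta = {"kind": curve.kind}
        for key in ("phase_correction", "variance_corrected", "whitened",
                    "upsampled", "estimator", "scheme", "voxel_size"):
            if key in curve.metadata:
                meta[key] = curve.metadata[key]
    else:
        profile = curve
        meta = {"kind": "profile"}
    if extra_metadata:
        meta.update(extra_metadata)
    buf = _io.StringIO()
    for key, val in meta.items():
        buf.write(f"# {key}: {val}\n")
    _profile_frame(profile).to_csv(buf, index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())


def read_curve(path: str | Path) -> tuple[RadialProfile, dict]:
    """Read a curve CSV back into a profile plus its metadata dict."""
    lines = Path(path).read_text().splitlines()
    meta: dict = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    flags = df["flags"].fillna("").astype(str)
    profile = RadialProfile(
        shell=df["shell"].to_numpy(),
        frequency=df["frequency_inv_angstrom"].to_numpy(),
        value=df["value"].to_numpy(),
        n_indices=df["n_indices"].to_numpy(),
        complete=(flags != "incomplete").to_numpy() & (flags != "undefined").to_numpy(),
        defined=(flags != "undefined").to_numpy(),
    )
    return profile, meta


def read_config(path: str | Path) -> dict:
    """Read a flat key-value YAML config mirroring the CLI flags."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
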