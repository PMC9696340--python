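"""Volumes, masks, scan series, and their on-disk formats.

A reconstructed uCT volume is a 3-D grid of gray values encoding the local
X-ray linear attenuation coefficient.  Arrays are indexed ``[z, y, x]`` with
``z`` the tablet's axial direction; multi-page TIFF stacks store one ``z``
slice per page (page order = increasing z).  A scan series is written as one
TIFF per timestep plus a JSON manifest recording timestamps (hours), the
voxel size (micrometres) and the axis order, so a series can be re-read
without ambiguity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "ScanSeries",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_profile_csv",
    "write_profile_csv",
]

_AXIS_ORDER = "zyx"


@dataclass
class VoxelVolume:
    """A 3-D scalar grid of attenuation gray values with a physical voxel size.

    Parameters
    ----------
    values
        3-D array of gray values, indexed ``[z, y, x]``.
    voxel_size_um
        Edge length of the (isotropic) voxel in micrometres.
    """

    values: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError(f"volume must be 3-D, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValidationError("volume contains non-finite gray values")
        if not self.voxel_size_um > 0:
            raise ValidationError(f"voxel size must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """Boolean grid with the same shape as its parent volume."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            raise ValidationError(f"mask must be boolean, got dtype {self.values.dtype}")
        if self.values.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.values.sum())

    def check_matches(self, vol: VoxelVolume) -> None:
        if self.shape != vol.shape:
            raise ValidationError(
                f"mask shape {self.shape} does not match volume shape {vol.shape}"
            )


@dataclass
class ScanSeries:
    """Time-ordered volumes on one shared grid, timestamps in hours."""

    volumes: list[VoxelVolume]
    times_h: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        if len(self.volumes) == 0:
            raise ValidationError("scan series must contain at least one volume")
        if len(self.volumes) != len(self.times_h):
            raise ValidationError(
                f"{len(self.volumes)} volumes but {len(self.times_h)} timestamps"
            )
        if len(self.times_h) > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        ref = self.volumes[0]
        for i, v in enumerate(self.volumes):
            if v.shape != ref.shape:
                raise ValidationError(
                    f"volume {i} shape {v.shape} differs from {ref.shape}"
                )
            if v.voxel_size_um != ref.voxel_size_um:
                raise ValidationError("volumes in a series must share one voxel size")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def voxel_size_um(self) -> float:
        return self.volumes[0].voxel_size_um


def write_series(series: ScanSeries, directory: str | Path, prefix: str = "t") -> Path:
    """Write one multi-page TIFF per timestep plus a JSON manifest.

    Gray values are written with their in-memory dtype (float volumes as
    32-bit float, integer volumes unchanged), so a round trip preserves them
    exactly.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, vol in enumerate(series.volumes):
        name = f"{prefix}{i:03d}.tif"
        data = vol.values
        if data.dtype.kind == "f":
            data = data.astype(np.float32)
        try:
            tifffile.imwrite(directory / name, data, photometric="minisblack")
        except OSError as exc:  # pragma: no cover - disk errors
            raise ValidationError(f"could not write {directory / name}: {exc}") from exc
        files.append(name)
    manifest = {
        "axis_order": _AXIS_ORDER,
        "voxel_size_um": series.voxel_size_um,
        "timestamps_h": [float(t) for t in series.times_h],
        "files": files,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_series(manifest_path: str | Path) -> ScanSeries:
    """Read a scan series from a JSON manifest written by :func:`write_series`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ValidationError(f"manifest not found: {manifest_path}")
    meta = json.loads(manifest_path.read_text())
    for key in ("voxel_size_um", "timestamps_h", "files"):
        if key not in meta:
            raise ValidationError(f"manifest missing required key '{key}'")
    if meta.get("axis_order", _AXIS_ORDER) != _AXIS_ORDER:
        raise ValidationError(
            f"unsupported axis order {meta['axis_order']!r}; expected {_AXIS_ORDER!r}"
        )
    times = np.asarray(meta["timestamps_h"], dtype=float)
    if len(times) != len(meta["files"]):
        raise ValidationError("manifest timestamps and files differ in length")
    vols = []
    for name in meta["files"]:
        fpath = manifest_path.parent / name
        if not fpath.exists():
            raise ValidationError(f"volume file not found: {fpath}")
        vols.append(VoxelVolume(tifffile.imread(fpath), meta["voxel_size_um"]))
    return ScanSeries(vols, times)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit multi-page TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.values.astype(np.uint8) * 255, photometric="minisblack")
    return path


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"mask file not found: {path}")
    return BinaryMask(tifffile.imread(path) > 0)


def write_profile_csv(times_h, values, path: str | Path, value_column: str = "release_pct") -> Path:
    """Write a two-column profile CSV with header ``time_h,<value_column>``."""
    times_h = np.asarray(times_h, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_h.shape != values.shape:
        raise ValidationError("time and value vectors differ in length")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_h", value_column])
        for t, v in zip(times_h, values):
            writer.writerow([repr(float(t)), repr(float(v))])
    return path


def read_profile_csv(path: str | Path, value_column: str = "release_pct"):
    """Read a two-column profile CSV; returns ``(times_h, values)`` arrays.

    Parse errors are reported with the offending 1-based line number.
    Negative or duplicate times are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"profile CSV not found: {path}")
    times, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if header[:1] != ["time_h"] or len(header) != 2:
            raise ValidationError(
                f"{path}: line 1: expected header 'time_h,{value_column}', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ValidationError(f"{path}: line {lineno}: expected 2 columns")
            try:
                t, v = float(row[0]), float(row[1])
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric cell in {row}"
                ) from None
            if t < 0:
                raise ValidationError(f"{path}: line {lineno}: negative time {t}")
            times.append(t)
            values.append(v)
    times = np.asarray(times)
    values = np.asarray(values)
    if len(np.unique(times)) != len(times):
        raise ValidationError(f"{path}: duplicate time points")
    order = np.argsort(times)
    return times[order], values[order]
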