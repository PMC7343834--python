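"""Volumes, label maps and seed ROIs: in-memory containers and file IO.

Coordinate conventions (used by every other module):

* Grid axes map to anatomy as ``axis 0 = dorso-ventral``, ``axis 1 =
  medio-lateral``, ``axis 2 = anterior-posterior``.  Axis 2 therefore indexes
  coronal slices, matching tomographic reconstructions whose reconstruction
  plane coincides with the coronal plane.
* Voxel indices are 0-based; the physical position of voxel ``(i, j, k)`` is
  its centre, ``(i + 1/2, j + 1/2, k + 1/2) * voxel_size_um``.
* Gray values are held as 32-bit floats in memory regardless of on-disk type.

Supported formats: multi-page TIFF (one page per coronal slice, ImageJ-style
voxel-size metadata) and HDF5 (``/volume`` dataset with a ``voxel_size_um``
attribute).  Voxel size is mandatory on read — there is no silent default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from ._exceptions import ConfigurationError, FormatError, MissingMetadataError

#: Anatomical names of grid axes 0, 1, 2 (asserted here and nowhere else).
AXIS_NAMES: tuple[str, str, str] = (
    "dorso-ventral",
    "medio-lateral",
    "anterior-posterior",
)

#: Default isotropic voxel edge length in micrometres (detector effective
#: pixel size of the acquisition the pipeline was designed around).
DEFAULT_VOXEL_SIZE_UM = 1.625

#: Column order of the per-object results CSV.
RECORD_COLUMNS = [
    "object_id",
    "object_class",
    "region",
    "volume_um3",
    "surface_um2",
    "sphericity",
    "cx_um",
    "cy_um",
    "cz_um",
    "ax",
    "ay",
    "az",
    "azimuth_deg",
    "elevation_deg",
    "eig1_um2",
    "eig2_um2",
    "eig3_um2",
    "axis_tie_flag",
    "sphericity_flag",
]

#: Column order of the seed-ROI CSV.
SEED_COLUMNS = ["cx", "cy", "z_start", "z_end", "radius_um", "region"]


@dataclass
class Volume:
    """A 3D scalar voxel grid with isotropic physical voxel size.

    Parameters
    ----------
    voxels
        3D array of gray values; stored as ``float32``.
    voxel_size_um
        Isotropic physical edge length of one voxel, in micrometres.
    """

    voxels: np.ndarray
    voxel_size_um: float
    axis_names: tuple[str, str, str] = AXIS_NAMES

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ConfigurationError(
                f"volume must be 3D with all extents >= 1, got shape {self.voxels.shape}"
            )
        if not self.voxel_size_um > 0:
            raise ConfigurationError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if not np.all(np.isfinite(self.voxels)):
            raise ConfigurationError("volume contains non-finite gray values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical centre coordinates (um) of integer voxel ``indices`` (n, 3)."""
        return (np.asarray(indices, dtype=np.float64) + 0.5) * self.voxel_size_um


@dataclass
class LabelMap:
    """Integer-labelled 3D mask sharing a Volume's grid; 0 is background."""

    labels: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ConfigurationError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigurationError("label map must have an integer dtype")
        if self.labels.size and self.labels.min() < 0:
            raise ConfigurationError("labels must be non-negative")
        if not self.voxel_size_um > 0:
            raise ConfigurationError("voxel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class SeedROI:
    """A circular in-plane ROI extruded over a coronal slice range.

    ``center`` is (axis-0, axis-1) voxel coordinates on the coronal plane;
    ``slice_range`` is an inclusive (start, end) pair of coronal slice
    indices along axis 2.
    """

    center: tuple[float, float]
    radius_um: float
    slice_range: tuple[int, int]
    region_tag: str = ""

    def validate(self, grid_shape: Sequence[int] | None = None) -> None:
        if not self.radius_um > 0:
            raise ConfigurationError(f"radius_um must be > 0, got {self.radius_um}")
        z0, z1 = self.slice_range
        if z0 > z1:
            raise ConfigurationError(f"slice_range start {z0} > end {z1}")
        if grid_shape is not None:
            cx, cy = self.center
            if not (0 <= cx < grid_shape[0] and 0 <= cy < grid_shape[1]):
                raise ConfigurationError(
                    f"seed center {self.center} outside grid {tuple(grid_shape)}"
                )


# ---------------------------------------------------------------------------
# Volume IO
# ---------------------------------------------------------------------------

def write_volume(volume: Volume, path: str | Path, format: str | None = None) -> None:
    """Write a volume to a multi-page TIFF stack or an HDF5 file.

    TIFF pages run along axis 2 (one page per coronal slice) and carry
    ImageJ-style voxel-size metadata.  HDF5 stores the grid unchanged in a
    ``/volume`` dataset with a ``voxel_size_um`` attribute.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "tiff-stack":
        pages = np.moveaxis(volume.voxels, 2, 0)  # page index = coronal slice
        res = 1.0 / volume.voxel_size_um
        tifffile.imwrite(
            path,
            pages,
            imagej=True,
            resolution=(res, res),
            metadata={"spacing": volume.voxel_size_um, "unit": "um", "axes": "ZYX"},
        )
    else:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=volume.voxels)
            ds.attrs["voxel_size_um"] = volume.voxel_size_um
            ds.attrs["axis_names"] = list(volume.axis_names)


def read_volume(
    path: str | Path,
    format: str | None = None,
    voxel_size_um: float | None = None,
) -> Volume:
    """Read a volume from TIFF stack or HDF5.

    ``voxel_size_um`` overrides/provides the voxel size; without it the file
    must carry voxel-size metadata or :class:`MissingMetadataError` is raised.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "tiff-stack":
        with tifffile.TiffFile(path) as tif:
            try:
                pages = tif.asarray()
            except Exception as exc:  # ragged pages etc.
                raise FormatError(f"cannot assemble TIFF stack {path}: {exc}") from exc
            vs = voxel_size_um
            if vs is None:
                meta = tif.imagej_metadata or {}
                vs = meta.get("spacing")
            if vs is None:
                raise MissingMetadataError(
                    f"{path}: no voxel-size metadata (ImageJ 'spacing') and no "
                    "voxel_size_um override given"
                )
        if pages.ndim == 2:
            pages = pages[None, ...]
        if pages.ndim != 3:
            raise FormatError(f"{path}: expected a 3D stack, got shape {pages.shape}")
        voxels = np.moveaxis(pages, 0, 2)
        return Volume(voxels=voxels, voxel_size_um=float(vs))
    with h5py.File(path, "r") as f:
        if "volume" not in f:
            raise FormatError(f"{path}: missing '/volume' dataset")
        ds = f["volume"]
        vs = voxel_size_um
        if vs is None:
            if "voxel_size_um" not in ds.attrs:
                raise MissingMetadataError(
                    f"{path}: '/volume' lacks the 'voxel_size_um' attribute and no "
                    "override was given"
                )
            vs = float(ds.attrs["voxel_size_um"])
        return Volume(voxels=ds[()], voxel_size_um=float(vs))


def _resolve_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tiff-stack", "hdf5"):
            raise ConfigurationError(f"unknown volume format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ConfigurationError(f"cannot infer volume format from suffix {suffix!r}")


def write_label_map(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as a multi-page TIFF stack (same page convention)."""
    arr = labels.labels
    dtype = np.uint16 if arr.max(initial=0) < 2**16 else np.uint32
    pages = np.moveaxis(arr.astype(dtype), 2, 0)
    res = 1.0 / labels.voxel_size_um
    tifffile.imwrite(
        path,
        pages,
        imagej=True,
        resolution=(res, res),
        metadata={"spacing": labels.voxel_size_um, "unit": "um", "axes": "ZYX"},
    )


def read_label_map(path: str | Path, voxel_size_um: float | None = None) -> LabelMap:
    """Read a label map written by :func:`write_label_map`."""
    vol = read_volume(path, format="tiff-stack", voxel_size_um=voxel_size_um)
    return LabelMap(labels=vol.voxels.astype(np.int64), voxel_size_um=vol.voxel_size_um)


# ---------------------------------------------------------------------------
# Seed ROI IO
# ---------------------------------------------------------------------------

def read_seed_rois(path: str | Path, grid_shape: Sequence[int] | None = None) -> list[SeedROI]:
    """Read seed ROIs from CSV or JSON.

    CSV columns: ``cx, cy, z_start, z_end, radius_um, region``.  Rows that
    violate seed invariants raise :class:`FormatError` naming the row number.
    An empty table yields an empty list.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows)
        if df.empty:
            return []
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return []
    if df.empty:
        return []
    missing = [c for c in SEED_COLUMNS if c not in df.columns and c != "region"]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    seeds: list[SeedROI] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            seed = SeedROI(
                center=(float(row.cx), float(row.cy)),
                radius_um=float(row.radius_um),
                slice_range=(int(row.z_start), int(row.z_end)),
                region_tag=str(getattr(row, "region", "")),
            )
            seed.validate(grid_shape)
        except (ValueError, ConfigurationError) as exc:
            raise FormatError(f"{path}: row {row_no}: {exc}") from exc
        seeds.append(seed)
    return seeds


def write_seed_rois(seeds: Sequence[SeedROI], path: str | Path) -> None:
    """Write seed ROIs to the canonical CSV layout."""
    df = pd.DataFrame(
        {
            "cx": [s.center[0] for s in seeds],
            "cy": [s.center[1] for s in seeds],
            "z_start": [s.slice_range[0] for s in seeds],
            "z_end": [s.slice_range[1] for s in seeds],
            "radius_um": [s.radius_um for s in seeds],
            "region": [s.region_tag for s in seeds],
        },
        columns=SEED_COLUMNS,
    )
    df.to_csv(path, index=False)
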