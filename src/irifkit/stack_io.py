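"""Containers and I/O for image stacks and SMLM localization tables.

Conventions fixed at this boundary (everything downstream relies on them):

* axis order is ``(z, y, x)``; multi-channel data is ``(c, z, y, x)``,
* image-space physical quantities are **micrometres**, localization-space
  quantities are **nanometres**,
* voxel indexing is 0-based; the physical origin sits at the corner of
  voxel ``(0, 0, 0)``, so voxel centre ``i`` maps to ``(i + 0.5) * voxel_size``.

Stacks are stored as multi-page TIFF (pages = z-planes with channels
interleaved: z0c0, z0c1, ..., z1c0, ...) with voxel sizes written both into
the TIFF resolution tags (x/y) and a JSON sidecar carrying the full
geometry and channel names. Localization tables ("orte matrices") are plain
CSV with a mandatory header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: required columns of an orte-matrix CSV, in canonical order
ORTE_COLUMNS = ["x_nm", "y_nm", "z_section", "frame", "precision_nm", "channel"]


@dataclass
class VolumeStack:
    """A multi-channel 3D intensity volume with physical voxel sizes.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, nz, ny, nx)``, arbitrary intensity
        units.
    voxel_size:
        Physical voxel edge lengths ``(dz, dy, dx)`` in µm.
    channel_names:
        One label per channel (e.g. ``("dapi", "gH2AX", "53BP1")``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (c, z, y, x), got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        """Return one channel volume ``(z, y, x)`` by its label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.data[idx]


@dataclass
class LabelMap:
    """Integer-labelled partition of a volume (0 = background)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z, y, x), got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class OrteMatrix:
    """SMLM localization list: coordinates, precision, frame, channel.

    Thin validated wrapper around a :class:`pandas.DataFrame` with columns
    ``x_nm, y_nm, z_section, frame, precision_nm, channel``. Coordinates are
    in nm within the acquisition plane; ``z_section`` indexes the 500-nm
    optical section the localization belongs to.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ORTE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"orte matrix is missing required column(s): {missing}")
        df = self.df[ORTE_COLUMNS].reset_index(drop=True)
        if len(df) and not (df["precision_nm"] > 0).all():
            raise ValueError("localization precision must be > 0")
        if len(df) and not np.isfinite(df[["x_nm", "y_nm"]].to_numpy(float)).all():
            raise ValueError("coordinates must be finite")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of in-plane coordinates in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(float)


# ---------------------------------------------------------------------------
# stack I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: VolumeStack, path: str | Path) -> Path:
    """Write *stack* as a multi-page TIFF plus a JSON metadata sidecar.

    Pages are z-major with channels interleaved. Returns the sidecar path.
    """
    path = Path(path)
    c, z, y, x = stack.data.shape
    pages = np.transpose(stack.data, (1, 0, 2, 3)).reshape(z * c, y, x)
    dz, dy, dx = stack.voxel_size
    # TIFF resolution tags are pixels per unit; store pixels per µm for x/y.
    tifffile.imwrite(
        path,
        pages,
        resolution=(1.0 / dx, 1.0 / dy),
        photometric="minisblack",
        metadata={"spacing": dz, "unit": "um", "axes": "QYX"},
    )
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "voxel_size_um": list(stack.voxel_size),
                "channel_names": list(stack.channel_names),
                "n_channels": c,
                "shape_zyx": [z, y, x],
                "dtype": str(stack.data.dtype),
                "page_order": "z-major, channels interleaved",
            },
            indent=1,
        )
    )
    return sidecar


def read_stack(
    path: str | Path,
    n_channels: int | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> VolumeStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Voxel sizes and channel layout come from the JSON sidecar when present,
    otherwise from the TIFF resolution tags (which requires *n_channels*).
    Raises if neither source provides the geometry, or if the channel count
    disagrees with the caller's expectation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = tuple(meta["voxel_size_um"])
        c = int(meta["n_channels"])
        names = tuple(meta["channel_names"])
    else:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            ij = tif.imagej_metadata or {}
        if xres is None or yres is None or "spacing" not in ij:
            raise ValueError(
                f"{path}: no voxel-size metadata (TIFF resolution tags + spacing "
                f"or sidecar {sidecar.name} required)"
            )
        dx = xres.value[1] / xres.value[0]
        dy = yres.value[1] / yres.value[0]
        voxel_size = (float(ij["spacing"]), float(dy), float(dx))
        if n_channels is None:
            raise ValueError(f"{path}: no sidecar; pass n_channels to deinterleave pages")
        c = n_channels
        names = tuple(f"ch{i}" for i in range(c))
    if n_channels is not None and n_channels != c:
        raise ValueError(f"{path}: expected {n_channels} channels, found {c}")
    if channel_names is not None:
        if len(channel_names) != c:
            raise ValueError(f"{path}: {len(channel_names)} names for {c} channels")
        names = tuple(channel_names)
    if pages.shape[0] % c:
        raise ValueError(f"{path}: {pages.shape[0]} pages not divisible by {c} channels")
    z = pages.shape[0] // c
    data = np.transpose(pages.reshape(z, c, *pages.shape[1:]), (1, 0, 2, 3))
    return VolumeStack(data=data, voxel_size=voxel_size, channel_names=names)


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    """Write a label map as 16-bit multi-page TIFF with a sidecar."""
    path = Path(path)
    if labels.n_labels > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"voxel_size_um": list(labels.voxel_size)}))
    return sidecar


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: sidecar {sidecar.name} with voxel size required")
    meta = json.loads(sidecar.read_text())
    arr = tifffile.imread(path).astype(np.int32)
    if arr.ndim == 2:
        arr = arr[None]
    return LabelMap(labels=arr, voxel_size=tuple(meta["voxel_size_um"]))


# ---------------------------------------------------------------------------
# orte-matrix I/O


def write_orte(orte: OrteMatrix, path: str | Path) -> None:
    """Write a localization table as CSV in the canonical column order."""
    orte.df.to_csv(path, index=False)


def read_orte(path: str | Path) -> OrteMatrix:
    """Read a localization CSV, dropping rows with non-finite coordinates.

    Rows removed this way are counted and logged as a warning; row order of
    the surviving localizations is preserved. A file containing only the
    header yields an empty table. A missing required column is an error
    naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ORTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    coords = df[["x_nm", "y_nm"]].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(coords.to_numpy(float)).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d localization(s) with non-finite coordinates", path, n_dropped)
        df = df[keep]
    return OrteMatrix(df=df.reset_index(drop=True))
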