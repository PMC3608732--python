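"""Reading and writing of image stacks, masks, curve tables and configuration.

A time-lapse movie travels through the pipeline as an :class:`ImageStack`:
a ``T x H x W`` array of 16-bit frames plus per-frame timestamps (seconds)
and the pixel size (micrometres per pixel).  On disk a stack is a lossless
multi-page grayscale TIFF accompanied by a JSON sidecar (``<stack>.json``)
carrying the acquisition metadata; vendor TIFF tag dialects vary too much
for embedded metadata to be the primary channel, although an embedded
``ImageDescription`` JSON blob is accepted as a fallback on read.

Binary compartment masks are exchanged with external editors as single-page
PNG or TIFF images (any nonzero pixel is "set"), matching the workflow in
which an automatically generated vessel mask is corrected by hand in a
drawing program and read back.

Curve tables (compartment intensity time courses, per-timepoint morphometry)
are written as plain UTF-8 CSV with "." decimals and Unix newlines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ConfigError, FormatError, MetadataError

__all__ = [
    "ImageStack",
    "CompartmentMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_curves",
    "read_curves",
    "load_config",
]

MASK_LABELS = ("vessel", "extravascular", "tumor_roi", "perfused")


@dataclass
class ImageStack:
    """A registered or raw time-lapse stack.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Nonnegative intensities in the 16-bit range.
    timestamps : ndarray, shape (T,)
        Acquisition times in seconds, strictly increasing.
    pixel_size : float
        Lateral pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise MetadataError(
                f"{self.frames.shape[0]} frames but {self.timestamps.size} timestamps"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise MetadataError("timestamps must be strictly increasing")
        if not self.pixel_size > 0:
            raise MetadataError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


@dataclass
class CompartmentMask:
    """Boolean pixel mask tagged with the compartment it labels."""

    grid: np.ndarray
    label: str = "vessel"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise FormatError(f"mask grid must be 2-D, got shape {self.grid.shape}")
        if self.label not in MASK_LABELS:
            raise ConfigError(f"unknown mask label {self.label!r}; expected one of {MASK_LABELS}")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path, extra_metadata: Mapping | None = None) -> Path:
    """Write a stack as a 16-bit multi-page TIFF plus a JSON sidecar.

    Returns the path of the TIFF file.  ``extra_metadata`` entries (seed,
    scenario, ground truth, ...) are merged into the sidecar.
    """
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.dtype != np.uint16:
        if frames.min() < 0 or frames.max() > np.iinfo(np.uint16).max:
            raise FormatError("frame values outside the 16-bit range")
        frames = frames.astype(np.uint16)
    meta = {
        "timestamps_s": [float(t) for t in stack.timestamps],
        "pixel_size_um": float(stack.pixel_size),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    try:
        tifffile.imwrite(path, frames, photometric="minisblack")
        _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    except OSError as exc:  # pragma: no cover - environment dependent
        from .exceptions import DataError

        raise DataError(f"I/O failure for {path}: {exc}") from exc
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack and its metadata.

    Timestamps and pixel size are taken from the JSON sidecar
    (``<stack>.json``); if the sidecar is absent, an embedded JSON
    ``ImageDescription`` tag is tried.  Missing metadata raises
    :class:`~vasculens.exceptions.MetadataError`.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected single-channel pages, got shape {frames.shape}")

    meta = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    else:  # tolerated fallback: embedded metadata
        with tifffile.TiffFile(path) as tif:
            desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = None
    if not isinstance(meta, dict):
        raise MetadataError(f"{path}: no sidecar JSON or embedded metadata found")
    if "timestamps_s" not in meta:
        raise MetadataError(f"{path}: metadata lacks 'timestamps_s'")
    if "pixel_size_um" not in meta:
        raise MetadataError(f"{path}: metadata lacks 'pixel_size_um'")
    return ImageStack(frames, np.asarray(meta["timestamps_s"], float), float(meta["pixel_size_um"]))


def read_stack_metadata(path: str | Path) -> dict:
    """Return the raw sidecar dictionary for a written stack."""
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        raise MetadataError(f"no sidecar JSON next to {path}")
    return json.loads(sidecar.read_text(encoding="utf-8"))


def write_mask(mask: CompartmentMask | np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit binary PNG or TIFF (255 = set)."""
    path = Path(path)
    grid = mask.grid if isinstance(mask, CompartmentMask) else np.asarray(mask, bool)
    img = np.where(grid, 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    return path


def read_mask(path: str | Path, label: str = "vessel") -> CompartmentMask:
    """Read a single-page binary image; any nonzero pixel is set.

    Multi-channel (RGB/RGBA) input is rejected: hand-edited masks must be
    exported as single-channel images so "set" is unambiguous.
    """
    path = Path(path)
    try:
        img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel 2-D, got shape {img.shape}")
    return CompartmentMask(img != 0, label=label)


CURVE_FLOAT_FORMAT = "%.8g"


def write_curves(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a time-indexed table as UTF-8 CSV ("." decimals, Unix newlines).

    The first column is expected to be ``time_s``; remaining columns are
    compartment or metric values, one row per timepoint.  An empty table
    produces a header-only file.
    """
    path = Path(path)
    table.to_csv(
        path,
        index=False,
        float_format=CURVE_FLOAT_FORMAT,
        lineterminator="\n",
        encoding="utf-8",
    )
    return path


def read_curves(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) run configuration into a dict."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    return cfg
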