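"""Skeleton-based morphometry of the perfused vessel network.

Per analysed timepoint the perfused-vessel mask within the tumour ROI is
reduced to a one-pixel-wide, 8-connected skeleton and four quantities are
measured:

* vascular length ``L_V`` — the skeleton length in micrometres, summed over
  8-neighbour adjacencies (1 pixel step for orthogonal neighbours, sqrt(2)
  for diagonal ones, each adjacency counted once).  Adjacency-weighted
  counting is used instead of raw pixel counting, which overestimates
  diagonal vessels by up to 41%;
* vascular area ``A_V`` — perfused pixels inside the ROI times the pixel
  area;
* tumour area ``A_T`` — ROI pixel count times the pixel area;
* the derived ratios ``FVD = L_V / A_T`` (functional vascular density,
  um^-1) and ``D_V = A_V / L_V`` (the length-weighted mean diameter of the
  perfused vessels, um).

When no vessel is perfused (complete vascular lock) ``L_V = 0``; FVD is 0
and D_V is reported as missing (NaN) rather than 0, so group averages are
not dragged down by fully locked tumours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import skeletonize as _skeletonize

from .exceptions import AnalysisError
from .segmentation import perfused_mask_at
from .stack_io import CompartmentMask, ImageStack

__all__ = [
    "MorphometryRecord",
    "skeletonize",
    "skeleton_length",
    "compute_morphometry",
    "morphometry_series",
    "records_to_frame",
]


@dataclass(frozen=True)
class MorphometryRecord:
    """Morphometry of one timepoint. Lengths um, areas um^2, FVD um^-1."""

    time: float
    lv_um: float
    av_um2: float
    at_um2: float
    fvd_per_um: float
    dv_um: float  # NaN when L_V = 0

    def __post_init__(self) -> None:
        if self.at_um2 <= 0:
            raise AnalysisError("tumor area must be positive")


def skeletonize(mask: CompartmentMask | np.ndarray) -> np.ndarray:
    """One-pixel-wide, topology-preserving medial skeleton of a binary mask."""
    grid = mask.grid if isinstance(mask, CompartmentMask) else np.asarray(mask, bool)
    if not grid.any():
        return np.zeros_like(grid)
    return _skeletonize(grid)


def skeleton_length(skeleton: np.ndarray, pixel_size: float) -> float:
    """Length of a 1-px skeleton in micrometres.

    Sums over 8-neighbour adjacencies of skeleton pixels: orthogonal
    neighbours contribute ``pixel_size``, diagonal ones
    ``sqrt(2) * pixel_size``; each unordered pair is counted once (only the
    E, S, SE and SW neighbours of each pixel are inspected).
    """
    sk = np.asarray(skeleton, bool)
    if not sk.any():
        return 0.0
    ortho = np.count_nonzero(sk[:, :-1] & sk[:, 1:]) + np.count_nonzero(sk[:-1, :] & sk[1:, :])
    diag = np.count_nonzero(sk[:-1, :-1] & sk[1:, 1:]) + np.count_nonzero(
        sk[:-1, 1:] & sk[1:, :-1]
    )
    return (ortho + diag * math.sqrt(2.0)) * pixel_size


def compute_morphometry(
    perfused_mask: CompartmentMask | np.ndarray,
    tumor_roi: CompartmentMask | np.ndarray,
    pixel_size: float,
    time: float = 0.0,
) -> MorphometryRecord:
    """Morphometry of one perfused mask within the tumour ROI."""
    p = perfused_mask.grid if isinstance(perfused_mask, CompartmentMask) else np.asarray(perfused_mask, bool)
    roi = tumor_roi.grid if isinstance(tumor_roi, CompartmentMask) else np.asarray(tumor_roi, bool)
    if p.shape != roi.shape:
        raise AnalysisError(f"mask shape {p.shape} != ROI shape {roi.shape}")
    roi_px = int(roi.sum())
    if roi_px == 0:
        raise AnalysisError("empty tumour ROI")
    inside = p & roi
    at = roi_px * pixel_size**2
    av = int(inside.sum()) * pixel_size**2
    lv = skeleton_length(skeletonize(inside), pixel_size)
    fvd = lv / at
    dv = av / lv if lv > 0 else float("nan")
    return MorphometryRecord(time, lv, av, at, fvd, dv)


def morphometry_series(
    stack: ImageStack,
    vessel_mask: CompartmentMask | np.ndarray,
    tumor_roi: CompartmentMask | np.ndarray,
    k_sd: float = 3.0,
    background: tuple[float, float] | None = None,
    background_frame_index: int | None = 0,
) -> list[MorphometryRecord]:
    """One morphometry record per timepoint, ordered by time.

    The perfused mask is re-detected at every frame (component-level tracer
    detection against the pre-injection background); the vessel mask and
    ROI are fixed, matching the workflow of one corrected mask reused with
    per-timepoint perfusion calls.
    """
    records = []
    for t_index, t in enumerate(stack.timestamps):
        perf = perfused_mask_at(
            stack,
            vessel_mask,
            t_index,
            k_sd=k_sd,
            background=background,
            background_frame_index=background_frame_index,
            tumor_roi=tumor_roi,
        )
        records.append(compute_morphometry(perf, tumor_roi, stack.pixel_size, float(t)))
    return records


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    """Tabular form with the stable CSV schema."""
    return pd.DataFrame(
        {
            "time_s": [r.time for r in records],
            "L_V_um": [r.lv_um for r in records],
            "A_V_um2": [r.av_um2 for r in records],
            "A_T_um2": [r.at_um2 for r in records],
            "FVD_per_um": [r.fvd_per_um for r in records],
            "D_V_um": [r.dv_um for r in records],
        }
    )
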