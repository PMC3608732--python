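"""Compartment intensity time courses and physiological readouts.

The mean fluorescence intensity of each compartment (intravascular =
vessel-mask pixels, extravascular = tumour-ROI pixels outside the vessels)
is computed at every timepoint and expressed as a percentage of the maximum
mean intensity reached over the observation period (Imax), which serves as
the 100% normalisation anchor per curve.  Permeability changes are read
from the relative variation of the extravascular curve with respect to a
pre-treatment baseline window.

Three scalar readouts summarise a movie:

* ``filling_time`` — when the normalised intravascular curve first reaches
  a given fraction of Imax (healthy tumour vessels fill to ~80% within
  2 minutes of injection);
* ``lock_duration`` — how long the functional vascular density stays below
  a small fraction of its pre-treatment baseline after treatment ("complete
  vascular lock"); censored when the lock outlasts the observation window;
* ``leakage_onset`` — when the extravascular relative variation first rises
  persistently above the baseline noise band, reported relative to the
  treatment time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import AnalysisError, ConfigError
from .morphometry import MorphometryRecord
from .stack_io import CompartmentMask, ImageStack

__all__ = [
    "CompartmentCurve",
    "compartment_means",
    "normalize_to_imax",
    "relative_variation",
    "filling_time",
    "lock_duration",
    "leakage_onset",
]

DEFAULT_LOCK_FRACTION = 0.05
DEFAULT_ONSET_K_SD = 2.0
DEFAULT_ONSET_PERSISTENCE = 2


@dataclass(frozen=True)
class CompartmentCurve:
    """Mean-intensity time series of one compartment.

    ``normalized`` is ``100 * mean_intensity / imax`` (percent of Imax);
    both are ``None`` until :func:`normalize_to_imax` has run.
    """

    compartment: str
    times: np.ndarray
    mean_intensity: np.ndarray
    imax: float | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "mean_intensity", np.asarray(self.mean_intensity, float))
        if self.times.shape != self.mean_intensity.shape:
            raise AnalysisError("times and mean_intensity must have the same length")


def compartment_means(stack: ImageStack, mask: CompartmentMask | np.ndarray, compartment: str | None = None) -> CompartmentCurve:
    """Arithmetic mean of the intensities over the mask pixels, per frame."""
    grid = mask.grid if isinstance(mask, CompartmentMask) else np.asarray(mask, bool)
    if grid.shape != stack.frame_shape:
        raise AnalysisError(f"mask shape {grid.shape} != frame shape {stack.frame_shape}")
    if not grid.any():
        raise AnalysisError("empty mask: compartment mean undefined")
    name = compartment or (mask.label if isinstance(mask, CompartmentMask) else "compartment")
    means = stack.frames[:, grid].mean(axis=1)
    return CompartmentCurve(name, stack.timestamps, means)


def normalize_to_imax(curve: CompartmentCurve) -> CompartmentCurve:
    """Express the curve as percent of its own maximum (Imax).

    Idempotent: normalising an already-normalised curve changes nothing.
    The peak of the normalised series is exactly 100.
    """
    imax = float(curve.mean_intensity.max())
    if imax <= 0:
        raise AnalysisError("all-zero curve: Imax undefined")
    return replace(curve, imax=imax, normalized=100.0 * curve.mean_intensity / imax)


def _baseline_values(times: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = (times >= lo) & (times < hi)
    if not sel.any():
        raise AnalysisError(f"empty baseline window [{lo}, {hi}) s")
    return values[sel]


def relative_variation(curve: CompartmentCurve, baseline_window: tuple[float, float]) -> np.ndarray:
    """Per-timepoint relative change w.r.t. the baseline-window mean.

    ``(value - baseline_mean) / baseline_mean``.  The baseline window is
    a half-open time interval ``[start_s, end_s)``; by convention it spans
    the frames between injection-plus-filling and treatment.
    """
    base = _baseline_values(curve.times, curve.mean_intensity, baseline_window)
    m = float(base.mean())
    if m <= 0:
        raise AnalysisError("baseline mean must be positive for relative variation")
    return (curve.mean_intensity - m) / m


def filling_time(curve: CompartmentCurve, fraction: float = 80.0) -> float:
    """Earliest sampled time at which the normalised curve reaches ``fraction`` %.

    Returns NaN when the fraction is never reached.  The answer has the
    resolution of the sampling grid (one frame interval), which matches the
    resolution at which such onsets can be stated at all.
    """
    if not 0 < fraction <= 100:
        raise ConfigError("fraction must be in (0, 100]")
    if curve.normalized is None:
        curve = normalize_to_imax(curve)
    idx = np.flatnonzero(curve.normalized >= fraction)
    if idx.size == 0:
        return float("nan")
    return float(curve.times[idx[0]])


def lock_duration(
    records: list[MorphometryRecord] | tuple[np.ndarray, np.ndarray],
    baseline_fvd: float,
    treatment_time: float,
    fraction: float = DEFAULT_LOCK_FRACTION,
) -> tuple[float, bool]:
    """Duration (s) of the complete vascular lock, plus a censoring flag.

    The lock is the maximal contiguous run, starting at the treatment time,
    during which FVD <= ``fraction * baseline_fvd``.  Its endpoint is the
    threshold crossing linearly interpolated between the last sub-threshold
    frame and the first frame exceeding the threshold.  If FVD never drops
    below the threshold the duration is 0; if it never re-emerges the
    duration is the remaining observation span and the censored flag is set.
    """
    if isinstance(records, tuple):
        times, fvd = (np.asarray(a, float) for a in records)
    else:
        times = np.asarray([r.time for r in records], float)
        fvd = np.asarray([r.fvd_per_um for r in records], float)
    if not baseline_fvd > 0:
        raise AnalysisError("baseline FVD must be positive")
    if treatment_time < times[0] or treatment_time > times[-1]:
        raise AnalysisError(
            f"treatment time {treatment_time} s outside series [{times[0]}, {times[-1]}] s"
        )
    threshold = fraction * baseline_fvd
    post = times >= treatment_time
    t_post, f_post = times[post], fvd[post]
    if t_post.size == 0 or f_post[0] > threshold:
        return 0.0, False
    above = np.flatnonzero(f_post > threshold)
    if above.size == 0:
        return float(t_post[-1] - treatment_time), True
    i = int(above[0])  # first frame exceeding the threshold; i >= 1 here
    t_a, v_a = t_post[i - 1], f_post[i - 1]
    t_b, v_b = t_post[i], f_post[i]
    t_cross = t_a + (threshold - v_a) / (v_b - v_a) * (t_b - t_a)
    return float(t_cross - treatment_time), False


def leakage_onset(
    times: np.ndarray,
    relvar: np.ndarray,
    baseline_window: tuple[float, float],
    treatment_time: float,
    k_sd: float = DEFAULT_ONSET_K_SD,
    persistence: int = DEFAULT_ONSET_PERSISTENCE,
) -> float:
    """Onset (s after treatment) of persistent extravascular signal rise.

    The first timestamp at which the relative-variation series exceeds
    ``baseline mean + k_sd * baseline SD`` for ``persistence`` consecutive
    frames; the persistence filter keeps single-frame noise spikes from
    triggering.  Returns NaN when no qualifying run exists.
    """
    times = np.asarray(times, float)
    relvar = np.asarray(relvar, float)
    if baseline_window[1] > treatment_time:
        raise ConfigError("baseline window must precede the treatment time")
    base = _baseline_values(times, relvar, baseline_window)
    threshold = float(base.mean()) + k_sd * float(base.std(ddof=1) if base.size > 1 else 0.0)
    post = np.flatnonzero(times >= treatment_time)
    exceed = relvar[post] > threshold
    run = 0
    for j, flag in enumerate(exceed):
        run = run + 1 if flag else 0
        if run >= persistence:
            start = post[j - persistence + 1]
            return float(times[start] - treatment_time)
    return float("nan")
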