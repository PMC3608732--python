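"""Synthetic dorsal-window-chamber movie generator with full ground truth.

The generator emulates the acquisition protocol used for intravital imaging
of tumour vasculature after intra-orbital injection of a 70-kDa fluorescent
dextran: two 2-minute image series at 20-second intervals separated by a
20-second pause (during which electric pulses are applied, where
applicable), followed by a 58-minute series at 2-minute intervals.

A scene consists of

* a vessel network — tortuous polyline centrelines with per-segment
  diameters, rasterised by centreline dilation (disk of radius diameter/2,
  8-connected, no anti-aliasing so masks are pixel-exact);
* tracer pharmacokinetics — a mono-exponential plasma filling curve
  ``A * (1 - exp(-(t - t0)/tau))`` and a one-way extravasation integrator
  ``dC_ev/dt = k_perm * C_iv`` gated off before the leakage onset and
  whenever the local vessel carries no tracer;
* a perfusion scenario — binary perfused/unperfused state per segment per
  timepoint, modelling an untreated control, bleomycin-only, a
  reversible post-pulse "vascular lock" with staggered re-perfusion (EP),
  or a persistent lock with at most a peripheral fraction re-perfused
  (ECT, i.e. pulses plus bleomycin);
* a noise/drift model — Gaussian read noise, intensity-scaled shot noise,
  and integer-pixel cumulative field drift.

Everything the analysis pipeline is later asked to estimate (skeleton
length L_V, vascular area A_V, tumour area A_T, functional vascular density
FVD = L_V/A_T, length-weighted diameter D_V = A_V/L_V, perfusion timelines,
kinetic constants, injected drift) is recorded analytically in a
:class:`SceneTruth` object.  Identical inputs and seed produce bit-identical
stacks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon2mask

from .exceptions import ConfigError
from .stack_io import ImageStack

__all__ = [
    "VesselNetworkSpec",
    "VesselSegment",
    "PerfusionScenario",
    "TracerKinetics",
    "AcquisitionSchedule",
    "NoiseModel",
    "SceneTruth",
    "build_network",
    "plasma_concentration",
    "extravascular_concentration",
    "render_frame",
    "simulate_stack",
]

# Intensity of the unlabeled tissue background (16-bit counts).  Kept well
# above zero so shot noise and relative-variation baselines behave.
BACKGROUND_LEVEL = 100.0

# Width of the extravascular band around a leaking vessel that receives the
# extravasated tracer, in micrometres.
HALO_WIDTH_UM = 25.0

#: Default filling time constant: the plasma curve reaches 80% of its
#: plateau 2 minutes after injection, 120/ln(5) s.
DEFAULT_TAU_S = 120.0 / math.log(5.0)


def _default_roi(height: int, width: int) -> tuple[tuple[float, float], ...]:
    """Rectangular tumour ROI inset 10% from every field edge (row, col)."""
    r0, r1 = 0.1 * height, 0.9 * height
    c0, c1 = 0.1 * width, 0.9 * width
    return ((r0, c0), (r0, c1), (r1, c1), (r1, c0))


@dataclass(frozen=True)
class VesselNetworkSpec:
    """Geometry recipe for a synthetic vessel network.

    Lengths are micrometres; coordinates are 0-based row-major pixels.
    ``tumor_roi`` is a closed polygon of (row, col) vertices (even-odd fill)
    that must lie inside the field.  ``diameters_um``, when given, overrides
    random sampling; ``calibrate_lw_diameter_um``, when given, rescales all
    diameters so the ROI length-weighted mean diameter of the network equals
    it exactly (this is how the control scene pins its true D_V).
    """

    field_height_px: int = 420
    field_width_px: int = 420
    pixel_size: float = 1.0
    tumor_roi: tuple[tuple[float, float], ...] | None = None
    n_segments: int = 8
    diameter_mean: float = 20.0
    diameter_sd: float = 3.0
    tortuosity: float = 0.08
    seed: int = 0
    diameters_um: tuple[float, ...] | None = None
    calibrate_lw_diameter_um: float | None = 20.0

    def roi_polygon(self) -> tuple[tuple[float, float], ...]:
        if self.tumor_roi is not None:
            return tuple((float(r), float(c)) for r, c in self.tumor_roi)
        return _default_roi(self.field_height_px, self.field_width_px)

    def validate(self) -> None:
        if self.n_segments <= 0:
            raise ConfigError(f"n_segments must be positive, got {self.n_segments}")
        if self.field_height_px <= 0 or self.field_width_px <= 0:
            raise ConfigError("field dimensions must be positive")
        if not self.pixel_size > 0:
            raise ConfigError("pixel_size must be positive")
        if not self.diameter_mean > 0:
            raise ConfigError("diameter_mean must be positive")
        if self.tortuosity < 0:
            raise ConfigError("tortuosity must be >= 0")
        for r, c in self.roi_polygon():
            if not (0 <= r <= self.field_height_px and 0 <= c <= self.field_width_px):
                raise ConfigError("tumor_roi vertex outside the field")
        if self.diameters_um is not None and len(self.diameters_um) != self.n_segments:
            raise ConfigError("diameters_um length must equal n_segments")


@dataclass(frozen=True)
class VesselSegment:
    """One vessel: a polyline centreline (pixel coords) with a diameter."""

    centerline: np.ndarray  # (N, 2) float (row, col)
    diameter: float  # um
    region_tag: str = "tumor"  # "tumor" | "peritumoral"

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, float)
        object.__setattr__(self, "centerline", pts)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ConfigError("centerline must be an (N>=2, 2) point array")
        if not self.diameter > 0:
            raise ConfigError("segment diameter must be positive")

    def length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.centerline, axis=0).T)))


@dataclass(frozen=True)
class PerfusionScenario:
    """Binary perfusion timeline for every segment.

    ``reperfusion_times`` holds, per segment, the absolute time (s) at which
    flow returns after the lock, or ``None`` for a segment that never
    re-perfuses.  An empty tuple means no treatment effect at all (control /
    bleomycin-only).  Before ``lock_start`` every segment is perfused.
    """

    scenario: str = "control"
    treatment_time: float = 130.0
    lock_start: float = 130.0
    reperfusion_times: tuple[float | None, ...] = ()
    perfused_fraction_late: float = 1.0

    def validate(self, n_segments: int) -> None:
        if self.lock_start < self.treatment_time:
            raise ConfigError("lock_start must be >= treatment_time")
        if self.reperfusion_times and len(self.reperfusion_times) != n_segments:
            raise ConfigError(
                f"scenario lists {len(self.reperfusion_times)} reperfusion times "
                f"for {n_segments} segments"
            )
        for rt in self.reperfusion_times:
            if rt is not None and rt < self.lock_start:
                raise ConfigError("reperfusion_time must be >= lock_start")
        if not 0.0 <= self.perfused_fraction_late <= 1.0:
            raise ConfigError("perfused_fraction_late must be in [0, 1]")

    def perfused(self, segment_index: int, t: float) -> bool:
        """Flow state of one segment at time ``t`` (binary)."""
        if not self.reperfusion_times:
            return True
        if t < self.lock_start:
            return True
        rt = self.reperfusion_times[segment_index]
        return rt is not None and t >= rt

    # -- factories ---------------------------------------------------------

    @staticmethod
    def control(treatment_time: float = 130.0) -> "PerfusionScenario":
        return PerfusionScenario("control", treatment_time, treatment_time, ())

    @staticmethod
    def bleomycin(treatment_time: float = 130.0) -> "PerfusionScenario":
        # Drug alone does not lock tumour vessels.
        return PerfusionScenario("bleomycin", treatment_time, treatment_time, ())

    @staticmethod
    def ep(
        n_segments: int,
        treatment_time: float = 130.0,
        reperfusion_onset: float = 600.0,
        stagger: float = 60.0,
        reperfused_fraction: float = 0.5,
        diameters: Sequence[float] | None = None,
        select: str = "first",
    ) -> "PerfusionScenario":
        """Complete lock at treatment, staggered re-perfusion of a fraction.

        ``reperfusion_onset`` is measured from the treatment time.  With
        ``select="largest"`` the re-perfusing subset is the largest-diameter
        segments (requires ``diameters``); otherwise the first ones.
        """
        n_re = int(round(reperfused_fraction * n_segments))
        if select == "largest":
            if diameters is None:
                raise ConfigError("select='largest' requires segment diameters")
            order = list(np.argsort(np.asarray(diameters))[::-1][:n_re])
        else:
            order = list(range(n_re))
        times: list[float | None] = [None] * n_segments
        for rank, idx in enumerate(order):
            times[idx] = treatment_time + reperfusion_onset + rank * stagger
        return PerfusionScenario(
            "EP", treatment_time, treatment_time, tuple(times),
            perfused_fraction_late=n_re / n_segments,
        )

    @staticmethod
    def ect(
        n_segments: int,
        treatment_time: float = 130.0,
        perfused_fraction_late: float = 0.0,
        reperfusion_onset: float = 1800.0,
        region_tags: Sequence[str] | None = None,
    ) -> "PerfusionScenario":
        """Persistent lock; at most a small peripheral fraction re-perfuses."""
        n_re = int(round(perfused_fraction_late * n_segments))
        candidates = list(range(n_segments))
        if region_tags is not None:
            peri = [i for i, tag in enumerate(region_tags) if tag == "peritumoral"]
            candidates = peri + [i for i in candidates if i not in peri]
        times: list[float | None] = [None] * n_segments
        for idx in candidates[:n_re]:
            times[idx] = treatment_time + reperfusion_onset
        return PerfusionScenario(
            "ECT", treatment_time, treatment_time, tuple(times),
            perfused_fraction_late=perfused_fraction_late,
        )

    @staticmethod
    def named(name: str, n_segments: int, **kwargs) -> "PerfusionScenario":
        factories = {
            "control": lambda: PerfusionScenario.control(**kwargs),
            "bleomycin": lambda: PerfusionScenario.bleomycin(**kwargs),
            "EP": lambda: PerfusionScenario.ep(n_segments, **kwargs),
            "ECT": lambda: PerfusionScenario.ect(n_segments, **kwargs),
        }
        if name not in factories:
            raise ConfigError(
                f"unknown scenario {name!r}; expected one of {sorted(factories)}"
            )
        return factories[name]()


@dataclass(frozen=True)
class TracerKinetics:
    """Phenomenological dextran pharmacokinetics.

    ``injection_time`` t0 (s); filling time constant ``tau`` (s); plateau
    ``plateau`` (intensity counts); permeability-like leak rate ``k_perm``
    (1/s); ``leakage_onset_delay`` (s, measured from t0) before which no
    extravasation occurs.
    """

    injection_time: float = 0.0
    tau: float = DEFAULT_TAU_S
    plateau: float = 30000.0
    k_perm: float = 0.0
    leakage_onset_delay: float = 0.0

    def validate(self) -> None:
        if not self.tau > 0:
            raise ConfigError("tau must be positive")
        if not self.plateau > 0:
            raise ConfigError("plateau must be positive")
        if self.k_perm < 0 or self.leakage_onset_delay < 0:
            raise ConfigError("k_perm and leakage_onset_delay must be >= 0")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """A list of (start_s, interval_s, duration_s) acquisition series.

    A frame is taken at ``start + k*interval`` for every k with
    ``k*interval <= duration``.  The default reproduces the intravital
    protocol: 20-s frames for 2 min, a 20-s pause, 20-s frames for 2 min,
    then 2-min frames for 58 min.
    """

    series: tuple[tuple[float, float, float], ...] = (
        (0.0, 20.0, 120.0),
        (140.0, 20.0, 120.0),
        (380.0, 120.0, 3480.0),
    )
    bit_depth: int = 16

    def timestamps(self) -> np.ndarray:
        ts: list[float] = []
        for start, interval, duration in self.series:
            if interval <= 0 or duration < 0:
                raise ConfigError("schedule series needs interval > 0 and duration >= 0")
            n = int(math.floor(duration / interval + 1e-9)) + 1
            ts.extend(start + k * interval for k in range(n))
        arr = np.asarray(ts, float)
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ConfigError("schedule timestamps must be strictly increasing")
        return arr

    @staticmethod
    def default() -> "AcquisitionSchedule":
        return AcquisitionSchedule()


@dataclass(frozen=True)
class NoiseModel:
    """Additive read noise, intensity-scaled shot noise, and field drift.

    ``drift_per_frame`` is a (dy, dx) pixel displacement per frame; the
    cumulative shift applied to frame k is rounded to integer pixels so
    translation-only registration can recover it exactly.
    """

    read_noise_sd: float = 30.0
    photon_scale: float = 1.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def validate(self) -> None:
        if self.read_noise_sd < 0 or self.photon_scale < 0:
            raise ConfigError("noise amplitudes must be >= 0")

    def cumulative_shift(self, frame_index: int) -> tuple[int, int]:
        dy, dx = self.drift_per_frame
        return (int(round(frame_index * dy)), int(round(frame_index * dx)))


@dataclass
class SceneTruth:
    """Analytic ground truth of a simulated scene.

    Geometry (within the tumour ROI): per-segment ROI-clipped centreline
    lengths and diameters, L_V (um), A_V (um^2), A_T (um^2),
    FVD = L_V/A_T (um^-1) and the length-weighted D_V = A_V/L_V (um) —
    the two identities hold exactly by construction.  Perfusion: the binary
    flow state of every segment at every timestamp, plus the scenario's
    treatment/lock/re-perfusion times.  Acquisition: kinetic constants and
    the integer drift shift injected into every frame.
    """

    diameters_um: list[float]
    segment_lengths_um: list[float]  # ROI-clipped centreline lengths
    region_tags: list[str]
    lv_um: float
    av_um2: float
    at_um2: float
    fvd_per_um: float
    dv_um: float
    pixel_size: float
    seed: int
    timestamps_s: list[float] = field(default_factory=list)
    perfusion: list[list[bool]] = field(default_factory=list)  # [segment][frame]
    scenario: str = "control"
    treatment_time_s: float | None = None
    lock_start_s: float | None = None
    reperfusion_times_s: list[float | None] = field(default_factory=list)
    kinetics: dict = field(default_factory=dict)
    drift_shifts: list[tuple[int, int]] = field(default_factory=list)

    def perfused_dv_um(self, t: float) -> float:
        """True length-weighted diameter over segments perfused at time t."""
        if not self.timestamps_s:
            return self.dv_um
        idx = int(np.argmin(np.abs(np.asarray(self.timestamps_s) - t)))
        num = den = 0.0
        for d, length, flags in zip(self.diameters_um, self.segment_lengths_um, self.perfusion):
            if flags[idx]:
                num += length * d
                den += length
        return num / den if den > 0 else float("nan")

    def to_json_dict(self) -> dict:
        return {
            "diameters_um": self.diameters_um,
            "segment_lengths_um": self.segment_lengths_um,
            "region_tags": self.region_tags,
            "lv_um": self.lv_um,
            "av_um2": self.av_um2,
            "at_um2": self.at_um2,
            "fvd_per_um": self.fvd_per_um,
            "dv_um": self.dv_um,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
            "timestamps_s": self.timestamps_s,
            "perfusion": [[bool(b) for b in row] for row in self.perfusion],
            "scenario": self.scenario,
            "treatment_time_s": self.treatment_time_s,
            "lock_start_s": self.lock_start_s,
            "reperfusion_times_s": self.reperfusion_times_s,
            "kinetics": self.kinetics,
            "drift_shifts": [list(s) for s in self.drift_shifts],
        }

    @staticmethod
    def from_json_dict(d: dict) -> "SceneTruth":
        truth = SceneTruth(
            diameters_um=list(d["diameters_um"]),
            segment_lengths_um=list(d["segment_lengths_um"]),
            region_tags=list(d["region_tags"]),
            lv_um=d["lv_um"],
            av_um2=d["av_um2"],
            at_um2=d["at_um2"],
            fvd_per_um=d["fvd_per_um"],
            dv_um=d["dv_um"],
            pixel_size=d["pixel_size"],
            seed=d["seed"],
        )
        truth.timestamps_s = list(d.get("timestamps_s", []))
        truth.perfusion = [list(row) for row in d.get("perfusion", [])]
        truth.scenario = d.get("scenario", "control")
        truth.treatment_time_s = d.get("treatment_time_s")
        truth.lock_start_s = d.get("lock_start_s")
        truth.reperfusion_times_s = list(d.get("reperfusion_times_s", []))
        truth.kinetics = dict(d.get("kinetics", {}))
        truth.drift_shifts = [tuple(s) for s in d.get("drift_shifts", [])]
        return truth


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def _wandering_polyline(
    rng: np.random.Generator,
    row0: float,
    width: int,
    tortuosity: float,
    row_lo: float,
    row_hi: float,
    step: float = 3.0,
) -> np.ndarray:
    """A left-to-right polyline whose heading jitters by N(0, tortuosity) rad."""
    pts = [(row0, 0.0)]
    r, c = row0, 0.0
    while c < width - 1:
        theta = rng.normal(0.0, tortuosity) if tortuosity > 0 else 0.0
        c = min(c + step * math.cos(theta), float(width - 1))
        r = float(np.clip(r + step * math.sin(theta), row_lo, row_hi))
        pts.append((r, c))
    return np.asarray(pts, float)


def build_network(spec: VesselNetworkSpec) -> tuple[list[VesselSegment], SceneTruth]:
    """Generate the vessel segments and the analytic scene geometry.

    Segments are laid out as roughly parallel, slightly tortuous polylines on
    jittered, evenly spaced rows (spaced so vessel cross-sections do not
    merge, keeping one connected component per vessel).  Diameters are drawn
    from N(diameter_mean, diameter_sd) clipped to > 2 px, unless given
    explicitly.  Ground-truth morphometry is computed analytically: lengths
    are ROI-clipped polyline lengths, areas are length x diameter, and
    A_T is the exact polygon area.  Deterministic in ``spec.seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    d_rng, path_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    H, W, px = spec.field_height_px, spec.field_width_px, spec.pixel_size
    n = spec.n_segments

    if spec.diameters_um is not None:
        diameters = np.asarray(spec.diameters_um, float).copy()
        if np.any(diameters <= 0):
            raise ConfigError("explicit diameters must be positive")
    else:
        diameters = d_rng.normal(spec.diameter_mean, spec.diameter_sd, size=n)
        # symmetric truncation: keeps extreme draws from making neighbouring
        # vessels touch, without biasing the mean
        diameters = np.clip(
            diameters,
            spec.diameter_mean - 2.5 * spec.diameter_sd,
            spec.diameter_mean + 2.5 * spec.diameter_sd,
        )
    diameters = np.maximum(diameters, 2.0 * px * (1.0 + 1e-9))  # resolvable

    roi_pts = spec.roi_polygon()
    roi_poly = Polygon(roi_pts)
    if not roi_poly.is_valid or roi_poly.area <= 0:
        raise ConfigError("tumor_roi polygon is degenerate")

    # Vessels cross the tumour: rows are spread over the ROI's row extent
    # (with jitter), spaced so neighbouring vessel cross-sections stay
    # disjoint and each vessel remains one connected component.
    r_lo, _, r_hi, _ = roi_poly.bounds
    spacing = (r_hi - r_lo) / (n + 1)
    rows = [
        r_lo + (i + 1) * spacing + path_rng.uniform(-spacing / 8, spacing / 8)
        for i in range(n)
    ]
    polylines = []
    for i in range(n):
        # confine each centreline to a band around its row so that adjacent
        # vessel cross-sections cannot touch (one connected component per
        # vessel, which the per-component perfusion detector relies on)
        band = max(0.375 * spacing - diameters[i] / (2 * px) - 1.0, 1.0)
        margin = diameters[i] / (2 * px) + 1
        polylines.append(
            _wandering_polyline(
                path_rng, rows[i], W, spec.tortuosity,
                row_lo=max(rows[i] - band, margin),
                row_hi=min(rows[i] + band, H - 1 - margin),
            )
        )

    clipped_lengths_px = np.array(
        [LineString(p).intersection(roi_poly).length for p in polylines]
    )
    clipped_lengths_um = clipped_lengths_px * px

    if spec.calibrate_lw_diameter_um is not None:
        lw = float(np.sum(clipped_lengths_um * diameters) / np.sum(clipped_lengths_um))
        diameters = diameters * (spec.calibrate_lw_diameter_um / lw)

    segments = []
    for i in range(n):
        mid = polylines[i][len(polylines[i]) // 2]
        tag = "tumor" if roi_poly.contains(Point(mid[0], mid[1])) else "peritumoral"
        segments.append(VesselSegment(polylines[i], float(diameters[i]), tag))

    lv = float(np.sum(clipped_lengths_um))
    av = float(np.sum(clipped_lengths_um * diameters))
    at = float(roi_poly.area) * px * px
    truth = SceneTruth(
        diameters_um=[float(d) for d in diameters],
        segment_lengths_um=[float(v) for v in clipped_lengths_um],
        region_tags=[s.region_tag for s in segments],
        lv_um=lv,
        av_um2=av,
        at_um2=at,
        fvd_per_um=lv / at,
        dv_um=av / lv if lv > 0 else float("nan"),
        pixel_size=px,
        seed=spec.seed,
    )
    return segments, truth


# ---------------------------------------------------------------------------
# Tracer kinetics
# ---------------------------------------------------------------------------


def plasma_concentration(t: float | np.ndarray, k: TracerKinetics) -> np.ndarray | float:
    """Intravascular tracer level: mono-exponential rise to the plateau.

    0 before the injection; ``A * (1 - exp(-(t - t0)/tau))`` after.
    Monotone nondecreasing in t.
    """
    t = np.asarray(t, float)
    dt = np.maximum(t - k.injection_time, 0.0)
    out = k.plateau * (1.0 - np.exp(-dt / k.tau))
    return float(out) if out.ndim == 0 else out


def extravascular_concentration(
    times: Sequence[float],
    k: TracerKinetics,
    perfusion_gate: Sequence[bool] | None = None,
) -> np.ndarray:
    """One-way extravasation integrated on the sampling grid.

    Forward-Euler accumulation of ``dC_ev/dt = k_perm * C_iv(t)``, with the
    rate forced to zero before ``t0 + leakage_onset_delay`` and at any step
    where the local vessel is unperfused (no intravascular tracer supply,
    hence no efflux).  The result is monotone nondecreasing; there is no
    backflux.
    """
    times = np.asarray(times, float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ConfigError("times must be strictly increasing")
    if perfusion_gate is None:
        gate = np.ones(times.size, bool)
    else:
        gate = np.asarray(perfusion_gate, bool)
        if gate.shape != times.shape:
            raise ConfigError("perfusion gate must match times in length")
    c_iv = plasma_concentration(times, k)
    onset = k.injection_time + k.leakage_onset_delay
    c_ev = np.zeros(times.size)
    for i in range(1, times.size):
        dt = times[i] - times[i - 1]
        rate = k.k_perm * c_iv[i - 1] if (gate[i - 1] and times[i - 1] >= onset) else 0.0
        c_ev[i] = c_ev[i - 1] + rate * dt
    return c_ev


# ---------------------------------------------------------------------------
# Rasterisation and rendering
# ---------------------------------------------------------------------------


def _rasterize_segment(
    segment: VesselSegment, shape: tuple[int, int], pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vessel mask (centreline dilated to the diameter) and leak halo mask."""
    H, W = shape
    canvas = np.ones(shape, bool)
    pts = segment.centerline
    # densely sample the polyline and mark nearest pixels
    seglens = np.hypot(*np.diff(pts, axis=0).T)
    for (p0, p1), L in zip(zip(pts[:-1], pts[1:]), seglens):
        nsamp = max(int(math.ceil(L / 0.5)), 1) + 1
        for s in np.linspace(0.0, 1.0, nsamp):
            r = int(round(p0[0] + s * (p1[0] - p0[0])))
            c = int(round(p0[1] + s * (p1[1] - p0[1])))
            if 0 <= r < H and 0 <= c < W:
                canvas[r, c] = False
    dist = distance_transform_edt(canvas)
    radius_px = segment.diameter / (2.0 * pixel_size)
    if radius_px < 0.5:
        warnings.warn(
            f"segment diameter {segment.diameter:.2f} um is below one pixel; "
            "rendering 1 px wide",
            stacklevel=2,
        )
        radius_px = 0.5
    vessel = dist <= radius_px
    halo = (dist > radius_px) & (dist <= radius_px + HALO_WIDTH_UM / pixel_size)
    return vessel, halo


class _RasterCache:
    """Per-segment vessel and halo rasters, computed once per scene."""

    def __init__(self, segments: Sequence[VesselSegment], shape: tuple[int, int], pixel_size: float):
        self.shape = shape
        self.vessel_masks = []
        self.halo_masks = []
        for seg in segments:
            v, h = _rasterize_segment(seg, shape, pixel_size)
            self.vessel_masks.append(v)
            self.halo_masks.append(h)

    def union_vessel_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, bool)
        for m in self.vessel_masks:
            out |= m
        return out


def _translate(img: np.ndarray, shift: tuple[int, int], fill: float) -> np.ndarray:
    """Integer-pixel translation with constant fill (no wrap-around)."""
    dy, dx = shift
    out = np.full_like(img, fill)
    H, W = img.shape
    ys = slice(max(dy, 0), min(H + dy, H))
    xs = slice(max(dx, 0), min(W + dx, W))
    ys_src = slice(max(-dy, 0), min(H - dy, H))
    xs_src = slice(max(-dx, 0), min(W - dx, W))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def render_frame(
    segments: Sequence[VesselSegment],
    perfused: Sequence[bool],
    c_iv: float,
    c_ev: Sequence[float],
    noise: NoiseModel,
    frame_index: int,
    *,
    pixel_size: float,
    shape: tuple[int, int] | None = None,
    background: float = BACKGROUND_LEVEL,
    rng: np.random.Generator | None = None,
    raster: _RasterCache | None = None,
) -> np.ndarray:
    """Render one 16-bit frame.

    Perfused segments appear at ``background + c_iv``; unperfused segments
    are indistinguishable from background.  The extravascular halo of each
    segment appears at ``background + c_ev[i]``.  The whole frame is
    translated by the cumulative injected drift, then Gaussian read noise
    and intensity-scaled shot noise are added and values clipped to the
    16-bit range.
    """
    if raster is None:
        if shape is None:
            raise ConfigError("render_frame needs a field shape or a raster cache")
        raster = _RasterCache(segments, shape, pixel_size)
    img = np.full(raster.shape, float(background))
    for mask, cev_i in zip(raster.halo_masks, c_ev):
        if cev_i > 0:
            np.maximum(img, np.where(mask, background + cev_i, 0.0), out=img)
    for mask, on in zip(raster.vessel_masks, perfused):
        level = background + c_iv if on else background
        np.maximum(img, np.where(mask, level, 0.0), out=img)
    img = _translate(img, noise.cumulative_shift(frame_index), background)
    if rng is not None:
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
        if noise.photon_scale > 0:
            sd = np.sqrt(noise.photon_scale * np.clip(img, 0.0, None))
            img = img + rng.standard_normal(img.shape) * sd
    return np.clip(np.round(img), 0, 2**16 - 1).astype(np.uint16)


# ---------------------------------------------------------------------------
# Full stack simulation
# ---------------------------------------------------------------------------


def simulate_stack(
    spec: VesselNetworkSpec,
    scenario: PerfusionScenario | None = None,
    kinetics: TracerKinetics | None = None,
    schedule: AcquisitionSchedule | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Simulate a full acquisition: one frame per schedule timestamp.

    The perfusion state of every segment is evaluated from the scenario
    timeline at every timestamp; per-segment extravascular tracer follows
    the gated one-way leak model.  ``seed`` drives the noise stream (unless
    the noise model carries its own seed); the network geometry is driven by
    ``spec.seed``.  The returned :class:`SceneTruth` records everything
    needed for recovery tests.  Fully reproducible: identical inputs give
    bit-identical stacks.
    """
    scenario = scenario or PerfusionScenario.control()
    kinetics = kinetics or TracerKinetics()
    schedule = schedule or AcquisitionSchedule.default()
    noise = noise or NoiseModel()
    kinetics.validate()
    noise.validate()

    segments, truth = build_network(spec)
    scenario.validate(len(segments))
    ts = schedule.timestamps()
    raster = _RasterCache(segments, (spec.field_height_px, spec.field_width_px), spec.pixel_size)

    perfusion = np.array(
        [[scenario.perfused(i, t) for t in ts] for i in range(len(segments))], bool
    )
    c_iv = np.asarray(plasma_concentration(ts, kinetics))
    # Tissue accumulates tracer continuously, not only at acquisition times:
    # integrate the leak on a fine grid and sample it at the frame times, so
    # an onset falling inside a long inter-frame gap is not lost.
    fine = np.union1d(ts, np.arange(ts[0], ts[-1] + 1e-9, 5.0))
    c_ev = np.array(
        [
            np.interp(
                ts,
                fine,
                extravascular_concentration(
                    fine, kinetics, [scenario.perfused(i, t) for t in fine]
                ),
            )
            for i in range(len(segments))
        ]
    )

    noise_seed = noise.seed if noise.seed is not None else seed
    rng = np.random.default_rng(noise_seed)
    frames = np.empty((ts.size, spec.field_height_px, spec.field_width_px), np.uint16)
    shifts = []
    for k, t in enumerate(ts):
        frames[k] = render_frame(
            segments,
            perfusion[:, k],
            float(c_iv[k]),
            c_ev[:, k],
            noise,
            k,
            pixel_size=spec.pixel_size,
            rng=rng,
            raster=raster,
        )
        shifts.append(noise.cumulative_shift(k))

    stack = ImageStack(frames, ts, spec.pixel_size)
    truth.timestamps_s = [float(t) for t in ts]
    truth.perfusion = [[bool(b) for b in row] for row in perfusion]
    truth.scenario = scenario.scenario
    truth.treatment_time_s = scenario.treatment_time
    truth.lock_start_s = scenario.lock_start
    truth.reperfusion_times_s = [
        None if rt is None else float(rt) for rt in scenario.reperfusion_times
    ]
    truth.kinetics = {
        "injection_time_s": kinetics.injection_time,
        "tau_s": kinetics.tau,
        "plateau": kinetics.plateau,
        "k_perm_per_s": kinetics.k_perm,
        "leakage_onset_delay_s": kinetics.leakage_onset_delay,
    }
    truth.drift_shifts = shifts
    return stack, truth


def roi_mask_from_polygon(
    polygon: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise a (row, col) polygon to a boolean mask (even-odd fill)."""
    return polygon2mask(shape, np.asarray(polygon, float))
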