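"""End-to-end orchestration: simulate -> align -> segment -> quantify -> compare.

The three pipeline commands are importable functions (the CLI in
:mod:`vasculens.cli` is a thin wrapper):

* :func:`cmd_simulate` — build a synthetic scene from a config and write
  the stack (TIFF + JSON sidecar), the ground truth and a run log;
* :func:`cmd_analyze` — align a stack, build the compartment masks (with
  optional hand-correction masks), and write compartment curves, the
  morphometry time series, the physiological readouts, QC overlays and a
  provenance report;
* :func:`cmd_compare` — group-compare analyze outputs per metric.

Every default parameter is echoed into the report together with a hash of
the effective configuration, so a run can be reproduced bit-for-bit from
its own outputs plus the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time as _time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import morphometry as morpho
from . import segmentation as seg
from . import stats as gstats
from .exceptions import ConfigError, DataError
from .registration import align_stack
from .simulate import (
    AcquisitionSchedule,
    NoiseModel,
    PerfusionScenario,
    TracerKinetics,
    VesselNetworkSpec,
    roi_mask_from_polygon,
    simulate_stack,
)
from .stack_io import (
    CompartmentMask,
    ImageStack,
    read_mask,
    read_stack,
    write_curves,
    write_mask,
    write_stack,
)

__all__ = ["cmd_simulate", "cmd_analyze", "cmd_compare", "analyze_stack", "build_components"]

log = logging.getLogger("vasculens")

DEFAULT_ANALYSIS_PARAMS = {
    "injection_time_s": 0.0,
    "treatment_time_s": 130.0,
    "filling_window_s": 120.0,  # time after injection at which vessels count as filled
    "filling_fraction_pct": 80.0,
    "lock_fraction": kin.DEFAULT_LOCK_FRACTION,
    "onset_k_sd": kin.DEFAULT_ONSET_K_SD,
    "onset_persistence": kin.DEFAULT_ONSET_PERSISTENCE,
    "segmentation_k_sd": seg.DEFAULT_K_SD,
    "opening_radius_px": seg.DEFAULT_OPENING_RADIUS_PX,
    "min_component_px": seg.DEFAULT_MIN_COMPONENT_PX,
    "baseline_policy": "pre_treatment",  # or "first_post_filling"
}


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def build_components(
    config: Mapping,
) -> tuple[VesselNetworkSpec, PerfusionScenario, TracerKinetics, AcquisitionSchedule, NoiseModel]:
    """Instantiate simulator components from a config mapping."""
    scene_cfg = dict(config.get("scene", {}))
    if "tumor_roi" in scene_cfg and scene_cfg["tumor_roi"] is not None:
        scene_cfg["tumor_roi"] = tuple(tuple(p) for p in scene_cfg["tumor_roi"])
    if "diameters_um" in scene_cfg and scene_cfg["diameters_um"] is not None:
        scene_cfg["diameters_um"] = tuple(scene_cfg["diameters_um"])
    try:
        spec = VesselNetworkSpec(**scene_cfg)
    except TypeError as exc:
        raise ConfigError(f"invalid scene config: {exc}") from exc

    scen_cfg = dict(config.get("scenario", {}))
    if "name" not in scen_cfg:
        raise ConfigError("config must name a scenario (scenario.name)")
    name = scen_cfg.pop("name")
    try:
        scenario = PerfusionScenario.named(name, spec.n_segments, **scen_cfg)
    except TypeError as exc:
        raise ConfigError(f"invalid scenario config: {exc}") from exc

    try:
        kinetics = TracerKinetics(**config.get("kinetics", {}))
        sched_cfg = dict(config.get("schedule", {}))
        if "series" in sched_cfg:
            sched_cfg["series"] = tuple(tuple(s) for s in sched_cfg["series"])
        schedule = AcquisitionSchedule(**sched_cfg)
        noise_cfg = dict(config.get("noise", {}))
        if "drift_per_frame" in noise_cfg:
            noise_cfg["drift_per_frame"] = tuple(noise_cfg["drift_per_frame"])
        noise = NoiseModel(**noise_cfg)
    except TypeError as exc:
        raise ConfigError(f"invalid config: {exc}") from exc
    return spec, scenario, kinetics, schedule, noise


def cmd_simulate(config: Mapping, seed: int, out_dir: str | Path) -> Path:
    """Simulate a scene and write stack, sidecar, ground truth and log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    spec, scenario, kinetics, schedule, noise = build_components(config)
    stack, truth = simulate_stack(spec, scenario, kinetics, schedule, noise, seed=seed)
    chash = _config_hash(config)
    stack_path = write_stack(
        stack,
        out / "stack.tif",
        extra_metadata={"seed": seed, "scenario": scenario.scenario, "config_hash": chash},
    )
    (out / "scene_truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=1), encoding="utf-8"
    )
    (out / "run.log").write_text(
        f"stage=simulate seed={seed} scenario={scenario.scenario} "
        f"config_hash={chash} frames={stack.n_frames} elapsed_s={_time.time() - t0:.2f}\n",
        encoding="utf-8",
    )
    log.info("simulated %d frames (%s) -> %s", stack.n_frames, scenario.scenario, stack_path)
    return stack_path


def analyze_stack(
    stack: ImageStack,
    roi: np.ndarray | Sequence[tuple[float, float]],
    params: Mapping | None = None,
    add_mask: np.ndarray | None = None,
    remove_mask: np.ndarray | None = None,
) -> dict:
    """Run the full analysis on an in-memory stack.

    ``roi`` is a boolean mask or a (row, col) polygon.  Returns a dict with
    the aligned stack, masks, shifts, compartment curves, morphometry
    records and the scalar readouts.
    """
    p = dict(DEFAULT_ANALYSIS_PARAMS)
    if params:
        p.update(params)
    injection = float(p["injection_time_s"])
    treatment = float(p["treatment_time_s"])

    # Register to the first frame acquired after the injection: a frame
    # taken before the tracer arrives is uniform background with nothing to
    # register on.
    post_inj = np.flatnonzero(stack.timestamps > injection)
    ref_index = int(post_inj[0]) if post_inj.size else 0
    aligned, shifts = align_stack(stack, reference_index=ref_index)

    roi_grid = (
        np.asarray(roi, bool)
        if isinstance(roi, np.ndarray)
        else roi_mask_from_polygon(roi, aligned.frame_shape)
    )
    roi_mask = CompartmentMask(roi_grid, label="tumor_roi")

    # Build the vessel mask from the pre-treatment frames: vessels are
    # tracer-filled there, while extravascular leak (which would bias a
    # global threshold) only develops after treatment.
    pre = np.flatnonzero(aligned.timestamps < treatment)
    window = (0, int(pre[-1]) + 1) if pre.size else None
    reference = seg.reference_projection(aligned, window)
    vessel = seg.segment_vessels(
        reference,
        opening_radius_px=int(p["opening_radius_px"]),
        min_component_px=int(p["min_component_px"]),
    )
    vessel = seg.apply_corrections(vessel, add_mask, remove_mask)
    extravascular = seg.extravascular_mask(vessel, roi_mask)

    records = morpho.morphometry_series(
        aligned, vessel, roi_mask, k_sd=float(p["segmentation_k_sd"])
    )
    times = aligned.timestamps

    iv_curve = kin.compartment_means(aligned, vessel, "intravascular")
    iv_norm = kin.normalize_to_imax(iv_curve)
    ev_curve = kin.compartment_means(aligned, extravascular, "extravascular")

    post_filling = injection + float(p["filling_window_s"])
    if p["baseline_policy"] == "first_post_filling" or post_filling >= treatment:
        relvar_window = (injection, treatment)
    else:
        relvar_window = (post_filling, treatment)
    ev_relvar = kin.relative_variation(ev_curve, relvar_window)

    filling = kin.filling_time(iv_norm, float(p["filling_fraction_pct"]))

    fvd = np.array([r.fvd_per_um for r in records])
    base_sel = (times >= min(post_filling, treatment - 1e-9)) & (times < treatment)
    if not base_sel.any():
        base_sel = times < treatment
    baseline_fvd = float(fvd[base_sel].mean())
    if baseline_fvd > 0:
        lock_s, censored = kin.lock_duration(records, baseline_fvd, treatment, float(p["lock_fraction"]))
    else:
        lock_s, censored = float("nan"), False

    # Noise band for onset detection over all pre-treatment frames: the
    # post-filling window can contain a single frame, too few for an SD.
    onset = kin.leakage_onset(
        times,
        ev_relvar,
        (injection, treatment),
        treatment,
        k_sd=float(p["onset_k_sd"]),
        persistence=int(p["onset_persistence"]),
    )

    return {
        "params": p,
        "aligned": aligned,
        "shifts": shifts,
        "reference": reference,
        "roi_mask": roi_mask,
        "vessel_mask": vessel,
        "extravascular_mask": extravascular,
        "records": records,
        "iv_curve": iv_norm,
        "ev_curve": ev_curve,
        "ev_relvar": ev_relvar,
        "baseline_fvd_per_um": baseline_fvd,
        "readouts": {
            "filling_time_s": filling,
            "lock_duration_s": lock_s,
            "lock_censored": censored,
            "leakage_onset_s": onset,
        },
    }


def _qc_overlay(reference: np.ndarray, vessel: CompartmentMask, roi: CompartmentMask, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(reference, cmap="gray")
    for mask, color in ((vessel.grid, "red"), (roi.grid, "cyan")):
        ys, xs = np.nonzero(find_boundaries(mask, mode="outer"))
        ax.scatter(xs, ys, s=0.05, c=color, linewidths=0)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def cmd_analyze(
    stack_path: str | Path,
    config: Mapping,
    out_dir: str | Path,
    add_mask_path: str | Path | None = None,
    remove_mask_path: str | Path | None = None,
    roi_mask_path: str | Path | None = None,
) -> Path:
    """Analyze a stack file and write curves, morphometry, report and QC."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    try:
        stack = read_stack(stack_path)
    except DataError as exc:
        raise DataError(f"[read] {exc}") from exc

    analysis_cfg = dict(config.get("analysis", {}))
    scen_cfg = config.get("scenario", {})
    if "treatment_time" in scen_cfg and "treatment_time_s" not in analysis_cfg:
        analysis_cfg["treatment_time_s"] = scen_cfg["treatment_time"]
    kin_cfg = config.get("kinetics", {})
    if "injection_time" in kin_cfg and "injection_time_s" not in analysis_cfg:
        analysis_cfg["injection_time_s"] = kin_cfg["injection_time"]

    if roi_mask_path is not None:
        roi = read_mask(roi_mask_path, label="tumor_roi").grid
    else:
        poly = config.get("analysis", {}).get("tumor_roi") or config.get("scene", {}).get("tumor_roi")
        if poly is not None:
            roi = roi_mask_from_polygon(poly, stack.frame_shape)
        else:
            spec = VesselNetworkSpec(
                field_height_px=stack.frame_shape[0], field_width_px=stack.frame_shape[1]
            )
            roi = roi_mask_from_polygon(spec.roi_polygon(), stack.frame_shape)

    add = read_mask(add_mask_path).grid if add_mask_path else None
    remove = read_mask(remove_mask_path).grid if remove_mask_path else None

    result = analyze_stack(stack, roi, analysis_cfg, add, remove)

    curves = pd.DataFrame(
        {
            "time_s": result["aligned"].timestamps,
            "intravascular_mean": result["iv_curve"].mean_intensity,
            "intravascular_pct_imax": result["iv_curve"].normalized,
            "extravascular_mean": result["ev_curve"].mean_intensity,
            "extravascular_relvar": result["ev_relvar"],
        }
    )
    write_curves(curves, out / "curves.csv")
    write_curves(morpho.records_to_frame(result["records"]), out / "morphometry.csv")
    shifts = pd.DataFrame(
        {
            "time_s": result["aligned"].timestamps,
            "shift_dy_px": [s[0] for s in result["shifts"]],
            "shift_dx_px": [s[1] for s in result["shifts"]],
        }
    )
    write_curves(shifts, out / "shifts.csv")
    write_mask(result["vessel_mask"], out / "vessel_mask.png")
    write_mask(result["roi_mask"], out / "roi_mask.png")
    _qc_overlay(result["reference"], result["vessel_mask"], result["roi_mask"], out / "overlay.png")

    chash = _config_hash(config)
    readouts = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in result["readouts"].items()
    }
    report = {
        "config_hash": chash,
        "stack": str(stack_path),
        "n_frames": stack.n_frames,
        "pixel_size_um": stack.pixel_size,
        "parameters": result["params"],
        "imax_intravascular": result["iv_curve"].imax,
        "baseline_fvd_per_um": result["baseline_fvd_per_um"],
        "readouts": readouts,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1), encoding="utf-8")
    (out / "run.log").write_text(
        f"stage=analyze stack={stack_path} config_hash={chash} "
        f"elapsed_s={_time.time() - t0:.2f}\n",
        encoding="utf-8",
    )
    return out / "report.json"


def cmd_compare(groups: Mapping[str, Sequence[str | Path]], config: Mapping, out_dir: str | Path) -> Path:
    """Group-compare analyze outputs: per-timepoint FVD/D_V plus readouts.

    ``groups`` maps a group name to the analyze output directories of its
    members.  All members must share one timebase.
    """
    if len(groups) < 2:
        raise ConfigError("compare needs at least two groups")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    morph: dict[str, list[pd.DataFrame]] = {}
    readouts: dict[str, list[dict]] = {}
    timebase = None
    for name, dirs in groups.items():
        morph[name] = []
        readouts[name] = []
        for d in dirs:
            d = Path(d)
            df = pd.read_csv(d / "morphometry.csv")
            if timebase is None:
                timebase = df["time_s"].to_numpy()
            elif not np.array_equal(timebase, df["time_s"].to_numpy()):
                raise DataError(
                    f"mismatched timebases: {d} does not share the reference time grid; "
                    "re-run analyze with a common acquisition schedule"
                )
            morph[name].append(df)
            readouts[name].append(json.loads((d / "report.json").read_text())["readouts"])

    results: dict = {"per_timepoint": {}, "readouts": {}}
    mode = config.get("stats", {}).get("mode", "per_timepoint")
    alpha = float(config.get("stats", {}).get("alpha", 0.05))
    if mode == "per_timepoint":
        for metric in ("FVD_per_um", "D_V_um"):
            per_t = []
            for i, t in enumerate(timebase):
                vals = {
                    name: [df[metric].iloc[i] for df in dfs if np.isfinite(df[metric].iloc[i])]
                    for name, dfs in morph.items()
                }
                if any(len(v) < 2 for v in vals.values()):
                    continue
                rep = gstats.group_compare(vals, alpha)
                rep["time_s"] = float(t)
                per_t.append(rep)
            results["per_timepoint"][metric] = per_t
    else:  # summary mode: one value per mouse = time-average post-treatment
        treatment = float(config.get("scenario", {}).get("treatment_time", 130.0))
        post = timebase >= treatment
        for metric in ("FVD_per_um", "D_V_um"):
            vals = {
                name: [float(np.nanmean(df[metric].to_numpy()[post])) for df in dfs]
                for name, dfs in morph.items()
            }
            results["per_timepoint"][metric] = [gstats.group_compare(vals, alpha)]

    for key in ("filling_time_s", "lock_duration_s", "leakage_onset_s"):
        vals = {
            name: [r[key] for r in reps if r.get(key) is not None]
            for name, reps in readouts.items()
        }
        if all(len(v) >= 2 for v in vals.values()):
            results["readouts"][key] = gstats.group_compare(vals, alpha)

    path = out / "stats.json"
    path.write_text(json.dumps(results, indent=1), encoding="utf-8")
    return path
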