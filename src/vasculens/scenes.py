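"""Preset study scenes: the simulated counterparts of the study arms.

Each builder returns ``(stack, truth)`` for one canonical condition:

* :func:`control_scene` — untreated tumour; every vessel perfused
  throughout, network calibrated so the true length-weighted D_V is 20 um;
* :func:`ep_lock_scene` — electric pulses only: complete vascular lock at
  treatment, staggered re-perfusion of half the vessels starting 600 s
  (10 min) later;
* :func:`ect_scene` — pulses plus bleomycin: persistent lock, no vessel
  re-perfuses within the observation window;
* :func:`ep_reperfusion_dv_scene` — an EP arm in which only the
  larger-diameter half of the vessels re-perfuses, so the true
  length-weighted diameter of the perfused subset (40 um) is twice the
  control value;
* :func:`ep_leakage_scene` — an EP arm in which half the vessels re-perfuse
  almost immediately and tracer starts extravasating 120 s (2 min) after
  treatment.

Treatment always happens at 130 s, in the 20-s pause between the two fast
acquisition series; the tracer is injected at t = 0 (acquisition start).
The builders are what the acceptance checks, the CLI presets and the
recovery tests all share.
"""

from __future__ import annotations

from .simulate import (
    NoiseModel,
    PerfusionScenario,
    SceneTruth,
    TracerKinetics,
    VesselNetworkSpec,
    simulate_stack,
)
from .stack_io import ImageStack

__all__ = [
    "TREATMENT_TIME_S",
    "control_scene",
    "ep_lock_scene",
    "ect_scene",
    "ep_reperfusion_dv_scene",
    "ep_leakage_scene",
]

TREATMENT_TIME_S = 130.0


def _default_spec(seed: int, **overrides) -> VesselNetworkSpec:
    return VesselNetworkSpec(seed=seed, **overrides)


def control_scene(seed: int = 0, noise: NoiseModel | None = None) -> tuple[ImageStack, SceneTruth]:
    spec = _default_spec(seed)
    return simulate_stack(
        spec,
        scenario=PerfusionScenario.control(TREATMENT_TIME_S),
        kinetics=TracerKinetics(),
        noise=noise,
        seed=seed,
    )


def ep_lock_scene(
    seed: int = 0,
    reperfusion_onset: float = 600.0,
    stagger: float = 60.0,
    reperfused_fraction: float = 0.5,
    noise: NoiseModel | None = None,
) -> tuple[ImageStack, SceneTruth]:
    spec = _default_spec(seed)
    scenario = PerfusionScenario.ep(
        spec.n_segments,
        treatment_time=TREATMENT_TIME_S,
        reperfusion_onset=reperfusion_onset,
        stagger=stagger,
        reperfused_fraction=reperfused_fraction,
    )
    return simulate_stack(spec, scenario=scenario, kinetics=TracerKinetics(), noise=noise, seed=seed)


def ect_scene(
    seed: int = 0,
    perfused_fraction_late: float = 0.0,
    noise: NoiseModel | None = None,
) -> tuple[ImageStack, SceneTruth]:
    spec = _default_spec(seed)
    scenario = PerfusionScenario.ect(
        spec.n_segments,
        treatment_time=TREATMENT_TIME_S,
        perfused_fraction_late=perfused_fraction_late,
    )
    return simulate_stack(spec, scenario=scenario, kinetics=TracerKinetics(), noise=noise, seed=seed)


def ep_reperfusion_dv_scene(
    seed: int = 0, noise: NoiseModel | None = None
) -> tuple[ImageStack, SceneTruth]:
    """EP arm where only the larger-diameter half of the vessels re-perfuses.

    Four 14-um and four 40-um vessels; the 40-um half re-perfuses together
    600 s after treatment, so the true perfused-subset D_V is exactly 40 um
    — twice the 20-um control value.
    """
    diameters = (14.0,) * 4 + (40.0,) * 4
    # taller field: 40-um vessels need wider row spacing to stay disjoint
    spec = VesselNetworkSpec(
        field_height_px=900,
        n_segments=8,
        diameters_um=diameters,
        calibrate_lw_diameter_um=None,
        seed=seed,
    )
    scenario = PerfusionScenario.ep(
        spec.n_segments,
        treatment_time=TREATMENT_TIME_S,
        reperfusion_onset=600.0,
        stagger=0.0,
        reperfused_fraction=0.5,
        diameters=diameters,
        select="largest",
    )
    return simulate_stack(spec, scenario=scenario, kinetics=TracerKinetics(), noise=noise, seed=seed)


def ep_leakage_scene(
    seed: int = 0,
    leakage_delay_after_treatment: float = 120.0,
    k_perm: float = 2e-4,
    noise: NoiseModel | None = None,
) -> tuple[ImageStack, SceneTruth]:
    """EP arm with rapid partial re-perfusion and delayed tracer leakage.

    Half the vessels re-perfuse 10 s after treatment; extravasation starts
    ``leakage_delay_after_treatment`` seconds after treatment and is
    confined to the re-perfused vessels' surroundings.
    """
    spec = _default_spec(seed)
    scenario = PerfusionScenario.ep(
        spec.n_segments,
        treatment_time=TREATMENT_TIME_S,
        reperfusion_onset=10.0,
        stagger=0.0,
        reperfused_fraction=0.5,
    )
    kinetics = TracerKinetics(
        k_perm=k_perm,
        leakage_onset_delay=TREATMENT_TIME_S + leakage_delay_after_treatment,
    )
    return simulate_stack(spec, scenario=scenario, kinetics=kinetics, noise=noise, seed=seed)
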