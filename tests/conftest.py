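"""Shared fixtures: simulated study scenes, analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from vasculens.pipeline import analyze_stack
from vasculens.scenes import (
    control_scene,
    ect_scene,
    ep_leakage_scene,
    ep_lock_scene,
    ep_reperfusion_dv_scene,
)
from vasculens.simulate import VesselNetworkSpec, roi_mask_from_polygon

SEED = 1


def _default_roi(shape=(420, 420)):
    spec = VesselNetworkSpec(field_height_px=shape[0], field_width_px=shape[1])
    return roi_mask_from_polygon(spec.roi_polygon(), shape)


@pytest.fixture(scope="session")
def default_roi():
    return _default_roi()


@pytest.fixture(scope="session")
def control(default_roi):
    stack, truth = control_scene(seed=SEED)
    return stack, truth, analyze_stack(stack, default_roi)


@pytest.fixture(scope="session")
def ep_lock(default_roi):
    stack, truth = ep_lock_scene(seed=SEED)
    return stack, truth, analyze_stack(stack, default_roi)


@pytest.fixture(scope="session")
def ect(default_roi):
    stack, truth = ect_scene(seed=SEED)
    return stack, truth, analyze_stack(stack, default_roi)


@pytest.fixture(scope="session")
def ep_leak(default_roi):
    stack, truth = ep_leakage_scene(seed=SEED)
    return stack, truth, analyze_stack(stack, default_roi)


@pytest.fixture(scope="session")
def ep_dv(default_roi):
    stack, truth = ep_reperfusion_dv_scene(seed=SEED)
    roi = _default_roi(stack.frame_shape)
    return stack, truth, analyze_stack(stack, roi)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
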