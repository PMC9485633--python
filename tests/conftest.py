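"""Shared fixtures: protocol parameters, schedules, phantom and dictionaries.

Dictionary builds are session-scoped because they dominate runtime; every
test that needs a fine dictionary shares the reduced-range (T1 200-2000 ms,
T2 10-300 ms, 1 ms steps) build at B1 = 1.
"""

from __future__ import annotations

import numpy as np
import pytest

from multimapping.dictionary_matching import (
    DictionaryGrid,
    build_dictionary,
    coarse_default_grid,
    fine_default_grid,
)
from multimapping.phantom import (
    PhantomDefinition,
    make_phantom,
    myocardial_roi,
    septal_roi,
    simulate_acquisition,
)
from multimapping.sequence_model import (
    PulseSequenceParams,
    TissueParams,
    multimapping_schedule,
)

MYO = TissueParams(1100.0, 50.0)
BLOOD = TissueParams(1600.0, 250.0)


@pytest.fixture(scope="session")
def params_mm() -> PulseSequenceParams:
    return PulseSequenceParams.multimapping()


@pytest.fixture(scope="session")
def params_ref() -> PulseSequenceParams:
    return PulseSequenceParams.reference()


@pytest.fixture(scope="session")
def schedule_mm(params_mm):
    return multimapping_schedule(1000.0, params=params_mm)


@pytest.fixture(scope="session")
def phantom_definition() -> PhantomDefinition:
    return PhantomDefinition()


@pytest.fixture(scope="session")
def phantom_maps(phantom_definition):
    return make_phantom(phantom_definition)


@pytest.fixture(scope="session")
def septum_mask(phantom_definition):
    return septal_roi(phantom_definition)


@pytest.fixture(scope="session")
def myocardium_mask(phantom_definition):
    return myocardial_roi(phantom_definition)


@pytest.fixture(scope="session")
def noiseless_series(phantom_maps, schedule_mm, params_mm):
    series, _ = simulate_acquisition(
        phantom_maps, "multimapping", schedule=schedule_mm, params=params_mm, noise_sd=0.0
    )
    return series


@pytest.fixture(scope="session")
def coarse_dict(params_mm, schedule_mm):
    return build_dictionary(coarse_default_grid(), params_mm, schedule_mm)


@pytest.fixture(scope="session")
def fine_grid_reduced():
    return fine_default_grid(t1_min=200.0, t1_max=2000.0)


@pytest.fixture(scope="session")
def fine_dict_b1_1(fine_grid_reduced, params_mm, schedule_mm):
    grid = DictionaryGrid(
        fine_grid_reduced.t1_values, fine_grid_reduced.t2_values, (1.0,)
    )
    return build_dictionary(grid, params_mm, schedule_mm)


# ---------------------------------------------------------------------------
# Independent naive per-TR Bloch oracle (scalar, 3-vector), kept deliberately
# separate from the package's vectorized engine.
# ---------------------------------------------------------------------------

def naive_series_oracle(params, schedule, t1, t2, b1=1.0):
    """Per-TR scalar Bloch recursion over the full schedule."""

    def relax3(m, d):
        e1, e2 = np.exp(-d / t1), np.exp(-d / t2)
        return np.array([m[0] * e2, m[1] * e2, 1.0 + (m[2] - 1.0) * e1])

    def rotx(m, th):
        c, s = np.cos(th), np.sin(th)
        return np.array([m[0], c * m[1] + s * m[2], -s * m[1] + c * m[2]])

    starts = schedule.shot_start_times_ms()
    alpha = np.deg2rad(params.flip_angle_deg) * b1
    n_su, n_rd = params.n_startup, params.n_readout_lines
    echo_idx = params.center_line_index
    m = np.array([0.0, 0.0, 1.0])
    prev_end = None
    out = []
    for b in range(schedule.n_beats):
        ev = schedule.events[b]
        t_shot = starts[b]
        if ev.kind == "inversion":
            delay = ev.delay_ms if ev.delay_ms is not None else params.inversion_delay_ms
            t_inv = t_shot - delay
            if prev_end is not None and t_inv < prev_end:
                t_inv = prev_end
            if prev_end is not None:
                m = relax3(m, max(t_inv - prev_end, 0.0))
            m = np.array([0.0, 0.0, -params.inversion_efficiency * m[2]])
            m = relax3(m, max(t_shot - t_inv, 0.0))
        elif ev.kind == "t2prep":
            te = ev.te_ms or 0.0
            if prev_end is not None:
                m = relax3(m, max(t_shot - te - prev_end, 0.0))
            m = np.array([0.0, 0.0, m[2] * np.exp(-te / t2)])
        else:
            if prev_end is not None:
                m = relax3(m, max(t_shot - prev_end, 0.0))
        sign = -1.0 if m[2] < 0 else 1.0
        m = np.array([0.0, 0.0, m[2]])
        sample = None
        for j in range(n_su + n_rd):
            th = alpha * (j + 1) / n_su if j < n_su else alpha
            if j % 2 == 1:
                th = -th
            m = rotx(m, th)
            m = relax3(m, params.tr_ms / 2.0)
            if j == echo_idx:
                sample = sign * np.hypot(m[0], m[1])
            m = relax3(m, params.tr_ms / 2.0)
        m = np.array([0.0, 0.0, m[2]])
        if schedule.acquire[b]:
            out.append(sample)
        prev_end = t_shot + params.shot_duration_ms
    return np.array(out)
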