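"""Shared fixtures: small synthetic sessions and a session-scoped cohort run."""

import warnings

import numpy as np
import pytest

from cogload import pipeline, synthgen

COHORT_SEED = 20240901


def short_plan(session_type):
    """Desk-scale session plan with enough load time for several windows."""
    if session_type == "HL":
        load = [("load_task:reading_span", 180.0),
                ("load_task:stroop", 150.0),
                ("load_task:nback", 180.0)]
    else:
        load = [("load_task:game", 360.0)]
    return ([("baseline", 60.0), ("voice", 30.0), ("eyes_closed", 15.0),
             ("questionnaire", 30.0)]
            + load
            + [("questionnaire", 30.0), ("eating", 60.0),
               ("questionnaire", 30.0)])


@pytest.fixture
def clean_session_spec():
    """Noise-free, burst-free HL session for exact recovery checks."""
    return synthgen.SessionSpec(
        subject_id="S01", session_type="HL",
        segment_plan=[("baseline", 60.0), ("load_task:stroop", 150.0)],
        hr_base=60.0, hr_load_delta=0.0, hr_jitter=0.0,
        scr_rate_base=2.0, scr_rate_load=2.0, motion_burst_rate=0.0,
        noise_sd={"ppg": 0.0, "gsr": 0.0, "accel": 0.0, "temp": 0.0},
        seed=7)


@pytest.fixture
def default_session():
    spec = synthgen.SessionSpec(
        subject_id="S01", session_type="HL",
        segment_plan=short_plan("HL"), seed=11)
    frame, truth = synthgen.generate_recording(spec)
    return spec, frame, truth


@pytest.fixture(scope="session")
def cohort_run():
    """12-subject end-to-end run with the stated HL effects (computed once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_end_to_end(
            n_subjects=12, seed=COHORT_SEED, segment_plan=short_plan,
            hr_load_delta=12.0, scr_rate_load=12.0, scr_rate_base=4.0,
            rf_estimators=50)


@pytest.fixture(scope="session")
def cohort_table(cohort_run):
    return cohort_run["table"]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
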