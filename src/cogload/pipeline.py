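"""End-to-end composition: raw session -> windows -> features -> evaluation.

These helpers wire the stage modules together for the CLI, the tests, and
cohort-level experiments on synthetic data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import features as feat
from . import ingest, modelsel, preprocess, synthgen

log = logging.getLogger(__name__)

PPG_BAND = (0.5, 8.0)
ACCEL_BAND = (0.5, 6.0)


def preprocess_recording(rec: ingest.RawRecording, decompose=True,
                         eda_kwargs=None):
    """Filter channels, detect beats, and decompose the conductance.

    Returns ``(derived, beats)`` where ``derived`` maps channel names
    (``ppg_filt``, ``accel_mag``, ``tonic``, ``phasic``, ``smna``) to
    full-length arrays on the sensor clock.
    """
    fs = rec.fs
    ppg_filt = preprocess.bandpass(rec.channels["ppg"], *PPG_BAND, fs=fs)
    accel_mag = preprocess.filtered_accel_magnitude(
        rec.channels["accel_x"], rec.channels["accel_y"],
        rec.channels["accel_z"], fs=fs, low=ACCEL_BAND[0], high=ACCEL_BAND[1])
    beats = preprocess.detect_beats(ppg_filt, fs=fs)
    derived = {"ppg_filt": ppg_filt, "accel_mag": accel_mag}
    if decompose:
        eda = preprocess.decompose_eda(rec.channels["gsr"], fs=fs,
                                       **(eda_kwargs or {}))
        derived.update(tonic=eda.tonic, phasic=eda.phasic, smna=eda.smna)
    return derived, beats


def session_windows(rec: ingest.RawRecording, events: ingest.EventTrack,
                    sync=True, eda_kwargs=None):
    """Synchronise, preprocess, segment, window, and flag one session."""
    if sync:
        ingest.detect_sync_taps(rec)
    derived, beats = preprocess_recording(rec, eda_kwargs=eda_kwargs)
    slices = ingest.segment(rec, events, extra_channels={
        "ppg": derived["ppg_filt"],        # windows consume the filtered pulse
        "accel_mag": derived["accel_mag"],
        "tonic": derived["tonic"], "phasic": derived["phasic"],
        "smna": derived["smna"],
    })
    for sl in slices:
        sl.subject_id = rec.subject_id
        sl.session_type = rec.session_type
        # beat series re-expressed on the slice-local clock
        t0 = rec.t0_offset + sl.start_s
        sl.beats = beats.shifted(t0).slice(0.0, sl.duration_s)
    windows = feat.make_windows(slices)
    for w in windows:
        feat.flag_artefacts(w)
    return windows


def session_features(rec, events, **kwargs):
    windows = session_windows(rec, events, **kwargs)
    return feat.build_feature_table(windows)


def recording_from_frame(frame, subject_id, session_type, fs=preprocess.DEFAULT_FS):
    """RawRecording from an in-memory signals table (no CSV round trip)."""
    return ingest.RawRecording(
        subject_id=subject_id, session_type=session_type, fs=fs,
        channels={
            "ppg": frame["ppg"].to_numpy(float),
            "gsr": np.clip(frame["gsr_uS"].to_numpy(float), 0.0, None),
            "accel_x": frame["accel_x"].to_numpy(float),
            "accel_y": frame["accel_y"].to_numpy(float),
            "accel_z": frame["accel_z"].to_numpy(float),
            "temp": frame["temp_C"].to_numpy(float),
        })


def cohort_feature_table(specs, eda_kwargs=None):
    """Generate and featurise every session of a synthetic cohort."""
    tables = []
    for spec in specs:
        frame, _ = synthgen.generate_recording(spec)
        rec = recording_from_frame(frame, spec.subject_id, spec.session_type,
                                   fs=spec.fs)
        events = ingest.EventTrack.from_frame(synthgen.events_frame(spec))
        t = session_features(rec, events, eda_kwargs=eda_kwargs)
        if t.empty:
            log.warning("session %s/%s produced no clean windows",
                        spec.subject_id, spec.session_type)
            continue
        tables.append(t)
    if not tables:
        raise RuntimeError("no session produced clean windows")
    table = pd.concat(tables, ignore_index=True)
    log.info("cohort feature table: %d windows x %d features",
             len(table), len(feat.FEATURE_NAMES))
    return table


def run_end_to_end(n_subjects=12, seed=0, duration_scale=0.1,
                   hr_load_delta=12.0, scr_rate_load=12.0, scr_rate_base=4.0,
                   model_family="svm", segment_plan=None,
                   selection_folds=12, rf_estimators=100, eda_kwargs=None,
                   permute_labels=False):
    """Synthetic cohort -> features -> selection -> nested LOSO summary.

    Selection runs once on the full table before the outer loop (the
    published, reproduction-mode order).  ``permute_labels`` shuffles the
    window labels before selection and evaluation, as a chance-level control.
    Returns a dict with the feature table, selection, evaluations, summary.
    """
    specs = synthgen.make_cohort_specs(
        n_subjects=n_subjects, seed=seed, duration_scale=duration_scale,
        hr_load_delta=hr_load_delta, scr_rate_load=scr_rate_load,
        scr_rate_base=scr_rate_base, segment_plan=segment_plan)
    table = cohort_feature_table(specs, eda_kwargs=eda_kwargs)
    if permute_labels:
        rng = np.random.default_rng(seed + 1)
        table = table.copy()
        table["load_class"] = rng.permutation(table["load_class"].to_numpy())
    selection = modelsel.select_features(
        table, folds=selection_folds, seed=seed, n_estimators=rf_estimators)
    evals, provenance = modelsel.nested_loso(
        table, selection.selected, model_family=model_family, seed=seed,
        reproduction_mode=True)
    return {
        "table": table,
        "selection": selection,
        "evaluations": evals,
        "provenance": provenance,
        "summary": modelsel.summarise(evals),
    }
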