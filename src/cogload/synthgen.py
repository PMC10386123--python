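"""Synthetic subject-session generator.

Produces multichannel wearable recordings (PPG, skin conductance, 3-axis
accelerometer, skin temperature at 51.2 Hz), task-segment label tracks,
questionnaire responses, and food-weight tables with configurable
high-load/low-load effect sizes, plus a ground-truth record of every latent
event so downstream stages can be tested without real data.

Conventions
-----------
* The *sensor clock* starts at 0 when the recording starts.  Three hand-tap
  accelerometer spikes occur in the first 10 s; the label clock (task
  timestamps) starts at the last tap.
* ``GroundTruth`` times are on the sensor clock; segment intervals are also
  provided on the label clock for writing ``events.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DEFAULT_FS, scr_kernel

HL_TASKS = ("reading_span", "stroop", "nback")
LL_TASKS = ("game",)

#: snack item -> (offered amount in g or mL, kcal per g/mL, sugar g per g/mL)
FOOD_ITEMS = {
    "chocolate": (54.0, 4.49, 0.60),
    "chips": (55.0, 5.36, 0.03),
    "pretzels": (75.0, 3.80, 0.02),
    "nuts": (55.0, 6.07, 0.05),
    "grapes": (77.5, 0.69, 0.16),
    "carrot": (77.5, 0.41, 0.05),
    "cucumber": (77.5, 0.15, 0.02),
    "orange_juice": (500.0, 0.45, 0.09),
    "water": (500.0, 0.0, 0.0),
}


class MalformedSpec(ValueError):
    """Session specification violates its invariants."""


def default_segment_plan(session_type, duration_scale=1.0):
    """Task sequence of one recording session, scaled by ``duration_scale``.

    Baseline video, voice prompts, eyes-closed rest, a questionnaire block,
    the load tasks (three high-load tasks or one casual game), a second
    questionnaire block, the eating break, and a closing questionnaire.
    """
    if session_type == "HL":
        load = [("load_task:reading_span", 510.0),
                ("load_task:stroop", 390.0),
                ("load_task:nback", 600.0)]
    elif session_type == "LL":
        load = [("load_task:game", 1500.0)]
    else:
        raise MalformedSpec(f"unknown session type {session_type!r}")
    plan = (
        [("baseline", 600.0), ("voice", 180.0), ("eyes_closed", 60.0),
         ("questionnaire", 120.0)]
        + load
        + [("questionnaire", 120.0), ("eating", 1200.0),
           ("eyes_closed", 60.0), ("questionnaire", 120.0)]
    )
    return [(name, dur * duration_scale) for name, dur in plan]


@dataclass
class SessionSpec:
    """Parameters of one synthetic subject-session."""

    subject_id: str
    session_type: str                       # "HL" | "LL"
    segment_plan: list = None               # [(name, duration_s), ...]
    fs: float = DEFAULT_FS
    hr_base: float = 70.0
    hr_load_delta: float = 12.0             # added inside load segments
    hr_jitter: float = 0.02                 # fractional beat-interval jitter
    scr_rate_base: float = 4.0              # events/min outside load
    scr_rate_load: float = 12.0             # events/min inside load
    tonic_level: float = 2.0                # uS
    tonic_drift: float = 0.05               # uS/min
    motion_burst_rate: float = 4.0          # bursts/hour
    noise_sd: dict = field(default_factory=lambda: {
        "ppg": 0.02, "gsr": 0.005, "accel": 0.05, "temp": 0.01})
    sync_lead_s: float = 8.0                # pre-label sensor time holding taps
    tap_times_s: tuple = (2.0, 2.5, 3.0)    # sensor clock
    seed: int = 0

    def __post_init__(self):
        if self.segment_plan is None:
            self.segment_plan = default_segment_plan(self.session_type)
        self.validate()

    def validate(self):
        if self.session_type not in ("HL", "LL"):
            raise MalformedSpec(f"session_type must be HL or LL")
        if not self.segment_plan:
            raise MalformedSpec("empty segment plan")
        for name, dur in self.segment_plan:
            if dur <= 0:
                raise MalformedSpec(f"non-positive duration for segment {name!r}")
        if self.fs <= 0:
            raise MalformedSpec("non-positive sampling rate")
        if self.scr_rate_base < 0 or self.scr_rate_load < 0:
            raise MalformedSpec("negative SCR rate")
        if not (35.0 <= self.hr_base + self.hr_load_delta <= 180.0):
            raise MalformedSpec("hr_base + hr_load_delta outside [35, 180] bpm")
        if not (35.0 <= self.hr_base <= 180.0):
            raise MalformedSpec("hr_base outside [35, 180] bpm")
        if max(self.tap_times_s) >= 10.0 or min(self.tap_times_s) <= 0.0:
            raise MalformedSpec("sync taps must lie inside the first 10 s")
        if max(self.tap_times_s) >= self.sync_lead_s:
            raise MalformedSpec("sync taps must precede the label start")

    @property
    def duration_s(self):
        """Total sensor-clock duration."""
        return self.sync_lead_s + sum(d for _, d in self.segment_plan)

    def label_segments(self):
        """(name, start, end) on the label clock."""
        out, t = [], 0.0
        for name, dur in self.segment_plan:
            out.append((name, t, t + dur))
            t += dur
        return out


@dataclass
class GroundTruth:
    """Latent events of one generated recording (sensor clock, seconds)."""

    beat_times: np.ndarray
    scr_onsets: np.ndarray
    artefact_intervals: list            # [(start, end), ...]
    segment_intervals: list             # [(name, start, end)] sensor clock
    tap_times: list
    label_start_s: float

    def to_json(self, path):
        d = {
            "beat_times": list(map(float, self.beat_times)),
            "scr_onsets": list(map(float, self.scr_onsets)),
            "artefact_intervals": [list(map(float, ab)) for ab in self.artefact_intervals],
            "segment_intervals": [[n, float(a), float(b)] for n, a, b in self.segment_intervals],
            "tap_times": list(map(float, self.tap_times)),
            "label_start_s": float(self.label_start_s),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(
            beat_times=np.asarray(d["beat_times"]),
            scr_onsets=np.asarray(d["scr_onsets"]),
            artefact_intervals=[tuple(ab) for ab in d["artefact_intervals"]],
            segment_intervals=[(n, a, b) for n, a, b in d["segment_intervals"]],
            tap_times=d["tap_times"],
            label_start_s=d["label_start_s"],
        )


def _is_load(name):
    return name.startswith("load_task")


def _gaussian_bumps(t_grid, centers, amps, width):
    """Sum of Gaussians added onto a sample grid (local windows only)."""
    out = np.zeros_like(t_grid)
    fs = 1.0 / (t_grid[1] - t_grid[0]) if len(t_grid) > 1 else 1.0
    half = int(np.ceil(4 * width * fs))
    for c, a in zip(centers, np.broadcast_to(amps, (len(centers),))):
        i = int(round(c * fs))
        lo, hi = max(0, i - half), min(len(t_grid), i + half + 1)
        if lo >= hi:
            continue
        out[lo:hi] += a * np.exp(-0.5 * ((t_grid[lo:hi] - c) / width) ** 2)
    return out


def generate_recording(spec: SessionSpec):
    """Generate one recording and its ground truth.

    Returns ``(frame, truth)`` where ``frame`` is a DataFrame with columns
    ``time_s, ppg, gsr_uS, accel_x, accel_y, accel_z, temp_C`` on the sensor
    clock, and ``truth`` is a :class:`GroundTruth`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    lead = spec.sync_lead_s

    sensor_segments = [(name, a + lead, b + lead) for name, a, b in spec.label_segments()]
    load_spans = [(a, b) for name, a, b in sensor_segments if _is_load(name)]

    def in_load(x):
        return any(a <= x < b for a, b in load_spans)

    # --- heart rate profile and beat times ------------------------------
    hr_t = np.full(n, spec.hr_base, dtype=float)
    for a, b in load_spans:
        hr_t[int(a * fs):int(b * fs)] += spec.hr_load_delta
    # smooth the steps (~5 s ramp)
    k = int(5 * fs)
    if k > 1:
        kernel = np.ones(k) / k
        hr_t = np.convolve(hr_t, kernel, mode="same")
        hr_t[:k] = hr_t[k]
        hr_t[-k:] = hr_t[-k - 1]

    beats = []
    tb = float(rng.uniform(0.2, 0.8))
    while tb < spec.duration_s - 1.0:
        beats.append(tb)
        hr_here = hr_t[min(int(tb * fs), n - 1)]
        step = 60.0 / hr_here
        if spec.hr_jitter > 0:
            step *= max(0.5, 1.0 + rng.normal(0.0, spec.hr_jitter))
        tb += step
    beat_times = np.asarray(beats)

    # PPG: systolic Gaussian at the beat time plus a smaller dicrotic bump
    # 0.3 s later (close enough to be suppressed by the peak detector's
    # minimum-separation rule).
    ppg = _gaussian_bumps(t, beat_times, 1.0, 0.06)
    ppg += _gaussian_bumps(t, beat_times + 0.30, 0.30, 0.09)
    if spec.noise_sd.get("ppg", 0) > 0:
        ppg += rng.normal(0, spec.noise_sd["ppg"], n)

    # --- skin conductance -----------------------------------------------
    tonic = spec.tonic_level + spec.tonic_drift * t / 60.0
    onsets = []
    seg_rates = [(0.0, lead, spec.scr_rate_base)] + [
        (a, b, spec.scr_rate_load if _is_load(name) else spec.scr_rate_base)
        for name, a, b in sensor_segments
    ]
    for a, b, rate in seg_rates:
        if rate <= 0:
            continue
        x = a + float(rng.exponential(60.0 / rate))
        while x < b:
            onsets.append(x)
            x += float(rng.exponential(60.0 / rate))
    onsets = np.asarray(sorted(onsets))
    driver = np.zeros(n)
    for o in onsets:
        i = int(round(o * fs))
        if i < n:
            driver[i] += rng.gamma(2.0, 0.15)
    kern = scr_kernel(fs)
    phasic = np.convolve(driver, kern)[:n]
    gsr = tonic + phasic
    if spec.noise_sd.get("gsr", 0) > 0:
        gsr = gsr + rng.normal(0, spec.noise_sd["gsr"], n)
    np.clip(gsr, 0.0, None, out=gsr)

    # --- accelerometer ---------------------------------------------------
    sd_a = spec.noise_sd.get("accel", 0)
    acc = rng.normal(0, sd_a, (3, n)) if sd_a > 0 else np.zeros((3, n))
    acc[2] += 9.81  # gravity; removed by band-pass filtering

    for tap in spec.tap_times_s:
        # Gaussian-windowed oscillation centred on the nominal tap time so the
        # filtered-magnitude peak coincides with the ground-truth timestamp
        i0, i1 = int((tap - 0.3) * fs), int((tap + 0.3) * fs)
        tt = t[i0:i1] - tap
        burst = np.exp(-0.5 * (tt / 0.08) ** 2) * np.cos(2 * np.pi * 4.0 * tt)
        acc[0, i0:i1] += 35.0 * burst
        acc[1, i0:i1] += 20.0 * burst

    artefacts = []
    total = spec.duration_s
    n_bursts = rng.poisson(spec.motion_burst_rate * (total / 3600.0))
    for _ in range(n_bursts):
        start = float(rng.uniform(lead + 5.0, max(lead + 6.0, total - 30.0)))
        dur = float(rng.uniform(15.0, 30.0))
        end = min(start + dur, total)
        artefacts.append((start, end))
        i0, i1 = int(start * fs), int(end * fs)
        osc = np.sin(2 * np.pi * 2.5 * (t[i0:i1] - start))
        amp = rng.uniform(5.0, 8.0)
        for ax in range(3):
            acc[ax, i0:i1] += amp * osc * rng.uniform(0.5, 1.0)
        # motion corrupts the optical and conductance channels too
        ppg[i0:i1] += 0.6 * osc * rng.normal(1.0, 0.3, i1 - i0)
        gsr[i0:i1] += 0.05 * np.abs(osc)

    # --- temperature ------------------------------------------------------
    temp = 33.0 + 0.4 * np.sin(2 * np.pi * t / 1800.0)
    if spec.noise_sd.get("temp", 0) > 0:
        temp = temp + rng.normal(0, spec.noise_sd["temp"], n)

    frame = pd.DataFrame({
        "time_s": t, "ppg": ppg, "gsr_uS": gsr,
        "accel_x": acc[0], "accel_y": acc[1], "accel_z": acc[2],
        "temp_C": temp,
    })
    truth = GroundTruth(
        beat_times=beat_times,
        scr_onsets=onsets,
        artefact_intervals=sorted(artefacts),
        segment_intervals=sensor_segments,
        tap_times=list(spec.tap_times_s),
        label_start_s=max(spec.tap_times_s),
    )
    return frame, truth


def events_frame(spec: SessionSpec):
    """Label-clock ``events.csv`` table for one session."""
    rows = []
    for name, a, b in spec.label_segments():
        if _is_load(name):
            task = name.split(":", 1)[1]
            load_class = "HL" if task in HL_TASKS else "LL"
        else:
            load_class = "none"
        rows.append({"segment": name, "start_s": a, "end_s": b,
                     "load_class": load_class})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

PANAS_TIMEPOINTS = ("before_load", "after_load", "after_eating")


def generate_questionnaires(spec: SessionSpec, affect_effect=0.0,
                            workload_effect=0.0, seed=None):
    """PANAS item responses (three timepoints) and per-task workload subscales.

    Negative-affect items are shifted upward by ``affect_effect`` (summed over
    the 10 items) after the load block of an HL session; workload subscales of
    HL tasks are shifted by ``workload_effect``.
    Returns ``(panas, tlx)`` DataFrames.
    """
    if not (np.isfinite(affect_effect) and np.isfinite(workload_effect)):
        raise ValueError("effects must be finite")
    rng = np.random.default_rng(spec.seed + 1000003 if seed is None else seed)
    panas_rows = []
    for tp in PANAS_TIMEPOINTS:
        row = {"subject_id": spec.subject_id, "session_type": spec.session_type,
               "timepoint": tp}
        shift = affect_effect / 10.0 if (
            tp == "after_load" and spec.session_type == "HL") else 0.0
        for i in range(1, 11):
            row[f"pa_{i:02d}"] = int(np.clip(round(3.0 + rng.normal(0, 0.8)), 1, 5))
        for i in range(1, 11):
            base = 1.0 + rng.exponential(0.4)
            row[f"na_{i:02d}"] = int(np.clip(round(base + shift), 1, 5))
        panas_rows.append(row)
    panas = pd.DataFrame(panas_rows)

    tasks = HL_TASKS if spec.session_type == "HL" else LL_TASKS
    subscales = ("mental", "physical", "temporal", "performance", "effort",
                 "frustration")
    tlx_rows = []
    for task in tasks:
        row = {"subject_id": spec.subject_id, "session_type": spec.session_type,
               "task": task}
        shift = workload_effect if spec.session_type == "HL" else 0.0
        for s in subscales:
            row[s] = float(np.clip(40.0 + shift + rng.normal(0, 12.0), 0.0, 100.0))
        tlx_rows.append(row)
    return panas, pd.DataFrame(tlx_rows)


# ---------------------------------------------------------------------------
# Food weights
# ---------------------------------------------------------------------------

def generate_food_table(n_subjects, item_effects=None, seed=0,
                        subject_ids=None):
    """Per-subject, per-session food weights before/after eating.

    Consumed amounts are truncated-normal draws inside ``[0, offered]``; the
    HL-session mean of each item is multiplied by ``item_effects[item]``.
    """
    item_effects = dict(item_effects or {})
    for item, mult in item_effects.items():
        if mult <= 0:
            raise ValueError(f"multiplier for {item!r} must be positive")
        if item not in FOOD_ITEMS:
            raise KeyError(f"unknown food item {item!r}")
    rng = np.random.default_rng(seed)
    if subject_ids is None:
        subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    rows = []
    for sid in subject_ids:
        prefs = {item: rng.uniform(0.2, 0.6) for item in FOOD_ITEMS}
        for session in ("HL", "LL"):
            for item, (offered, _, _) in FOOD_ITEMS.items():
                mean = prefs[item] * offered
                if session == "HL":
                    mean = min(mean * item_effects.get(item, 1.0), 0.95 * offered)
                sd = 0.25 * offered
                a, b = (0.0 - mean) / sd, (offered - mean) / sd
                consumed = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                                     random_state=rng))
                rows.append({
                    "subject_id": sid, "session_type": session, "item": item,
                    "weight_before_g": offered,
                    "weight_after_g": offered - consumed,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohorts and file output
# ---------------------------------------------------------------------------

def make_cohort_specs(n_subjects=12, seed=0, duration_scale=0.1,
                      hr_load_delta=12.0, scr_rate_load=12.0,
                      scr_rate_base=4.0, segment_plan=None,
                      motion_burst_rate=4.0):
    """Session specs for a cohort: one HL and one LL session per subject.

    The load effects apply to HL sessions only; LL sessions keep the base
    rates so the two classes differ as configured.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        hr_base = float(np.clip(rng.normal(70.0, 5.0), 55.0, 90.0))
        for session in ("HL", "LL"):
            plan = (segment_plan(session) if callable(segment_plan)
                    else default_segment_plan(session, duration_scale))
            specs.append(SessionSpec(
                subject_id=sid,
                session_type=session,
                segment_plan=plan,
                hr_base=hr_base,
                hr_load_delta=hr_load_delta if session == "HL" else 0.0,
                scr_rate_base=scr_rate_base,
                scr_rate_load=scr_rate_load if session == "HL" else scr_rate_base,
                motion_burst_rate=motion_burst_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
    return specs


def write_session(spec: SessionSpec, out_dir, affect_effect=6.0,
                  workload_effect=20.0):
    """Write signals.csv, events.csv, panas.csv, nasatlx.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame, truth = generate_recording(spec)
    frame.to_csv(out / "signals.csv", index=False, float_format="%.6f")
    events_frame(spec).to_csv(out / "events.csv", index=False)
    panas, tlx = generate_questionnaires(spec, affect_effect, workload_effect)
    panas.to_csv(out / "panas.csv", index=False)
    tlx.to_csv(out / "nasatlx.csv", index=False)
    truth.to_json(out / "truth.json")
    return frame, truth
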