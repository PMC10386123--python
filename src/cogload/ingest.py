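"""Reading sensor/label CSVs, tap-based clock synchronisation, segmentation.

The sensor clock is aligned to the label clock by locating the hand-tap
accelerometer signature: label time 0 corresponds to the (by default, last)
of the three largest filtered-magnitude peaks near the start of the
recording.  The label clock is authoritative; the sensor stream is shifted,
never resampled.  Intervals are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import preprocess
from .preprocess import DEFAULT_FS

log = logging.getLogger(__name__)

SIGNAL_COLUMNS = ("time_s", "ppg", "gsr_uS", "accel_x", "accel_y", "accel_z",
                  "temp_C")
CHANNELS = ("ppg", "gsr", "accel_x", "accel_y", "accel_z", "temp")

HL_TASK_NAMES = {"reading_span", "stroop", "nback"}
LL_TASK_NAMES = {"game", "bejeweled"}


class FormatError(ValueError):
    """Input file does not match the expected CSV dialect."""


class ConfigError(ValueError):
    """File metadata contradicts the configuration."""


class SyncError(RuntimeError):
    """The recording cannot be synchronised to the label clock."""


class ValidationError(ValueError):
    """Event or signal content violates an invariant."""


@dataclass
class RawRecording:
    """Synchronised multichannel streams of one subject-session."""

    subject_id: str
    session_type: str
    fs: float
    channels: dict                 # name -> np.ndarray, equal lengths
    t0_offset: float = 0.0        # sensor-clock time of label time 0
    repairs: list = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError("channels have unequal lengths")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    @property
    def n_samples(self):
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self):
        return self.n_samples / self.fs

    def label_to_index(self, t_label):
        """Sample index of a label-clock time."""
        return int(round((t_label + self.t0_offset) * self.fs))


@dataclass
class EventTrack:
    """Ordered, non-overlapping labelled intervals on the label clock."""

    intervals: list                # [(name, start_s, end_s, load_class), ...]

    def __post_init__(self):
        prev_end = -np.inf
        for name, start, end, load_class in self.intervals:
            if start >= end:
                raise ValidationError(f"interval {name!r}: start >= end")
            if start < prev_end:
                raise ValidationError(f"interval {name!r} overlaps its predecessor")
            if load_class not in ("HL", "LL", "none"):
                raise ValidationError(f"bad load_class {load_class!r}")
            prev_end = end

    def __len__(self):
        return len(self.intervals)

    @classmethod
    def from_frame(cls, frame):
        required = {"segment", "start_s", "end_s"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"events file missing column(s) {sorted(missing)}")
        rows = []
        for _, r in frame.sort_values("start_s").iterrows():
            name = str(r["segment"])
            if "load_class" in frame.columns and not pd.isna(r["load_class"]):
                load_class = str(r["load_class"])
            else:
                load_class = infer_load_class(name)
            rows.append((name, float(r["start_s"]), float(r["end_s"]), load_class))
        return cls(rows)

    @classmethod
    def from_csv(cls, path):
        return cls.from_frame(pd.read_csv(path))


def infer_load_class(segment_name):
    """HL for the three load tasks, LL for the game, ``none`` otherwise."""
    if segment_name.startswith("load_task"):
        task = segment_name.split(":", 1)[-1].strip().lower()
        if task in HL_TASK_NAMES:
            return "HL"
        if task in LL_TASK_NAMES:
            return "LL"
    return "none"


# ---------------------------------------------------------------------------
# Signal IO
# ---------------------------------------------------------------------------

_COLUMN_TO_CHANNEL = {"ppg": "ppg", "gsr_uS": "gsr", "accel_x": "accel_x",
                      "accel_y": "accel_y", "accel_z": "accel_z",
                      "temp_C": "temp"}


def _repair_channel(x, fs, max_gap_s=0.5, name=""):
    """Interpolate non-finite runs shorter than ``max_gap_s``; flag longer ones."""
    x = np.array(x, dtype=float)
    bad = ~np.isfinite(x)
    repairs, flagged = [], []
    if not bad.any():
        return x, repairs, flagged
    idx = np.arange(len(x))
    # group runs of bad samples
    starts = np.flatnonzero(bad & ~np.r_[False, bad[:-1]])
    ends = np.flatnonzero(bad & ~np.r_[bad[1:], False])
    interp_ok = np.copy(bad)
    for s, e in zip(starts, ends):
        run = e - s + 1
        if run / fs < max_gap_s:
            repairs.append((name, s, e))
        else:
            flagged.append((name, s, e))
            interp_ok[s:e + 1] = False  # leave long runs as NaN
    if repairs:
        good = np.isfinite(x)
        x[interp_ok] = np.interp(idx[interp_ok], idx[good], x[good])
    return x, repairs, flagged


def read_signals(path, subject_id="unknown", session_type="HL", fs=DEFAULT_FS,
                 fs_tolerance=0.01):
    """Read and validate a ``signals.csv`` into a :class:`RawRecording`.

    Non-finite runs shorter than 0.5 s are repaired by linear interpolation
    (logged on ``rec.repairs``); longer runs are left for the window-level
    artefact rejection and flagged.
    """
    frame = pd.read_csv(path)
    missing = set(SIGNAL_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"signals file missing column(s) {sorted(missing)}")
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        fs_file = 1.0 / np.median(np.diff(t))
        if abs(fs_file - fs) / fs > fs_tolerance:
            raise ConfigError(
                f"file sampling rate {fs_file:.3f} Hz != configured {fs} Hz")
    channels, repairs = {}, []
    for col, ch in _COLUMN_TO_CHANNEL.items():
        x, reps, flagged = _repair_channel(
            frame[col].to_numpy(dtype=float), fs, name=ch)
        repairs.extend(reps)
        for item in flagged:
            warnings.warn(f"long non-finite run in channel {item[0]}; "
                          "left for window-level rejection")
        channels[ch] = x
    # conductance is physically nonnegative; tiny negative noise is clipped
    neg = channels["gsr"] < 0
    if neg.any():
        if np.nanmin(channels["gsr"]) < -0.5:
            raise ValidationError("gsr_uS has strongly negative values")
        channels["gsr"] = np.clip(channels["gsr"], 0.0, None)
        log.info("clipped %d slightly negative gsr samples", int(neg.sum()))
    rec = RawRecording(subject_id=subject_id, session_type=session_type,
                       fs=fs, channels=channels)
    rec.repairs = repairs
    return rec


def write_signals(rec: RawRecording, path, float_format="%.6f"):
    """Inverse of :func:`read_signals` (up to float formatting)."""
    t = np.arange(rec.n_samples) / rec.fs
    frame = pd.DataFrame({
        "time_s": t,
        "ppg": rec.channels["ppg"],
        "gsr_uS": rec.channels["gsr"],
        "accel_x": rec.channels["accel_x"],
        "accel_y": rec.channels["accel_y"],
        "accel_z": rec.channels["accel_z"],
        "temp_C": rec.channels["temp"],
    })
    frame.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Synchronisation
# ---------------------------------------------------------------------------

def detect_sync_taps(rec: RawRecording, search_window_s=60.0, align="last",
                     min_magnitude=2.0, n_taps=3, min_separation_s=0.3):
    """Locate the hand-tap spikes and set ``rec.t0_offset``.

    The three largest peaks of the band-passed accelerometer magnitude within
    the search window, above ``max(min_magnitude, 5 x median magnitude)``, are
    taken as the taps.  Label time 0 is aligned to the last (or first) tap.
    """
    if rec.duration_s < 15.0:
        raise SyncError("recording shorter than 15 s cannot be synchronised")
    if align not in ("first", "last"):
        raise ValueError("align must be 'first' or 'last'")
    n = min(rec.n_samples, int(search_window_s * rec.fs))
    mag = preprocess.filtered_accel_magnitude(
        rec.channels["accel_x"][:n], rec.channels["accel_y"][:n],
        rec.channels["accel_z"][:n], fs=rec.fs)
    # 5x median adapts to baseline noise; the cap keeps the strongest events
    # (the taps) detectable when the window also contains sustained motion
    threshold = min(max(min_magnitude, 5.0 * float(np.median(mag))),
                    0.5 * float(np.max(mag)))
    peaks, props = sp_signal.find_peaks(
        mag, height=threshold, distance=max(1, int(min_separation_s * rec.fs)))
    if len(peaks) < n_taps:
        raise SyncError(
            f"found {len(peaks)} peak(s) above {threshold:.2f} m/s^2; "
            f"need {n_taps} taps")
    order = np.argsort(props["peak_heights"])[::-1][:n_taps]
    tap_indices = np.sort(peaks[order])
    tap_times = tap_indices / rec.fs
    tap_time = float(tap_times[-1] if align == "last" else tap_times[0])
    rec.t0_offset = tap_time
    return tap_time


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class Slice:
    """One labelled interval of a synchronised recording."""

    name: str
    load_class: str
    start_s: float                 # label clock
    end_s: float
    channels: dict                 # channel -> samples
    fs: float

    @property
    def duration_s(self):
        return len(next(iter(self.channels.values()))) / self.fs


def segment(rec: RawRecording, events: EventTrack, extra_channels=None):
    """Cut the synchronised recording into labelled slices.

    ``extra_channels`` maps names to full-length derived series (e.g. tonic,
    phasic, smna, accel_mag) that are sliced alongside the raw channels.
    Intervals extending beyond the recording are truncated with a warning.
    """
    out = []
    sources = dict(rec.channels)
    if extra_channels:
        for name, x in extra_channels.items():
            if len(x) != rec.n_samples:
                raise ValidationError(f"extra channel {name!r} length mismatch")
            sources[name] = x
    for name, start, end, load_class in events.intervals:
        i0 = rec.label_to_index(start)
        i1 = rec.label_to_index(end)
        if i0 >= rec.n_samples or i1 <= 0:
            warnings.warn(f"interval {name!r} lies outside the recording; dropped")
            continue
        if i1 > rec.n_samples or i0 < 0:
            warnings.warn(f"interval {name!r} extends beyond the recording; truncated")
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
        out.append(Slice(
            name=name, load_class=load_class,
            start_s=start, end_s=end, fs=rec.fs,
            channels={ch: x[i0:i1] for ch, x in sources.items()},
        ))
    return out
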