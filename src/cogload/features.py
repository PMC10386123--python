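"""Windowing, artefact rejection, and the 125-feature catalogue.

Labelled HL/LL slices are cut into 2-minute windows with 75% overlap
(30 s stride), windows are screened by three artefact rules (motion,
heart-rate variability, implausibly low heart rate), and 125 named features
are computed per surviving window in six groups:

=============  =====
ppg_time         46   statistics of the filtered pulse signal and its
                      first/second differences, plus peak-amplitude statistics
ppg_freq          4   band powers and their ratio of the pulse signal
hr               11   beat-level heart-rate statistics
temp              2   temperature mean and standard deviation
gsr_time         43   statistics of the raw conductance and its differences
gsr_decomp       19   tonic / phasic / sudomotor-driver statistics
=============  =====

The catalogue is frozen: group cardinalities are asserted at import time and
exported via :func:`feature_catalogue`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .preprocess import BeatSeries, smna_event_count

log = logging.getLogger(__name__)

WINDOW_S = 120.0
STRIDE_S = 30.0

MOTION_THRESHOLD = 0.5        # m/s^2, mean filtered magnitude per window
MIN_UNIQUE_HR = 3             # distinct integer-rounded heart rates required
MIN_MEAN_HR = 35.0            # beats/min

LF_BAND = (0.5, 1.5)          # Hz, around the cardiac fundamental
HF_BAND = (1.5, 4.0)          # Hz, harmonics


@dataclass
class Window:
    """One 2-minute analysis window cut from a single labelled slice."""

    subject_id: str
    session_type: str
    load_class: str
    task: str
    start_s: float                 # label clock
    fs: float
    channels: dict                 # ppg, gsr, tonic, phasic, smna, temp, accel_mag
    beats: BeatSeries
    artefact_flags: set = field(default_factory=set)

    @property
    def n_samples(self):
        return len(next(iter(self.channels.values())))


def expected_window_count(slice_duration_s, window_s=WINDOW_S, stride_s=STRIDE_S):
    """floor((L - W)/S) + 1 for L >= W, else 0."""
    if slice_duration_s < window_s:
        return 0
    return int(np.floor((slice_duration_s - window_s) / stride_s)) + 1


def make_windows(slices, fs=None, window_s=WINDOW_S, stride_s=STRIDE_S,
                 classes=("HL", "LL")):
    """Cut labelled slices into fixed-length overlapping windows.

    Only slices whose ``load_class`` is in ``classes`` are windowed; windows
    never span slice boundaries.
    """
    windows = []
    for sl in slices:
        if sl.load_class not in classes:
            continue
        fs_ = fs or sl.fs
        win_n = int(round(window_s * fs_))
        stride_n = int(round(stride_s * fs_))
        n = len(next(iter(sl.channels.values())))
        for i0 in range(0, n - win_n + 1, stride_n):
            off = i0 / fs_
            beats = None
            if getattr(sl, "beats", None) is not None:
                beats = sl.beats.slice(off, off + window_s).shifted(off)
            windows.append(Window(
                subject_id=getattr(sl, "subject_id", "unknown"),
                session_type=getattr(sl, "session_type", "unknown"),
                load_class=sl.load_class,
                task=sl.name,
                start_s=sl.start_s + off,
                fs=fs_,
                channels={ch: x[i0:i0 + win_n] for ch, x in sl.channels.items()},
                beats=beats,
            ))
    return windows


def flag_artefacts(w: Window, motion_threshold=MOTION_THRESHOLD,
                   min_unique_hr=MIN_UNIQUE_HR, min_mean_hr=MIN_MEAN_HR):
    """Apply the three artefact rules; returns the window with flags set.

    * ``motion``: mean band-passed accelerometer magnitude above threshold.
    * ``hr_unique``: fewer than ``min_unique_hr`` distinct integer-rounded
      heart-rate values in the window (i.e. no credible beat variability).
    * ``hr_low``: mean heart rate below ``min_mean_hr`` beats/min.
    """
    flags = set()
    if "accel_mag" in w.channels:
        if float(np.mean(w.channels["accel_mag"])) > motion_threshold:
            flags.add("motion")
    hr = w.beats.hr if w.beats is not None else np.array([])
    if len(np.unique(np.round(hr))) < min_unique_hr:
        flags.add("hr_unique")
    if len(hr) == 0 or float(np.mean(hr)) < min_mean_hr:
        flags.add("hr_low")
    w.artefact_flags = flags
    return w


# ---------------------------------------------------------------------------
# Catalogue construction
# ---------------------------------------------------------------------------

_STAT13 = ("mean", "sd", "min", "max", "range", "median", "iqr", "p10", "p90",
           "skew", "kurt", "rms", "zcr")


def _build_catalogue():
    cat = {}

    def add(name, group, label):
        assert name not in cat, name
        cat[name] = {"group": group, "label": label}

    for sig, desc in (("ppg", "filtered pulse signal"),
                      ("ppg_d1", "first difference of the pulse signal"),
                      ("ppg_d2", "second difference of the pulse signal")):
        for st in _STAT13:
            add(f"{sig}_{st}", "ppg_time", f"{st} of the {desc}")
    for st, lab in (("n_peaks", "Number of pulse peaks"),
                    ("peak_amp_mean", "Mean pulse peak amplitude"),
                    ("peak_amp_sd", "Standard deviation of pulse peak amplitude"),
                    ("peak_amp_max", "Maximum pulse peak amplitude"),
                    ("peak_amp_min", "Minimum pulse peak amplitude"),
                    ("peak_interval_mean", "Mean pulse peak-to-peak interval"),
                    ("peak_interval_sd", "Standard deviation of peak-to-peak interval")):
        add(f"ppg_{st}", "ppg_time", lab)

    add("ppg_power_lf", "ppg_freq", "Low-frequency band power of the pulse signal")
    add("ppg_power_hf", "ppg_freq", "High-frequency band power of the pulse signal")
    add("ppg_lf_hf_ratio", "ppg_freq", "LF/HF band-power ratio of the pulse signal")
    add("ppg_power_total", "ppg_freq", "Total spectral power of the pulse signal")

    add("hr_mean", "hr", "Mean heart rate")
    add("hr_sd", "hr", "Standard deviation of heart rate")
    for st, lab in (("min", "Minimum heart rate"), ("max", "Maximum heart rate"),
                    ("range", "Heart-rate range"), ("rmssd", "RMSSD of beat intervals"),
                    ("sdsd", "SDSD of beat intervals"),
                    ("pnn50", "Percentage of successive interval changes > 50 ms"),
                    ("median", "Median heart rate"),
                    ("iqr", "Interquartile range of heart rate"),
                    ("count", "Number of accepted beats")):
        add(f"hr_{st}", "hr", lab)

    add("temp_mean", "temp", "Mean")
    add("temp_sd", "temp", "Standard deviation")

    for sig, desc in (("gsr", "raw conductance"),
                      ("gsr_d1", "first difference of the conductance"),
                      ("gsr_d2", "second difference of the conductance")):
        for st in _STAT13:
            label = "Mean raw amplitude" if (sig, st) == ("gsr", "mean") else \
                f"{st} of the {desc}"
            add(f"{sig}_{st}", "gsr_time", label)
    add("gsr_slope", "gsr_time", "Linear slope of the conductance")
    add("gsr_auc", "gsr_time", "Area under the conductance curve")
    add("gsr_prop_increasing", "gsr_time", "Proportion of rising conductance samples")
    add("gsr_d1_max_abs", "gsr_time", "Maximum absolute conductance derivative")

    for st, lab in (("mean", "Mean of tonic component"),
                    ("sd", "Standard deviation tonic component"),
                    ("min", "Minimum of tonic component"),
                    ("max", "Maximum of tonic component"),
                    ("slope", "Linear slope of tonic component"),
                    ("max_power", "Maximum power of tonic component")):
        add(f"tonic_{st}", "gsr_decomp", lab)
    for st, lab in (("mean", "Mean of phasic component"),
                    ("sd", "Standard deviation phasic component"),
                    ("min", "Minimum of phasic component"),
                    ("max", "Maximum of phasic component"),
                    ("auc", "Area under phasic component"),
                    ("max_power", "Maximum power of phasic component"),
                    ("n_peaks", "Number of phasic peaks")):
        add(f"phasic_{st}", "gsr_decomp", lab)
    for st, lab in (("count", "Sudomotor nerve activity count"),
                    ("mean", "Mean sudomotor driver amplitude"),
                    ("sd", "Standard deviation of sudomotor driver"),
                    ("max", "Maximum sudomotor driver amplitude"),
                    ("auc", "Area under sudomotor driver"),
                    ("sum", "Total sudomotor driver output")):
        add(f"smna_{st}", "gsr_decomp", lab)
    return cat


FEATURE_CATALOGUE = _build_catalogue()
FEATURE_NAMES = list(FEATURE_CATALOGUE)
GROUP_SIZES = {"ppg_time": 46, "ppg_freq": 4, "hr": 11, "temp": 2,
               "gsr_time": 43, "gsr_decomp": 19}

_counts = pd.Series([v["group"] for v in FEATURE_CATALOGUE.values()]).value_counts()
for _g, _n in GROUP_SIZES.items():
    assert _counts[_g] == _n, (_g, int(_counts[_g]))
assert len(FEATURE_NAMES) == 125, len(FEATURE_NAMES)

METADATA_COLUMNS = ("subject_id", "session_type", "load_class", "task", "start_s")


def feature_catalogue():
    """name -> {group, label} for all 125 features, in column order."""
    return {k: dict(v) for k, v in FEATURE_CATALOGUE.items()}


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def _stats13(x, prefix):
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    out = {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_sd": sd,
        f"{prefix}_min": float(np.min(x)),
        f"{prefix}_max": float(np.max(x)),
        f"{prefix}_range": float(np.ptp(x)),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        f"{prefix}_p10": float(np.percentile(x, 10)),
        f"{prefix}_p90": float(np.percentile(x, 90)),
        f"{prefix}_rms": float(np.sqrt(np.mean(x**2))),
    }
    if sd > 0:
        out[f"{prefix}_skew"] = float(sp_stats.skew(x))
        out[f"{prefix}_kurt"] = float(sp_stats.kurtosis(x))
    else:  # degenerate window: moments of a constant are defined as 0 here
        out[f"{prefix}_skew"] = 0.0
        out[f"{prefix}_kurt"] = 0.0
    c = x - np.mean(x)
    out[f"{prefix}_zcr"] = float(np.sum(np.signbit(c[:-1]) != np.signbit(c[1:])))
    return out


def _slope(x, fs):
    t = np.arange(len(x)) / fs
    return float(np.polyfit(t, x, 1)[0]) if len(x) > 1 else 0.0


def _max_power(x, fs):
    nper = min(len(x), 512)
    f, p = sp_signal.welch(x, fs=fs, nperseg=nper)
    return float(np.max(p))


def _band_power(f, p, band):
    m = (f >= band[0]) & (f < band[1])
    return float(np.trapezoid(p[m], f[m])) if m.any() else 0.0


def extract_features(w: Window):
    """Compute the 125-feature vector for an artefact-free window."""
    fs = w.fs
    ppg = np.asarray(w.channels["ppg"], dtype=float)
    gsr = np.asarray(w.channels["gsr"], dtype=float)
    tonic = np.asarray(w.channels["tonic"], dtype=float)
    phasic = np.asarray(w.channels["phasic"], dtype=float)
    smna = np.asarray(w.channels["smna"], dtype=float)
    temp = np.asarray(w.channels["temp"], dtype=float)

    out = {}
    out.update(_stats13(ppg, "ppg"))
    out.update(_stats13(np.diff(ppg), "ppg_d1"))
    out.update(_stats13(np.diff(ppg, 2), "ppg_d2"))

    peaks = w.beats.peak_indices if w.beats is not None else np.array([], dtype=int)
    peaks = np.clip(peaks, 0, len(ppg) - 1)  # sub-sample times can straddle edges
    amps = ppg[peaks] if len(peaks) else np.array([0.0])
    ipis = np.diff(peaks) / fs if len(peaks) > 1 else np.array([0.0])
    out["ppg_n_peaks"] = float(len(peaks))
    out["ppg_peak_amp_mean"] = float(np.mean(amps))
    out["ppg_peak_amp_sd"] = float(np.std(amps))
    out["ppg_peak_amp_max"] = float(np.max(amps))
    out["ppg_peak_amp_min"] = float(np.min(amps))
    out["ppg_peak_interval_mean"] = float(np.mean(ipis))
    out["ppg_peak_interval_sd"] = float(np.std(ipis))

    f, p = sp_signal.welch(ppg, fs=fs, nperseg=min(len(ppg), 1024))
    lf = _band_power(f, p, LF_BAND)
    hf = _band_power(f, p, HF_BAND)
    out["ppg_power_lf"] = lf
    out["ppg_power_hf"] = hf
    out["ppg_lf_hf_ratio"] = lf / hf if hf > 0 else 0.0
    out["ppg_power_total"] = float(np.trapezoid(p, f))

    hr = w.beats.hr if w.beats is not None else np.array([])
    ibi_ms = w.beats.ibi * 1000.0 if w.beats is not None else np.array([])
    if len(hr):
        dibi = np.diff(ibi_ms) if len(ibi_ms) > 1 else np.array([0.0])
        out["hr_mean"] = float(np.mean(hr))
        out["hr_sd"] = float(np.std(hr))
        out["hr_min"] = float(np.min(hr))
        out["hr_max"] = float(np.max(hr))
        out["hr_range"] = float(np.ptp(hr))
        out["hr_rmssd"] = float(np.sqrt(np.mean(dibi**2)))
        out["hr_sdsd"] = float(np.std(dibi))
        out["hr_pnn50"] = float(100.0 * np.mean(np.abs(dibi) > 50.0))
        out["hr_median"] = float(np.median(hr))
        out["hr_iqr"] = float(np.percentile(hr, 75) - np.percentile(hr, 25))
        out["hr_count"] = float(len(hr))
    else:
        for k in ("hr_mean", "hr_sd", "hr_min", "hr_max", "hr_range", "hr_rmssd",
                  "hr_sdsd", "hr_pnn50", "hr_median", "hr_iqr", "hr_count"):
            out[k] = np.nan

    out["temp_mean"] = float(np.mean(temp))
    out["temp_sd"] = float(np.std(temp))

    out.update(_stats13(gsr, "gsr"))
    d1 = np.diff(gsr)
    out.update(_stats13(d1, "gsr_d1"))
    out.update(_stats13(np.diff(gsr, 2), "gsr_d2"))
    out["gsr_slope"] = _slope(gsr, fs)
    out["gsr_auc"] = float(np.trapezoid(gsr, dx=1.0 / fs))
    out["gsr_prop_increasing"] = float(np.mean(d1 > 0)) if len(d1) else 0.0
    out["gsr_d1_max_abs"] = float(np.max(np.abs(d1))) if len(d1) else 0.0

    out["tonic_mean"] = float(np.mean(tonic))
    out["tonic_sd"] = float(np.std(tonic))
    out["tonic_min"] = float(np.min(tonic))
    out["tonic_max"] = float(np.max(tonic))
    out["tonic_slope"] = _slope(tonic, fs)
    out["tonic_max_power"] = _max_power(tonic, fs)

    ph_peaks, _ = sp_signal.find_peaks(phasic, prominence=0.01)
    out["phasic_mean"] = float(np.mean(phasic))
    out["phasic_sd"] = float(np.std(phasic))
    out["phasic_min"] = float(np.min(phasic))
    out["phasic_max"] = float(np.max(phasic))
    out["phasic_auc"] = float(np.trapezoid(phasic, dx=1.0 / fs))
    out["phasic_max_power"] = _max_power(phasic, fs)
    out["phasic_n_peaks"] = float(len(ph_peaks))

    out["smna_count"] = float(smna_event_count(smna, fs))
    out["smna_mean"] = float(np.mean(smna))
    out["smna_sd"] = float(np.std(smna))
    out["smna_max"] = float(np.max(smna))
    out["smna_auc"] = float(np.trapezoid(smna, dx=1.0 / fs))
    out["smna_sum"] = float(np.sum(smna))

    assert set(out) == set(FEATURE_NAMES)
    return {k: out[k] for k in FEATURE_NAMES}  # frozen column order


def build_feature_table(windows, apply_flags=True):
    """Feature table over artefact-free windows.

    Flagged windows and windows producing any non-finite feature are dropped
    (with the offending feature logged).
    """
    rows = []
    for w in windows:
        if apply_flags and w.artefact_flags:
            log.info("window %s/%s@%.0fs dropped: flags=%s", w.subject_id,
                     w.load_class, w.start_s, sorted(w.artefact_flags))
            continue
        feats = extract_features(w)
        bad = [k for k, v in feats.items() if not np.isfinite(v)]
        if bad:
            log.warning("window %s/%s@%.0fs dropped: non-finite %s",
                        w.subject_id, w.load_class, w.start_s, bad)
            continue
        row = {"subject_id": w.subject_id, "session_type": w.session_type,
               "load_class": w.load_class, "task": w.task, "start_s": w.start_s}
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + FEATURE_NAMES)
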