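"""Online cardiovascular signal conditioning and feature extraction.

Implements the 13-element cardiovascular feature vector computed from a
lead-II ECG and an arterial blood pressure (aBP) channel of an anesthetized
rat: per-beat ECG fiducials (P, Ta, Q, R, S, T and the isoelectric TP
reference), per-pulse systolic/diastolic pressure points, and a respiratory
rate derived from the linear envelope of the aBP waveform.  The feature
vector is emitted on a 100 ms grid and averaged over a trailing 4 s window.

Feature channels (units):

====  ======================  ========
 #    feature                 unit
====  ======================  ========
 1    ST epoch level          mV
 2    heart rate              bpm
 3    QRS duration            ms
 4    RT duration             ms
 5    ST duration             ms
 6    Ta level                mV
 7    R level                 mV
 8    ST slope                mV/s
 9    diastolic pressure      mmHg
10    systolic pressure       mmHg
11    mean arterial pressure  mmHg
12    pulse pressure          mmHg
13    breath rate             brpm
====  ======================  ========

ECG wave *levels* (features 1, 6 and 7) are referenced to the mean voltage
of the TP interval of the same cycle, so that a resting ST epoch sits near
0 mV and subendocardial ischemia drives it negative.  A config switch
(``literal_tp_sum``) restores the literal sum of wave level and TP level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "FeatureConfig",
    "FeatureFrame",
    "DerivedIndices",
    "FEATURE_NAMES",
    "FEATURE_UNITS",
    "condition_epoch",
    "detect_r_peaks",
    "detect_fiducials",
    "detect_bp_extrema",
    "breath_envelope",
    "breath_rate",
    "compute_features",
    "extract_features",
    "baseline_normalize",
    "derived_indices",
    "window_average",
    "step_grid",
]

FEATURE_NAMES = (
    "st_level", "heart_rate", "qrs_duration", "rt_duration", "st_duration",
    "ta_level", "r_level", "st_slope", "diastolic", "systolic",
    "map", "pulse_pressure", "breath_rate",
)
FEATURE_UNITS = (
    "mV", "bpm", "ms", "ms", "ms", "mV", "mV", "mV/s",
    "mmHg", "mmHg", "mmHg", "mmHg", "brpm",
)

STEP = 0.1              # feature update period (s)
WINDOW = 4.0            # trailing averaging window (s)


@dataclass
class FeatureConfig:
    """Tunable constants of the extraction pipeline.

    Fiducial search windows are expressed as fractions of the local RR
    interval, relative to the R peak (negative = before R).  They are sized
    for rat beats (RR around 130-170 ms) but scale with rate.
    """

    fs_raw: float = 10_000.0
    fs: float = 500.0                       # working rate after decimation
    # ECG peak picking
    r_prominence_frac: float = 0.5          # x median beat amplitude
    r_refractory: float = 0.060             # s
    # aBP peak picking
    bp_prominence_frac: float = 0.25        # x median pulse amplitude
    bp_refractory: float = 0.080            # s
    # fiducial windows, fractions of RR (lo, hi), half-open [lo, hi)
    win_p: tuple[float, float] = (-0.36, -0.18)
    win_ta: tuple[float, float] = (-0.18, -0.08)
    win_q: tuple[float, float] = (-0.08, -0.015)
    win_s: tuple[float, float] = (0.015, 0.115)
    win_t: tuple[float, float] = (0.125, 0.55)
    win_tp: tuple[float, float] = (0.40, 0.62)   # isoelectric reference
    # respiration
    resp_lowpass_hz: float = 3.0
    resp_baseline_hz: float = 0.15
    resp_min_interval: float = 0.2          # s between breaths
    # bookkeeping
    literal_tp_sum: bool = False            # printed-formula sum instead of difference
    carry_forward_max: float = 0.5          # s of missing-beat carry forward
    sd_floor_rel: float = 1e-6
    sd_floor_abs: float = 1e-9
    # per-feature baseline-SD floors at the measurement resolution of each
    # channel (mV / bpm / ms / mV/s / mmHg / brpm); a 30 s background can
    # otherwise underestimate a feature's variability severalfold and blow
    # up the standardized magnitudes of a whole recording
    sd_resolution: tuple = (0.002, 1.0, 0.5, 0.5, 0.5, 0.002, 0.002,
                            0.2, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass
class FeatureFrame:
    """The 13-feature time series on the 100 ms grid."""

    step_times: np.ndarray                  # (n,) s from recording start
    X: np.ndarray                           # (n, 13)
    labels: np.ndarray                      # (n,) str state labels
    missing: np.ndarray                     # (n,) bool
    baseline_mean: np.ndarray | None = None  # (13,)
    baseline_sd: np.ndarray | None = None    # (13,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.step_times = np.asarray(self.step_times, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (self.step_times.size, 13):
            raise ValueError(f"X must be (n, 13), got {self.X.shape}")

    def __len__(self):
        return self.step_times.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{i+1}_{n}" for i, n in enumerate(FEATURE_NAMES)])
        df.insert(0, "step_time", self.step_times)
        df["label"] = self.labels
        df["missing"] = self.missing
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def copy(self) -> "FeatureFrame":
        return replace(
            self,
            step_times=self.step_times.copy(), X=self.X.copy(),
            labels=self.labels.copy(), missing=self.missing.copy(),
            baseline_mean=None if self.baseline_mean is None else self.baseline_mean.copy(),
            baseline_sd=None if self.baseline_sd is None else self.baseline_sd.copy(),
            meta=dict(self.meta),
        )


@dataclass
class DerivedIndices:
    """Offline indices derived alongside the 13 features."""

    step_times: np.ndarray
    rpp: np.ndarray        # (heart rate x systolic)/100
    qtc: np.ndarray        # Bazett, QT(ms)/sqrt(RR(ms))
    qt_tq: np.ndarray      # QT / (RR - QT)
    flagged: np.ndarray    # bool, QT/TQ undefined at step


def step_grid(t_start: float, t_end: float, step: float = STEP) -> np.ndarray:
    """Feature step times: floor((t_end - t_start)/step) + 1 points."""
    n = int(np.floor((t_end - t_start) / step + 1e-9)) + 1
    return np.round(t_start + step * np.arange(n), 6)


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def condition_epoch(raw_ecg, raw_abp, fs_in: float = 10_000.0, fs_out: float = 500.0):
    """Anti-aliased decimation of the 10 kHz raw channels to 500 Hz.

    Uses a zero-phase FIR decimator so fiducial timing is not skewed.
    """
    raw_ecg = np.asarray(raw_ecg, dtype=float)
    raw_abp = np.asarray(raw_abp, dtype=float)
    if raw_ecg.size == 0 or raw_abp.size == 0:
        raise ValueError("empty signal")
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer factor, got {q}")
    q = int(round(q))
    if q == 1:
        return raw_ecg.copy(), raw_abp.copy()
    ecg = sps.decimate(raw_ecg, q, ftype="fir", zero_phase=True)
    abp = sps.decimate(raw_abp, q, ftype="fir", zero_phase=True)
    return ecg, abp


def _parabolic_refine(y: np.ndarray, idx: int, fs: float):
    """Sub-sample vertex of the parabola through (idx-1, idx, idx+1).

    Returns (time, level) with time in seconds from the start of ``y``.
    """
    if idx <= 0 or idx >= y.size - 1:
        return idx / fs, float(y[idx])
    y0, y1, y2 = float(y[idx - 1]), float(y[idx]), float(y[idx + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return idx / fs, y1
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    level = y1 - 0.25 * (y0 - y2) * delta
    return (idx + delta) / fs, level


_SEG_LEN = 10.0    # s; local-threshold segment for nonstationary amplitudes
_SEG_PAD = 0.5     # s of overlap so segment-edge peaks keep their prominence


def _segmented_peaks(x, fs, amp_fn, prom_frac, distance_s, min_amp=1e-12):
    """Prominence peak picking with per-segment thresholds.

    The deployed pipeline thresholds each short epoch locally, so detection
    must survive severalfold amplitude changes across a recording (e.g.
    high-dose pressor responses).  ``amp_fn(segment)`` estimates the local
    beat amplitude; peaks are picked per segment at ``prom_frac`` of it.
    """
    n = x.size
    seg = int(_SEG_LEN * fs)
    pad = int(_SEG_PAD * fs)
    dist = max(1, int(distance_s * fs))
    out = []
    for s in range(0, n, seg):
        lo, hi = max(0, s - pad), min(n, s + seg + pad)
        segment = x[lo:hi]
        amp = amp_fn(segment)
        if amp <= min_amp:
            continue
        idx, _ = sps.find_peaks(segment, prominence=prom_frac * amp, distance=dist)
        idx = idx + lo
        out.extend(int(i) for i in idx if s <= i < s + seg)
    out = np.array(sorted(set(out)), dtype=int)
    if out.size > 1:
        keep = np.concatenate([[True], np.diff(out) >= dist])
        out = out[keep]
    return out


def detect_r_peaks(ecg: np.ndarray, fs: float, config: FeatureConfig | None = None):
    """Prominence-based R peak picking with a physiologic refractory period.

    Thresholds adapt per 10 s segment (half the median beat amplitude of
    the segment).  Returns (times, levels, flagged); ``flagged`` is True
    when no peaks could be found (e.g. a flat line).
    """
    config = config or FeatureConfig()
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < fs:
        raise ValueError("need at least 1 s of signal")
    idx = _segmented_peaks(
        ecg, fs, lambda s: np.percentile(s, 99.5) - np.median(s),
        config.r_prominence_frac, config.r_refractory)
    if idx.size == 0:
        return np.array([]), np.array([]), True
    times = np.empty(idx.size)
    levels = np.empty(idx.size)
    for k, i in enumerate(idx):
        times[k], levels[k] = _parabolic_refine(ecg, int(i), fs)
    return times, levels, False


def _extremum_in_window(ecg, fs, t_lo, t_hi, mode):
    """Refined extremum of ``ecg`` on [t_lo, t_hi); None if out of bounds."""
    i_lo = int(np.ceil(t_lo * fs))
    i_hi = int(np.floor(t_hi * fs))
    if i_lo < 1 or i_hi >= ecg.size - 1 or i_hi <= i_lo:
        return None
    seg = ecg[i_lo:i_hi]
    j = int(np.argmax(seg) if mode == "max" else np.argmin(seg))
    return _parabolic_refine(ecg, i_lo + j, fs)


def detect_fiducials(ecg: np.ndarray, fs: float, r_times: np.ndarray,
                     r_levels: np.ndarray, config: FeatureConfig | None = None):
    """Window-based detection of P, Ta, Q, S and T around each R peak.

    Beats whose search windows fall outside the record (or with no
    following R to bound RR) are dropped and counted.  Returns a dict of
    per-beat arrays keyed by fiducial name plus ``tp_level`` (isoelectric
    reference), ``rr`` and ``n_dropped``.
    """
    config = config or FeatureConfig()
    ecg = np.asarray(ecg, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    out = {k: [] for k in ("r_time", "r_level", "rr", "p_time", "p_level",
                           "ta_time", "ta_level", "q_time", "q_level",
                           "s_time", "s_level", "t_time", "t_level", "tp_level")}
    dropped = 0
    if r_times.size < 2:
        out = {k: np.array(v) for k, v in out.items()}
        out["n_dropped"] = 0
        return out

    windows = {
        "p": (config.win_p, "max"),
        "ta": (config.win_ta, "min"),
        "q": (config.win_q, "min"),
        "s": (config.win_s, "min"),
        "t": (config.win_t, "max"),
    }
    for i in range(r_times.size - 1):
        r = r_times[i]
        rr = r_times[i + 1] - r_times[i]
        beat = {}
        ok = True
        for name, ((lo, hi), mode) in windows.items():
            res = _extremum_in_window(ecg, fs, r + lo * rr, r + hi * rr, mode)
            if res is None:
                ok = False
                break
            beat[name] = res
        lo, hi = config.win_tp
        i_lo, i_hi = int(np.ceil((r + lo * rr) * fs)), int(np.floor((r + hi * rr) * fs))
        if not ok or i_lo < 0 or i_hi > ecg.size or i_hi <= i_lo:
            dropped += 1
            continue
        tp = float(np.mean(ecg[i_lo:i_hi]))
        out["r_time"].append(r)
        out["r_level"].append(r_levels[i])
        out["rr"].append(rr)
        for name in ("p", "ta", "q", "s", "t"):
            out[f"{name}_time"].append(beat[name][0])
            out[f"{name}_level"].append(beat[name][1])
        out["tp_level"].append(tp)
    out = {k: np.asarray(v, dtype=float) for k, v in out.items()}
    out["n_dropped"] = dropped
    return out


def detect_bp_extrema(abp: np.ndarray, fs: float, config: FeatureConfig | None = None):
    """Systolic peaks and paired diastolic minima of the aBP waveform.

    Each pulse pairs a systolic peak with the diastolic minimum of the
    preceding inter-systolic interval, which resolves any non-alternating
    raw extrema.  Returns dict with per-pulse arrays and a ``flagged`` bool
    (constant pressure -> no extrema).
    """
    config = config or FeatureConfig()
    abp = np.asarray(abp, dtype=float)
    empty = {k: np.array([]) for k in ("sys_time", "sys_p", "dia_time", "dia_p")}
    idx = _segmented_peaks(
        abp, fs, lambda s: np.percentile(s, 98) - np.percentile(s, 2),
        config.bp_prominence_frac, config.bp_refractory, min_amp=1e-9)
    if idx.size < 2:
        return {**empty, "flagged": True}
    sys_time, sys_p, dia_time, dia_p = [], [], [], []
    for k in range(1, idx.size):
        st, sp = _parabolic_refine(abp, int(idx[k]), fs)
        seg = abp[idx[k - 1]:idx[k]]
        j = int(np.argmin(seg))
        dt, dp = _parabolic_refine(abp, int(idx[k - 1]) + j, fs)
        if sp <= dp:
            continue
        sys_time.append(st); sys_p.append(sp)
        dia_time.append(dt); dia_p.append(dp)
    return {
        "sys_time": np.asarray(sys_time), "sys_p": np.asarray(sys_p),
        "dia_time": np.asarray(dia_time), "dia_p": np.asarray(dia_p),
        "flagged": len(sys_time) == 0,
    }


_ENV_FS = 50.0   # resample rate of the envelope series (Hz)


def breath_envelope(abp: np.ndarray, fs: float, config: FeatureConfig | None = None):
    """Linear envelope of the aBP waveform carrying the respiratory cycle.

    The envelope is the upper-minus-lower pressure excursion of each pulse
    (systolic minus paired diastolic level), resampled to a uniform grid and
    low-pass filtered below the cardiac frequency.  Respiration modulates
    the pulse amplitude, so the envelope oscillates at the breath rate.
    Returns ``(t_grid, envelope)``.
    """
    config = config or FeatureConfig()
    pulses = detect_bp_extrema(abp, fs, config)
    n = np.asarray(abp).size
    t_grid = np.arange(int(n / fs * _ENV_FS)) / _ENV_FS
    if pulses["flagged"] or pulses["sys_time"].size < 4:
        return t_grid, np.zeros(t_grid.size)
    amp = pulses["sys_p"] - pulses["dia_p"]
    env = np.interp(t_grid, pulses["sys_time"], amp)
    nyq = _ENV_FS / 2.0
    b, a = sps.butter(4, config.resp_lowpass_hz / nyq, "low")
    return t_grid, sps.filtfilt(b, a, env)


def breath_times(abp: np.ndarray, fs: float, config: FeatureConfig | None = None):
    """Inhalation peak times from the aBP envelope; (times, flagged).

    Peak prominence is measured on the envelope normalized by its own slow
    baseline (relative modulation), so the detector is insensitive to
    pressure drifts across the recording; zero modulation depth flags the
    result instead of returning spurious breaths.
    """
    config = config or FeatureConfig()
    t_grid, env = breath_envelope(abp, fs, config)
    nyq = _ENV_FS / 2.0
    b, a = sps.butter(2, config.resp_baseline_hz / nyq, "low")
    base = sps.filtfilt(b, a, env)
    base = np.where(np.abs(base) < 1e-9, 1e-9, base)
    rel = env / base - 1.0
    depth = float(np.percentile(np.abs(rel - np.median(rel)), 90))
    if depth <= 2e-3:   # below 0.2 % relative modulation: no respiration signal
        return np.array([]), True
    idx, _ = sps.find_peaks(
        rel, prominence=0.6 * depth,
        distance=max(1, int(config.resp_min_interval * _ENV_FS)),
    )
    if idx.size == 0:
        return np.array([]), True
    times = np.array([_parabolic_refine(rel, int(i), _ENV_FS)[0] for i in idx])
    return times, False


def breath_rate(abp: np.ndarray, fs: float, config: FeatureConfig | None = None) -> float:
    """Breaths per minute over the given window of aBP signal.

    Rate is 60 / median inter-breath interval, which is robust to partial
    cycles at the window edges.  Returns 0.0 when there is no respiratory
    modulation (flagged condition).
    """
    times, flagged = breath_times(abp, fs, config)
    if flagged or times.size < 2:
        return 0.0
    return 60.0 / float(np.median(np.diff(times)))


# ---------------------------------------------------------------------------
# the 13-element feature vector
# ---------------------------------------------------------------------------

def _beat_feature_table(beats: dict, config: FeatureConfig):
    """Per-beat values of features 1-8 (times = R times)."""
    sign = 1.0 if config.literal_tp_sum else -1.0
    tp = beats["tp_level"]
    st_dur_s = beats["t_time"] - beats["s_time"]
    return {
        "t": beats["r_time"],
        "f1": beats["s_level"] + sign * tp,
        "f2": 60.0 / beats["rr"],
        "f3": 1e3 * (beats["s_time"] - beats["q_time"]),
        "f4": 1e3 * (beats["t_time"] - beats["r_time"]),
        "f5": 1e3 * st_dur_s,
        "f6": beats["ta_level"] + sign * tp,
        "f7": beats["r_level"] + sign * tp,
        "f8": (beats["t_level"] - beats["s_level"]) / st_dur_s,
    }


def compute_features(beats: dict, pulses: dict, breath_rate_value: float,
                     config: FeatureConfig | None = None) -> np.ndarray:
    """One 13-element feature vector from the annotations of one window.

    ``beats``/``pulses`` hold the per-beat and per-pulse annotation arrays
    of the trailing 4 s window; beat-level quantities are averaged across
    the beats present.  An empty window yields a vector of NaN.
    """
    config = config or FeatureConfig()
    v = np.full(13, np.nan)
    if beats["r_time"].size:
        tab = _beat_feature_table(beats, config)
        for i in range(8):
            v[i] = float(np.mean(tab[f"f{i+1}"]))
    if pulses["sys_time"].size:
        dia = float(np.mean(pulses["dia_p"]))
        sys_ = float(np.mean(pulses["sys_p"]))
        v[8] = dia
        v[9] = sys_
        v[10] = (sys_ + dia) / 2.0
        v[11] = sys_ - dia
    v[12] = breath_rate_value
    return v


def window_average(times: np.ndarray, values: np.ndarray, step_times: np.ndarray,
                   width: float = WINDOW) -> np.ndarray:
    """Mean of ``values`` over trailing half-open windows [t - width, t).

    Steps whose window holds no events yield NaN.  O(n + m) via cumulative
    sums; shared by the extractor and by the simulator's ground truth so
    both aggregate identically.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(times, step_times - width, side="left")
    hi = np.searchsorted(times, step_times, side="left")
    n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (csum[hi] - csum[lo]) / n
    out[n == 0] = np.nan
    return out


def _carry_forward(X: np.ndarray, step: float, max_carry: float):
    """Fill NaN steps from the previous step for at most ``max_carry`` s.

    Returns (X filled, missing mask) -- steps still NaN after the carry
    budget are flagged missing.
    """
    X = X.copy()
    max_steps = int(round(max_carry / step))
    n = X.shape[0]
    missing = np.zeros(n, dtype=bool)
    carry = 0
    for i in range(n):
        row_nan = np.isnan(X[i]).any()
        if row_nan and i > 0 and carry < max_steps and not missing[i - 1]:
            X[i] = X[i - 1]
            carry += 1
        elif row_nan:
            missing[i] = True
        else:
            carry = 0
    return X, missing


def _labels_for_steps(step_times: np.ndarray, protocol) -> np.ndarray:
    """Per-step state labels: rest before the label change point, the
    protocol's agent afterwards (label change = infusion start + onset lag,
    the point where features statistically deviate from baseline)."""
    labels = np.full(step_times.size, "rest", dtype=object)
    if getattr(protocol, "agent", "rest") != "rest":
        t_change = protocol.label_change
        t_end = getattr(protocol, "infusion_end", None)
        mask = step_times >= t_change - 1e-9
        if t_end is not None and t_end < protocol.timeline["end"]:
            mask &= step_times < t_end + protocol.onset_lag - 1e-9
        labels[mask] = protocol.agent
    return labels


def extract_features(record, config: FeatureConfig | None = None) -> FeatureFrame:
    """Run the full conditioning + detection + feature pipeline on a record.

    ``record`` needs ``ecg``, ``abp``, ``fs`` and ``protocol`` attributes
    (any object in the shape produced by :mod:`cardioloop.synth`, or loaded
    from CSV).  Output steps run from the protocol's window-init time to the
    recording end at 100 ms, each averaging the trailing 4 s.
    """
    config = config or FeatureConfig()
    if abs(record.fs - config.fs_raw) > 1e-6:
        raise ValueError(f"expected fs={config.fs_raw}, got {record.fs}")
    ecg, abp = condition_epoch(record.ecg, record.abp, record.fs, config.fs)
    fs = config.fs

    protocol = record.protocol
    t0 = protocol.timeline["window_init"]
    t_end = protocol.timeline["end"]
    steps = step_grid(t0, min(t_end, len(ecg) / fs))

    r_times, r_levels, r_flagged = detect_r_peaks(ecg, fs, config)
    X = np.full((steps.size, 13), np.nan)
    if not r_flagged:
        beats = detect_fiducials(ecg, fs, r_times, r_levels, config)
        if beats["r_time"].size:
            tab = _beat_feature_table(beats, config)
            for i in range(8):
                X[:, i] = window_average(tab["t"], tab[f"f{i+1}"], steps)
    pulses = detect_bp_extrema(abp, fs, config)
    if not pulses["flagged"]:
        dia = window_average(pulses["sys_time"], pulses["dia_p"], steps)
        sys_ = window_average(pulses["sys_time"], pulses["sys_p"], steps)
        X[:, 8] = dia
        X[:, 9] = sys_
        X[:, 10] = (sys_ + dia) / 2.0
        X[:, 11] = sys_ - dia
    br_times, br_flagged = breath_times(abp, fs, config)
    if not br_flagged and br_times.size >= 2:
        ibi_t = br_times[1:]
        ibi = np.diff(br_times)
        for widen in (WINDOW, 2 * WINDOW, 4 * WINDOW):
            rate = window_average(ibi_t, ibi, steps, width=widen)
            if widen == WINDOW:
                br = 60.0 / rate
            else:
                br = np.where(np.isnan(br), 60.0 / rate, br)
            if not np.isnan(br).any():
                break
        X[:, 12] = br
    else:
        X[:, 12] = 0.0

    X, missing = _carry_forward(X, STEP, config.carry_forward_max)
    frame = FeatureFrame(
        step_times=steps, X=X,
        labels=_labels_for_steps(steps, protocol),
        missing=missing,
        meta={"n_dropped_beats": 0 if r_flagged else beats["n_dropped"],
              "r_flagged": r_flagged,
              "timeline": dict(protocol.timeline)},
    )
    return frame


# ---------------------------------------------------------------------------
# baseline normalization and derived indices
# ---------------------------------------------------------------------------

def baseline_normalize(frame: FeatureFrame, background: tuple[float, float] | None = None,
                       min_background: float = 30.0,
                       config: FeatureConfig | None = None):
    """Baseline-subtract and standardize a frame from its background window.

    ``background`` defaults to the protocol window [window-init, decode
    start), i.e. the 30 s of pre-infusion feature data.  Returns
    ``(delta, z)`` arrays of the frame's shape and stores the per-feature
    baseline mean/SD on the frame.  The SD floor guards degenerate
    (constant) background features.
    """
    config = config or FeatureConfig()
    if background is None:
        tl = frame.meta.get("timeline")
        if tl is None:
            raise ValueError("no background window given and none in frame.meta")
        background = (tl["window_init"], tl["decode_start"])
    lo, hi = background
    if hi - lo < min_background - 1e-9:
        raise ValueError(f"background window {hi - lo:.1f} s shorter than {min_background} s")
    mask = (frame.step_times >= lo - 1e-9) & (frame.step_times < hi - 1e-9) & ~frame.missing
    if not mask.any():
        raise ValueError("background window holds no valid steps")
    mean = np.nanmean(frame.X[mask], axis=0)
    sd = np.nanstd(frame.X[mask], axis=0)
    sd = np.maximum(sd, config.sd_floor_rel * np.abs(mean) + config.sd_floor_abs)
    if len(config.sd_resolution) == sd.size:
        sd = np.maximum(sd, np.asarray(config.sd_resolution))
    frame.baseline_mean, frame.baseline_sd = mean, sd
    delta = frame.X - mean
    return delta, delta / sd


def derived_indices(frame: FeatureFrame, beats: dict | None = None) -> DerivedIndices:
    """RPP, Bazett QTc and the QT/TQ reentry-risk ratio per step.

    RPP = (heart rate x systolic pressure) / 100.  QTc = QT(ms)/sqrt(RR(ms))
    as printed by Bazett's formula.  QT runs from the Q-wave nadir to the T
    peak; TQ = RR - QT.  When per-beat annotations are given the QT is
    window-averaged from them, otherwise it is approximated from the frame's
    QRS/RT durations (QT = RT + QRS/2).
    """
    hr = frame.X[:, 1]
    sys_ = frame.X[:, 9]
    rpp = hr * sys_ / 100.0
    rr_ms = 60_000.0 / hr
    if beats is not None and beats["r_time"].size:
        qt_beat = 1e3 * (beats["t_time"] - beats["q_time"])
        qt_ms = window_average(beats["r_time"], qt_beat, frame.step_times)
    else:
        qt_ms = frame.X[:, 3] + frame.X[:, 2] / 2.0
    qtc = qt_ms / np.sqrt(rr_ms)
    tq = rr_ms - qt_ms
    flagged = ~(tq > 0)
    qt_tq = np.where(flagged, np.nan, qt_ms / np.where(flagged, np.nan, tq))
    return DerivedIndices(frame.step_times.copy(), rpp, qtc, qt_tq, flagged)
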