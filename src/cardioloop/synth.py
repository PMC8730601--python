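"""Synthetic rat cardiovascular recordings with exact ground truth.

Generates paired 10 kHz ECG and arterial blood pressure (aBP) waveforms
under catecholamine-infusion protocols (dobutamine D, norepinephrine NE,
combined D+NE, and 5x high-dose variants), together with exact per-beat
annotations and a per-100 ms ground-truth feature frame.  Beat morphology is
template-based: each wave (P, Ta, Q, R, S, T) is a compact raised-cosine
lobe whose amplitude and timing are driven by a slowly varying generative
feature series, so the true value of every extracted feature is known by
construction at every step.

The simulator also hosts a configurable vagus-nerve-stimulation response
plant: while stimulation is ON (and the vagus is intact) the infusion-
induced deviation of each feature relaxes toward baseline by a per-feature
reversal gain with a first-order time constant.  The plant is artifact
plumbing for end-to-end closed-loop tests, anchored to the qualitative
in-vivo observation that closed-loop stimulation reverses the ischemic
feature shifts and that a caudal vagotomy abolishes the effect.

Protocol timeline (defaults, seconds): stream start 0, sliding-window init
4, decode start 34 (30 s background), infusion start 94, end 214.  Feature
deviations ramp in ~15 s after infusion start, so state labels switch from
rest to the infused agent at 109 s, balancing the two label spans (105 s
each).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    FeatureFrame, step_grid, window_average, _labels_for_steps, STEP, WINDOW,
)

__all__ = [
    "AGENTS", "HIGH_DOSE_AGENTS", "PRIMARY_FEATURES",
    "InfusionProtocol", "SubjectParams", "PlantConfig", "WaveformRecord",
    "default_effect_table", "generate_recording", "inject_arrhythmia",
    "draw_subject", "generate_cohort", "save_record", "load_record",
]

AGENTS = ("rest", "D", "NE", "D+NE")
HIGH_DOSE_AGENTS = ("H-D", "H-NE", "H-D+NE")
HIGH_DOSE_SCALE = 5.0       # 10 ug/kg/min vs the standard 2-3 ug/kg/min

# generative primaries; f5/f11/f12 are geometric consequences
PRIMARY_FEATURES = ("f1", "f2", "f3", "f4", "f6", "f7", "f8", "f9", "f10", "f13")

# physiologic clip ranges for generative values (unit of each feature)
_CLIP = {
    "f1": (-0.6, 0.2), "f2": (150.0, 650.0), "f3": (8.0, 30.0),
    "f4": (20.0, 80.0), "f6": (-0.3, 0.1), "f7": (0.2, 2.0),
    "f8": (-5.0, 40.0), "f9": (20.0, 200.0), "f10": (40.0, 320.0),
    "f13": (20.0, 250.0),
}

# wave geometry: (center, half-width) as fractions of RR; Q/S/T centers are
# overridden per beat by the QRS/RT duration features.  Half-widths carry an
# absolute floor (s) so the lobes stay within the 250 Hz band of the 500 Hz
# working rate even at high heart rates.
_WAVE_GEOM = {
    "p": (-0.24, 0.055),
    "ta": (-0.12, 0.045),
    "q": (None, 0.024),
    "r": (0.0, 0.033),
    "s": (None, 0.024),
    "t": (None, 0.075),
}
_HW_FLOOR = {"q": 0.0035, "r": 0.0048, "s": 0.005, "t": 0.009, "p": 0.007, "ta": 0.006}
_TP_WINDOW = (0.40, 0.62)      # isoelectric span, fraction of RR after R
_P_AMP_DEFAULT = 0.10          # mV
_Q_AMP_DEFAULT = -0.10         # mV
_PULSE_DELAY = 0.030           # s, R peak to aBP upstroke foot
_PULSE_RISE = 0.25             # fraction of cycle from foot to systolic peak


def default_effect_table() -> dict:
    """Per-agent target shifts of the generative features at dose scale 1.

    Signs follow the infusion-response directions of the in-vivo data: ST
    epoch depression, tachycardia, mild QRS widening, RT shortening, Ta and
    R level depression, ST slope steepening, pressor response, and a breath
    rate increase, with the combined infusion maximal and NE closer to D+NE
    than D is.  Magnitudes are free model parameters (the source figures
    print no numbers); all are overridable.
    """
    return {
        "D":    {"f1": -0.010, "f2": 40.0, "f3": 0.5, "f4": -3.0, "f6": -0.008,
                 "f7": -0.04, "f8": 0.4, "f9": 4.0, "f10": 15.0, "f13": 4.0},
        "NE":   {"f1": -0.030, "f2": 25.0, "f3": 0.5, "f4": -4.0, "f6": -0.015,
                 "f7": -0.08, "f8": 0.8, "f9": 22.0, "f10": 40.0, "f13": 7.0},
        "D+NE": {"f1": -0.050, "f2": 60.0, "f3": 1.0, "f4": -6.0, "f6": -0.025,
                 "f7": -0.12, "f8": 1.4, "f9": 28.0, "f10": 50.0, "f13": 11.0},
    }


@dataclass
class InfusionProtocol:
    """One recording's infusion schedule and event timeline."""

    agent: str = "rest"
    dose_scale: float = 1.0
    timeline: dict = field(default_factory=lambda: {
        "stream_start": 0.0, "window_init": 4.0, "decode_start": 34.0,
        "infusion_start": 94.0, "end": 214.0,
    })
    onset_lag: float = 15.0     # s before features deviate from baseline
    ramp_width: float = 10.0    # s, logistic 5%-95% width of the onset ramp
    infusion_end: float | None = None   # defaults to timeline end

    def __post_init__(self):
        base = self.agent[2:] if self.agent.startswith("H-") else self.agent
        if base not in AGENTS:
            raise ValueError(f"unknown agent {self.agent!r}")
        if self.agent.startswith("H-"):
            # the H- prefix is shorthand for the 5x dose variant
            self.dose_scale = self.dose_scale * HIGH_DOSE_SCALE
            self.agent = base
            object.__setattr__(self, "_high_dose", True)
        order = ["stream_start", "window_init", "decode_start", "infusion_start", "end"]
        times = [self.timeline[k] for k in order]
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times must be strictly increasing: {times}")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be > 0")
        if self.onset_lag < 0:
            raise ValueError("onset_lag must be >= 0")
        if self.infusion_end is None:
            self.infusion_end = self.timeline["end"]

    @property
    def label_change(self) -> float:
        return self.timeline["infusion_start"] + self.onset_lag

    @property
    def is_high_dose(self) -> bool:
        return getattr(self, "_high_dose", False) or self.dose_scale >= HIGH_DOSE_SCALE - 1e-9

    @property
    def state_name(self) -> str:
        if self.agent == "rest":
            return "rest"
        return ("H-" + self.agent) if self.is_high_dose else self.agent

    def ramp(self, t: np.ndarray) -> np.ndarray:
        """Fraction of the full infusion effect present at time ``t``.

        Logistic onset centered onset_lag after infusion start (scale =
        width/4); a matching offset ramp follows the infusion end when the
        infusion stops before the recording does."""
        if self.agent == "rest":
            return np.zeros_like(np.asarray(t, dtype=float))
        s = self.ramp_width / 4.0
        c_on = self.timeline["infusion_start"] + self.onset_lag
        up = 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - c_on) / s))
        if self.infusion_end < self.timeline["end"]:
            c_off = self.infusion_end + self.onset_lag
            up = up - 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - c_off) / s))
        return up


@dataclass
class SubjectParams:
    """One animal's resting physiology, morphology, and noise scales."""

    resting_hr: float = 380.0           # bpm
    resting_sys: float = 125.0          # mmHg
    resting_dia: float = 85.0           # mmHg
    resting_breath: float = 75.0        # brpm
    qrs_ms: float = 16.0                # resting QRS (Q-to-S) duration
    rt_ms: float = 45.0                 # resting R-to-T duration
    amp_p: float = 0.10                 # mV
    amp_ta: float = -0.06               # mV
    amp_r: float = 0.80                 # mV
    amp_s: float = -0.15                # mV (resting ST epoch level)
    st_slope: float = 9.5               # mV/s resting (T-S)/(tT-tS)
    resp_mod: float = 0.06              # fractional aBP amplitude modulation
    dose_d50: float = np.inf            # Emax half-saturation (dose_scale
                                        # units); the default is linear
                                        # scaling, so the 5x dose drives 5x
                                        # the standard-dose response
    effect_fluct_sd: float = 0.2        # SD of the log of the systemic
                                        # effect-level fluctuation
    effect_fluct_tau: float = 25.0      # s; drug-level/baroreflex kinetics
    effect_scale: dict = field(default_factory=dict)   # per-agent multiplier
    effect_table: dict = field(default_factory=default_effect_table)
    noise_scales: dict = field(default_factory=lambda: {
        # per-beat additive noise SD, unit of each feature
        "f1": 0.004, "f2": 6.0, "f3": 0.4, "f4": 1.0, "f6": 0.003,
        "f7": 0.02, "f8": 0.25, "f9": 2.5, "f10": 3.0, "f13": 0.0,
    })
    drift_scales: dict = field(default_factory=lambda: {
        # stationary SD of the Ornstein-Uhlenbeck background fluctuation
        # (Mayer-wave / respiratory-coupled autonomic variability)
        "f1": 0.003, "f2": 4.0, "f3": 0.2, "f4": 0.6, "f6": 0.002,
        "f7": 0.01, "f8": 0.2, "f9": 2.0, "f10": 2.5, "f13": 2.0,
    })
    drift_tau: float = 4.0              # s; fast relative to the 30 s background
    ecg_noise_mv: float = 0.005         # white measurement noise on ECG
    abp_noise_mmhg: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not (250.0 <= self.resting_hr <= 500.0):
            raise ValueError("resting HR must be in [250, 500] bpm")
        if self.resting_sys <= self.resting_dia:
            raise ValueError("systolic must exceed diastolic")
        if any(v < 0 for v in self.noise_scales.values()):
            raise ValueError("noise scales must be >= 0")

    def noiseless(self) -> "SubjectParams":
        """Copy with every noise source zeroed (exact closure testing)."""
        return replace(
            self,
            noise_scales={k: 0.0 for k in self.noise_scales},
            drift_scales={k: 0.0 for k in self.drift_scales},
            ecg_noise_mv=0.0, abp_noise_mmhg=0.0, effect_fluct_sd=0.0,
        )

    def baseline_values(self) -> dict:
        f5 = self.rt_ms - self.qrs_ms / 2.0
        return {
            "f1": self.amp_s, "f2": self.resting_hr, "f3": self.qrs_ms,
            "f4": self.rt_ms, "f6": self.amp_ta, "f7": self.amp_r,
            "f8": self.st_slope, "f9": self.resting_dia,
            "f10": self.resting_sys, "f13": self.resting_breath,
            "_f5": f5,
        }


@dataclass
class PlantConfig:
    """Vagus-nerve-stimulation response plant.

    ``reversal_gain`` maps each generative feature to the fraction of the
    infusion-induced deviation removed while stimulation is ON; the
    deviation relaxes with first-order kinetics (``tau`` seconds).  With the
    vagus cut (``vagus_intact=False``) the gains are forced to zero and
    stimulation has no physiological effect.
    """

    vagus_intact: bool = True
    reversal_gain: dict = field(default_factory=lambda: {f: 0.85 for f in PRIMARY_FEATURES})
    tau: float = 5.0

    def __post_init__(self):
        if any(not (0.0 <= g <= 1.0) for g in self.reversal_gain.values()):
            raise ValueError("reversal gains must lie in [0, 1]")
        if not self.vagus_intact:
            self.reversal_gain = {f: 0.0 for f in self.reversal_gain}

    def gains(self) -> dict:
        if not self.vagus_intact:
            return {f: 0.0 for f in PRIMARY_FEATURES}
        return {f: self.reversal_gain.get(f, 0.0) for f in PRIMARY_FEATURES}


@dataclass
class WaveformRecord:
    """A simulated recording with its exact ground truth."""

    ecg: np.ndarray                  # mV at fs
    abp: np.ndarray                  # mmHg at fs
    fs: float
    protocol: InfusionProtocol
    subject: SubjectParams
    truth_beats: dict                # per-beat fiducial times/levels
    truth_pulses: dict               # per-pulse sys/dia times/pressures
    truth_breaths: np.ndarray        # inhalation peak times
    truth_series: dict               # generative feature series on step grid
    truth_frame: FeatureFrame        # window-averaged ground-truth features
    stim_log: list = field(default_factory=list)   # [(t_on, t_off), ...]
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.ecg.size / self.fs

    @property
    def labels(self) -> np.ndarray:
        return self.truth_frame.labels


# ---------------------------------------------------------------------------
# generative series
# ---------------------------------------------------------------------------

def _ou_series(rng, n, dt, tau, sd):
    """Stationary Ornstein-Uhlenbeck path, mean 0, SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    return x


def _dose_response(dose: float, d50: float) -> float:
    """Saturating (Emax) dose-response, normalized so the standard dose
    (dose_scale 1) yields the effect table exactly."""
    return dose * (1.0 + 1.0 / d50) / (1.0 + dose / d50)


def _effect_deltas(subject: SubjectParams, protocol: InfusionProtocol) -> dict:
    if protocol.agent == "rest":
        return {f: 0.0 for f in PRIMARY_FEATURES}
    table = subject.effect_table[protocol.agent]
    mult = subject.effect_scale.get(protocol.agent, 1.0)
    sat = _dose_response(protocol.dose_scale, subject.dose_d50)
    return {f: table[f] * sat * mult for f in PRIMARY_FEATURES}


def _clip(feature: str, values):
    """Soft physiologic saturation toward the feature's bounds.

    Identity over the interior of the range; within the outer 15 % margin
    the response compresses smoothly (tanh) toward the bound, the way
    pressor and chronotropic responses approach their physiologic ceilings.
    Strictly increasing, so orderings (dose monotonicity, between-state
    differences) survive even deep into saturation, unlike a hard clip.
    """
    lo, hi = _CLIP[feature]
    w = 0.15 * (hi - lo)
    v = np.asarray(values, dtype=float)
    upper = hi - w
    lower = lo + w
    out = np.where(v > upper, upper + w * np.tanh((v - upper) / w), v)
    out = np.where(v < lower, lower - w * np.tanh((lower - v) / w), out)
    return out if out.ndim else float(out)


def _generative_series(protocol, subject, plant, controller_hook, rng):
    """Per-100 ms generative values of the primary features.

    Runs causally so a controller hook can switch stimulation ON mid-
    stream: at each step the hook sees the current instantaneous feature
    vector (13 elements, derived features included) and returns the desired
    stimulation state.  Returns (series dict, stim intervals).
    """
    t_grid = step_grid(0.0, protocol.timeline["end"])
    n = t_grid.size
    base = subject.baseline_values()
    deltas = _effect_deltas(subject, protocol)
    ramp = protocol.ramp(t_grid)
    drift = {f: _ou_series(rng, n, STEP, subject.drift_tau, subject.drift_scales.get(f, 0.0))
             for f in PRIMARY_FEATURES}
    # one systemic effect-level fluctuation (drug level / reflex escape)
    # moves all features along the agent's response direction together
    fluct = np.exp(_ou_series(rng, n, STEP, subject.effect_fluct_tau,
                              subject.effect_fluct_sd))
    gains = plant.gains()

    series = {f: np.empty(n) for f in PRIMARY_FEATURES}
    stim_state = np.zeros(n, dtype=bool)
    r = {f: 1.0 for f in PRIMARY_FEATURES}    # plant relaxation factor
    stim_on = False
    intervals: list[list[float]] = []
    for i, t in enumerate(t_grid):
        for f in PRIMARY_FEATURES:
            target = (1.0 - gains[f]) if stim_on else 1.0
            r[f] += (STEP / plant.tau) * (target - r[f])
            series[f][i] = float(
                _clip(f, base[f] + deltas[f] * ramp[i] * fluct[i] * r[f]
                      + drift[f][i]))
        stim_state[i] = stim_on
        if controller_hook is not None:
            vec = _instantaneous_vector(series, i)
            try:
                want = bool(controller_hook(i, t, vec))
            except Exception as exc:   # abort with context per contract
                raise RuntimeError(
                    f"controller hook failed at step {i} (t={t:.1f} s)") from exc
            if want and not stim_on:
                intervals.append([t, t_grid[-1]])
            elif not want and stim_on:
                intervals[-1][1] = t
            stim_on = want
    return t_grid, series, stim_state, [tuple(iv) for iv in intervals]


def _instantaneous_vector(series: dict, i: int) -> np.ndarray:
    v = np.empty(13)
    f9, f10 = series["f9"][i], series["f10"][i]
    v[0] = series["f1"][i]; v[1] = series["f2"][i]
    v[2] = series["f3"][i]; v[3] = series["f4"][i]
    v[4] = series["f4"][i] - series["f3"][i] / 2.0
    v[5] = series["f6"][i]; v[6] = series["f7"][i]
    v[7] = series["f8"][i]
    v[8] = f9; v[9] = max(f10, f9 + 10.0)
    v[10] = (v[9] + v[8]) / 2.0; v[11] = v[9] - v[8]
    v[12] = series["f13"][i]
    return v


# ---------------------------------------------------------------------------
# beat table and waveform rendering
# ---------------------------------------------------------------------------

def _beat_table(t_grid, series, subject, rng, t_end):
    """Integrate the heart-rate series into a per-beat parameter table."""
    ns = subject.noise_scales

    def interp(f, t):
        return float(np.interp(t, t_grid, series[f]))

    beats = []
    t = 0.05
    while True:
        hr = interp("f2", t) + rng.normal(0.0, ns.get("f2", 0.0))
        hr = float(_clip("f2", hr))
        rr = 60.0 / hr
        if t + rr > t_end - 0.05:
            break
        f9 = _clip("f9", interp("f9", t) + rng.normal(0.0, ns.get("f9", 0.0)))
        f10 = _clip("f10", interp("f10", t) + rng.normal(0.0, ns.get("f10", 0.0)))
        f10 = max(f10, f9 + 10.0)
        # keep the T wave inside the beat: RT must end before the TP interval
        f4 = _clip("f4", interp("f4", t) + rng.normal(0.0, ns.get("f4", 0.0)))
        f4 = float(np.clip(f4, 0.15 * rr * 1e3, 0.32 * rr * 1e3))
        beat = {
            "t": t, "rr": rr, "hr": hr,
            "f1": float(_clip("f1", interp("f1", t) + rng.normal(0.0, ns.get("f1", 0.0)))),
            "f3": float(_clip("f3", interp("f3", t) + rng.normal(0.0, ns.get("f3", 0.0)))),
            "f4": f4,
            "f6": float(_clip("f6", interp("f6", t) + rng.normal(0.0, ns.get("f6", 0.0)))),
            "f7": float(_clip("f7", interp("f7", t) + rng.normal(0.0, ns.get("f7", 0.0)))),
            "f8": float(_clip("f8", interp("f8", t) + rng.normal(0.0, ns.get("f8", 0.0)))),
            "f9": float(f9), "f10": float(f10),
            "p_amp": subject.amp_p, "q_amp": _Q_AMP_DEFAULT,
            "width_scale": 1.0, "suppress_p": False, "kind": "normal",
        }
        beats.append(beat)
        t += rr
    return beats


def _hann_lobe(signal_arr, fs, center, hw, amp):
    """Add a raised-cosine lobe of half-width ``hw`` seconds in place."""
    i0 = max(0, int(np.ceil((center - hw) * fs)))
    i1 = min(signal_arr.size, int(np.floor((center + hw) * fs)) + 1)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / fs
    signal_arr[i0:i1] += amp * 0.5 * (1.0 + np.cos(np.pi * (tt - center) / hw))


def _render_ecg(beats, n_samples, fs, rng, noise_sd):
    ecg = np.zeros(n_samples)
    for b in beats:
        rr, t0, w = b["rr"], b["t"], b["width_scale"]
        d3 = b["f3"] / 1e3
        d4 = b["f4"] / 1e3
        f5_s = d4 - d3 / 2.0
        t_level = b["f1"] + b["f8"] * f5_s

        def hw(name):
            return max(_WAVE_GEOM[name][1] * rr, _HW_FLOOR[name])

        if not b["suppress_p"]:
            _hann_lobe(ecg, fs, t0 + _WAVE_GEOM["p"][0] * rr, hw("p"), b["p_amp"])
            _hann_lobe(ecg, fs, t0 + _WAVE_GEOM["ta"][0] * rr, hw("ta"), b["f6"])
        _hann_lobe(ecg, fs, t0 - d3 / 2.0, hw("q") * w, b["q_amp"])
        _hann_lobe(ecg, fs, t0, hw("r") * w, b["f7"])
        _hann_lobe(ecg, fs, t0 + d3 / 2.0, hw("s") * w, b["f1"])
        _hann_lobe(ecg, fs, t0 + d4, hw("t"), t_level)
    if noise_sd > 0:
        ecg += rng.normal(0.0, noise_sd, size=n_samples)
    return ecg


def _resp_phase(t_grid, series, n_samples, fs):
    """Respiratory phase by integrating the breath-rate series."""
    tt = np.arange(n_samples) / fs
    rate_hz = np.interp(tt, t_grid, series["f13"]) / 60.0
    return np.cumsum(rate_hz) / fs, tt


def _render_abp(beats, t_grid, series, subject, n_samples, fs, rng):
    abp = np.zeros(n_samples)
    phase, tt = _resp_phase(t_grid, series, n_samples, fs)
    sys_truth, dia_truth, sys_times, dia_times = [], [], [], []
    for b in beats:
        foot = b["t"] + _PULSE_DELAY
        rr = b["rr"]
        i0 = int(np.ceil(foot * fs))
        i1 = min(n_samples, int(np.floor((foot + rr) * fs)) + 1)
        if i0 >= n_samples or i1 <= i0:
            continue
        amp_mod = 1.0 + subject.resp_mod * np.sin(
            2 * np.pi * float(np.interp(foot, tt, phase)))
        amp = (b["f10"] - b["f9"]) * amp_mod * b.get("pulse_scale", 1.0)
        phi = (np.arange(i0, i1) / fs - foot) / rr
        shape = np.where(
            phi < _PULSE_RISE,
            0.5 - 0.5 * np.cos(np.pi * phi / _PULSE_RISE),
            0.5 + 0.5 * np.cos(np.pi * (phi - _PULSE_RISE) / (1.0 - _PULSE_RISE)),
        )
        abp[i0:i1] = b["f9"] + amp * shape
        sys_truth.append(b["f9"] + amp)
        sys_times.append(foot + _PULSE_RISE * rr)
        dia_truth.append(b["f9"])
        dia_times.append(foot)
    if beats:
        abp[: int(np.ceil((beats[0]["t"] + _PULSE_DELAY) * fs))] = dia_truth[0] if dia_truth else 0.0
        last = int(np.floor((beats[-1]["t"] + _PULSE_DELAY + beats[-1]["rr"]) * fs))
        if last < n_samples:
            abp[last:] = abp[max(last - 1, 0)]
    if subject.abp_noise_mmhg > 0:
        abp += rng.normal(0.0, subject.abp_noise_mmhg, size=n_samples)
    pulses = {
        "sys_time": np.asarray(sys_times), "sys_p": np.asarray(sys_truth),
        "dia_time": np.asarray(dia_times), "dia_p": np.asarray(dia_truth),
    }
    breath_peaks = _breath_peak_times(phase, fs)
    return abp, pulses, breath_peaks


def _breath_peak_times(phase, fs):
    """Times where the respiratory modulation sin(2*pi*phase) peaks."""
    k_lo = int(np.ceil(phase[0] - 0.25))
    k_hi = int(np.floor(phase[-1] - 0.25))
    targets = np.arange(k_lo, k_hi + 1) + 0.25
    idx = np.searchsorted(phase, targets)
    return idx[(idx > 0) & (idx < phase.size)] / fs


# ---------------------------------------------------------------------------
# truth aggregation
# ---------------------------------------------------------------------------

def _truth_frame(beats, pulses, t_grid, series, protocol) -> FeatureFrame:
    """Window-average the exact per-beat truth onto the 100 ms grid using
    the same trailing-window aggregation as the extractor."""
    steps = step_grid(protocol.timeline["window_init"], protocol.timeline["end"])
    bt = np.array([b["t"] for b in beats])
    X = np.full((steps.size, 13), np.nan)

    def beat_vals(key):
        return np.array([b[key] for b in beats])

    f5 = beat_vals("f4") - beat_vals("f3") / 2.0
    per_beat = {
        0: beat_vals("f1"), 1: beat_vals("hr"), 2: beat_vals("f3"),
        3: beat_vals("f4"), 4: f5, 5: beat_vals("f6"), 6: beat_vals("f7"),
        7: beat_vals("f8"),
    }
    for col, vals in per_beat.items():
        X[:, col] = window_average(bt, vals, steps)
    dia = window_average(pulses["sys_time"], pulses["dia_p"], steps)
    sys_ = window_average(pulses["sys_time"], pulses["sys_p"], steps)
    X[:, 8] = dia
    X[:, 9] = sys_
    X[:, 10] = (sys_ + dia) / 2.0
    X[:, 11] = sys_ - dia
    X[:, 12] = window_average(
        t_grid, series["f13"], steps, width=WINDOW)
    missing = np.isnan(X).any(axis=1)
    return FeatureFrame(
        step_times=steps, X=X, labels=_labels_for_steps(steps, protocol),
        missing=missing,
        meta={"timeline": dict(protocol.timeline), "truth": True},
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_recording(protocol: InfusionProtocol, subject: SubjectParams,
                       plant: PlantConfig | None = None,
                       controller_hook=None, fs: float = 10_000.0) -> WaveformRecord:
    """Simulate one recording under the given protocol and subject.

    ``controller_hook(step, t, feature_vec) -> bool`` (optional) is invoked
    once per 100 ms step with the instantaneous generative feature vector
    and may switch stimulation ON; the stimulation intervals it produces
    feed the plant causally and are returned in the record's ``stim_log``.
    All randomness derives from ``subject.seed``.
    """
    plant = plant or PlantConfig()
    rng_drift = np.random.default_rng(np.random.SeedSequence([int(subject.seed), 11]))
    rng_beats = np.random.default_rng(np.random.SeedSequence([int(subject.seed), 13]))
    rng_meas = np.random.default_rng(np.random.SeedSequence([int(subject.seed), 17]))

    t_grid, series, stim_state, intervals = _generative_series(
        protocol, subject, plant, controller_hook, rng_drift)
    t_end = protocol.timeline["end"]
    n_samples = int(round(t_end * fs))
    beats = _beat_table(t_grid, series, subject, rng_beats, t_end)
    ecg = _render_ecg(beats, n_samples, fs, rng_meas, subject.ecg_noise_mv)
    abp, pulses, breaths = _render_abp(beats, t_grid, series, subject, n_samples, fs, rng_meas)
    frame = _truth_frame(beats, pulses, t_grid, series, protocol)
    truth_beats = _beats_to_arrays(beats)
    return WaveformRecord(
        ecg=ecg, abp=abp, fs=fs, protocol=protocol, subject=subject,
        truth_beats=truth_beats, truth_pulses=pulses, truth_breaths=breaths,
        truth_series={"t": t_grid, **series, "stim": stim_state},
        truth_frame=frame, stim_log=list(intervals),
        meta={"seed": int(subject.seed), "state": protocol.state_name,
              "beat_list": beats},
    )


def _beats_to_arrays(beats) -> dict:
    arr = {k: np.array([b[k] for b in beats]) for k in
           ("t", "rr", "hr", "f1", "f3", "f4", "f6", "f7", "f8", "f9", "f10")}
    arr["kind"] = np.array([b["kind"] for b in beats], dtype=object)
    # exact fiducial times/levels implied by the wave geometry
    arr["q_time"] = arr["t"] - arr["f3"] / 2e3
    arr["s_time"] = arr["t"] + arr["f3"] / 2e3
    arr["t_time"] = arr["t"] + arr["f4"] / 1e3
    arr["p_time"] = arr["t"] + _WAVE_GEOM["p"][0] * arr["rr"]
    arr["ta_time"] = arr["t"] + _WAVE_GEOM["ta"][0] * arr["rr"]
    arr["r_level"] = arr["f7"]
    arr["s_level"] = arr["f1"]
    arr["ta_level"] = arr["f6"]
    arr["p_level"] = np.array([b["p_amp"] for b in beats])
    arr["t_level"] = arr["f1"] + arr["f8"] * (arr["f4"] - arr["f3"] / 2.0) / 1e3
    arr["tp_level"] = np.zeros(len(beats))
    return arr


def inject_arrhythmia(record: WaveformRecord, kind: str, rate: float,
                      seed: int = 0) -> WaveformRecord:
    """Insert ectopic beats (VT runs, PACs, or PVCs) into a recording.

    ``rate`` is the expected event rate per minute (Poisson).  The beat
    table is edited (premature timing; widened QRS and suppressed P/Ta for
    ventricular ectopy; short rapid wide runs for VT) and both waveforms are
    re-rendered, so the truth annotations mark every arrhythmic beat and
    cohort arrhythmia incidence is computable without a detector.
    """
    if kind not in ("VT", "PAC", "PVC"):
        raise ValueError(f"unknown arrhythmia kind {kind!r}")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if "beat_list" not in record.meta:
        raise ValueError("record lacks a beat table (not produced by this module?)")
    if rate == 0:
        return record
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    beats = [dict(b) for b in record.meta["beat_list"]]
    duration = record.duration
    n_events = rng.poisson(rate * duration / 60.0)
    if n_events == 0:
        out = replace(record)
        out.meta = dict(record.meta)
        return out
    candidates = np.arange(2, len(beats) - 6)
    picks = np.sort(rng.choice(candidates, size=min(n_events, candidates.size), replace=False))
    for k in picks:
        if kind == "PVC":
            _make_ectopic(beats[k], beats[k - 1], frac=0.60, wide=2.5, suppress_p=True)
            beats[k]["kind"] = "PVC"
        elif kind == "PAC":
            _make_ectopic(beats[k], beats[k - 1], frac=0.70, wide=1.0, suppress_p=False)
            beats[k]["kind"] = "PAC"
        else:  # VT: a run of rapid wide beats
            run = int(rng.integers(4, 8))
            t_prev = beats[k - 1]["t"]
            rr_fast = beats[k]["rr"] * 0.55
            for j in range(k, min(k + run, len(beats) - 1)):
                beats[j]["t"] = t_prev + rr_fast
                beats[j]["rr"] = rr_fast
                beats[j]["hr"] = 60.0 / rr_fast
                beats[j]["width_scale"] = 2.0
                beats[j]["suppress_p"] = True
                beats[j]["pulse_scale"] = 0.5
                beats[j]["kind"] = "VT"
                t_prev = beats[j]["t"]
    beats.sort(key=lambda b: b["t"])
    rng_meas = np.random.default_rng(np.random.SeedSequence([int(record.subject.seed), 17]))
    n_samples = record.ecg.size
    t_grid = record.truth_series["t"]
    series = {f: record.truth_series[f] for f in PRIMARY_FEATURES}
    ecg = _render_ecg(beats, n_samples, record.fs, rng_meas, record.subject.ecg_noise_mv)
    abp, pulses, breaths = _render_abp(
        beats, t_grid, series, record.subject, n_samples, record.fs, rng_meas)
    frame = _truth_frame(beats, pulses, t_grid, series, record.protocol)
    out = replace(
        record, ecg=ecg, abp=abp, truth_beats=_beats_to_arrays(beats),
        truth_pulses=pulses, truth_breaths=breaths, truth_frame=frame)
    out.meta = {**record.meta, "beat_list": beats,
                "arrhythmia": {"kind": kind, "rate": rate, "n_events": int(picks.size)}}
    return out


def _make_ectopic(beat, prev, frac, wide, suppress_p):
    beat["t"] = prev["t"] + frac * prev["rr"]
    beat["rr"] = max(prev["rr"] * 0.8, 0.06)
    beat["hr"] = 60.0 / beat["rr"]
    beat["width_scale"] = wide
    beat["suppress_p"] = suppress_p
    if suppress_p:
        beat["f7"] = beat["f7"] * 0.8
        beat["pulse_scale"] = 0.5


def arrhythmia_incidence(records) -> float:
    """Fraction of recordings containing at least one arrhythmic beat."""
    hits = [np.any(r.truth_beats["kind"] != "normal") for r in records]
    return float(np.mean(hits)) if hits else 0.0


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def draw_subject(rng, seed: int, shared_overlap: float = 0.7,
                 effect_sd: float = 0.15, **overrides) -> SubjectParams:
    """Sample one animal from the population distributions.

    Per-agent effect-size multipliers are log-normal; the NE and D+NE
    multipliers share a latent component with weight ``shared_overlap`` so
    their infusion responses correlate within a subject (state overlap).
    """
    hr = float(np.clip(rng.normal(380.0, 25.0), 300.0, 460.0))
    sys_ = float(rng.normal(125.0, 8.0))
    pp = float(np.clip(rng.normal(40.0, 4.0), 25.0, 60.0))
    z_common, z_d, z_ne, z_dne = rng.normal(size=4)
    w = shared_overlap
    mults = {
        "D": float(np.exp(effect_sd * z_d)),
        "NE": float(np.exp(effect_sd * (w * z_common + np.sqrt(1 - w * w) * z_ne))),
        "D+NE": float(np.exp(effect_sd * (w * z_common + np.sqrt(1 - w * w) * z_dne))),
    }
    params = dict(
        resting_hr=hr, resting_sys=sys_, resting_dia=sys_ - pp,
        resting_breath=float(np.clip(rng.normal(75.0, 10.0), 50.0, 120.0)),
        qrs_ms=float(rng.normal(16.0, 1.0)),
        # RT tracks cycle length (ventricular repolarization shortens with rate)
        rt_ms=float(rng.normal(0.29, 0.013)) * 60_000.0 / hr,
        amp_p=float(rng.normal(0.10, 0.012)), amp_ta=float(rng.normal(-0.06, 0.008)),
        amp_r=float(rng.normal(0.80, 0.08)), amp_s=float(rng.normal(-0.15, 0.02)),
        st_slope=float(rng.normal(9.5, 0.8)),
        effect_scale=mults, seed=int(seed),
    )
    params.update(overrides)
    return SubjectParams(**params)


def generate_cohort(n_subjects: int, protocols, seed: int = 0,
                    shared_overlap: float = 0.7, plant: PlantConfig | None = None,
                    subject_overrides: dict | None = None) -> list[WaveformRecord]:
    """Per-subject replicate recordings under a list of protocols.

    ``protocols`` may hold agent names (str) or InfusionProtocol instances;
    each subject records every entry.  One master seed threads per-subject
    and per-record child seeds so any record reproduces in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocols = list(protocols)
    if not protocols:
        raise ValueError("empty protocol list")
    ss = np.random.SeedSequence(int(seed))
    subj_seeds = ss.generate_state(n_subjects * (len(protocols) + 1)).astype(np.int64)
    records = []
    k = 0
    for s in range(n_subjects):
        rng = np.random.default_rng(int(subj_seeds[k]) & 0x7FFFFFFF)
        k += 1
        base_subject = draw_subject(rng, seed=0, shared_overlap=shared_overlap,
                                    **(subject_overrides or {}))
        for p in protocols:
            proto = (InfusionProtocol(agent=p) if isinstance(p, str)
                     else replace(p))
            subject = replace(base_subject, seed=int(subj_seeds[k]) & 0x7FFFFFFF)
            k += 1
            rec = generate_recording(proto, subject, plant=plant)
            rec.meta["subject_id"] = s
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# I/O: two-column CSV per channel + JSON sidecar
# ---------------------------------------------------------------------------

def save_record(record: WaveformRecord, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tt = np.arange(record.ecg.size) / record.fs
    pd.DataFrame({"time_s": tt, "ecg_mv": record.ecg}).to_csv(out / "ecg.csv", index=False)
    pd.DataFrame({"time_s": tt, "abp_mmhg": record.abp}).to_csv(out / "abp.csv", index=False)
    record.truth_frame.to_csv(out / "truth_features.csv")
    sidecar = {
        "fs": record.fs,
        "protocol": {
            "agent": record.protocol.agent, "dose_scale": record.protocol.dose_scale,
            "timeline": record.protocol.timeline, "onset_lag": record.protocol.onset_lag,
        },
        "stim_log": [list(iv) for iv in record.stim_log],
        "state": record.meta.get("state"),
        "seed": record.meta.get("seed"),
        "truth_beats": {k: v.tolist() for k, v in record.truth_beats.items()},
    }
    (out / "record.json").write_text(json.dumps(sidecar))
    return out


@dataclass
class LoadedRecord:
    """Minimal record view reloaded from disk (extractor-compatible)."""
    ecg: np.ndarray
    abp: np.ndarray
    fs: float
    protocol: InfusionProtocol
    stim_log: list
    meta: dict


def load_record(rec_dir) -> LoadedRecord:
    rec_dir = Path(rec_dir)
    side = json.loads((rec_dir / "record.json").read_text())
    ecg = pd.read_csv(rec_dir / "ecg.csv")["ecg_mv"].to_numpy()
    abp = pd.read_csv(rec_dir / "abp.csv")["abp_mmhg"].to_numpy()
    proto = InfusionProtocol(
        agent=side["protocol"]["agent"], dose_scale=side["protocol"]["dose_scale"],
        timeline=side["protocol"]["timeline"], onset_lag=side["protocol"]["onset_lag"])
    return LoadedRecord(ecg=ecg, abp=abp, fs=side["fs"], protocol=proto,
                        stim_log=[tuple(iv) for iv in side["stim_log"]],
                        meta={"state": side.get("state"), "seed": side.get("seed")})
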