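"""Closed-loop and open-loop vagus-nerve-stimulation (VNS) policies.

The closed-loop rule is the deployed one: stimulation starts at the first
100 ms step whose decoder ischemia (D+NE) score exceeds 0.5 and stays ON
until the end of the recording (214 s).  The open-loop control delivers a
preprogrammed 20 % ON / 80 % OFF duty cycle over a ~500 s recording whose
infusion starts at a random time.  ``run_arm`` wires simulator, feature
extraction, decoder and policy into the three-arm experiment (ischemia
alone, + closed loop, + open loop, and the caudal-vagotomy control in which
the plant gains are zero and stimulation is physiologically inert).

Stimulation train bookkeeping follows the implant parameters: biphasic
square pulses, 2-2.5 mA, 300 us per phase, 30 Hz; the delivered-charge
estimate is 2 x amplitude x pulse width x frequency x ON time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import synth
from .features import (
    FeatureConfig, extract_features, baseline_normalize, derived_indices, STEP,
)
from .decode import StreamDecoder, CLASSES

__all__ = [
    "StimParams", "StimulationSchedule", "ARMS",
    "closed_loop_policy", "open_loop_policy", "ClosedLoopController",
    "run_recording_closed_loop", "run_arm",
]

ARMS = ("isch", "isch+ANN-VNS", "isch+OL-VNS", "isch+ANN-VNS+vagotomy")


@dataclass
class StimParams:
    """Stimulation train parameters of the cervical VNS cuff."""

    amplitude_ma: float = 2.5
    pulse_width_us: float = 300.0     # per phase
    frequency_hz: float = 30.0
    waveform: str = "biphasic_square"

    def __post_init__(self):
        if not (2.0 <= self.amplitude_ma <= 2.5):
            raise ValueError("amplitude must lie in [2, 2.5] mA")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")

    def charge_uc(self, on_time_s: float) -> float:
        """Delivered charge (uC): 2 phases x I x width x pulses."""
        pulses = self.frequency_hz * on_time_s
        return 2.0 * self.amplitude_ma * self.pulse_width_us * 1e-3 * pulses


@dataclass
class StimulationSchedule:
    """Non-overlapping ON intervals with totals and charge bookkeeping."""

    intervals: list                   # [(t_on, t_off), ...] seconds
    mode: str                         # closed_loop | open_loop | none
    params: StimParams = field(default_factory=StimParams)
    trigger_latency: float | None = None   # s after physiological onset
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        iv = sorted((float(a), float(b)) for a, b in self.intervals)
        for (a0, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("ON intervals overlap")
        if any(b <= a for a, b in iv):
            raise ValueError("empty or inverted ON interval")
        self.intervals = iv

    @property
    def on_time(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    @property
    def charge_uc(self) -> float:
        return self.params.charge_uc(self.on_time)

    def is_on(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            on |= (t >= a) & (t < b)
        return on

    def to_dict(self) -> dict:
        return {"intervals": [list(iv) for iv in self.intervals],
                "mode": self.mode, "on_time": self.on_time,
                "charge_uc": self.charge_uc,
                "trigger_latency": self.trigger_latency,
                "params": {"amplitude_ma": self.params.amplitude_ma,
                           "pulse_width_us": self.params.pulse_width_us,
                           "frequency_hz": self.params.frequency_hz}}


def closed_loop_policy(step_times, ischemia_scores, end_time: float,
                       protocol: synth.InfusionProtocol | None = None,
                       threshold: float = 0.5, debounce_steps: int = 1,
                       params: StimParams | None = None) -> StimulationSchedule:
    """Trigger rule on a completed score stream.

    The first step whose ischemia score exceeds ``threshold`` (for
    ``debounce_steps`` consecutive steps; 1 = the literal single-step rule)
    opens one ON interval lasting until ``end_time``.  No trigger -> empty
    schedule.  Latency is reported relative to the physiological onset
    (infusion start + onset lag) when the protocol is given.
    """
    step_times = np.asarray(step_times, dtype=float)
    scores = np.asarray(ischemia_scores, dtype=float)
    above = scores > threshold
    trigger = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= debounce_steps:
            trigger = step_times[i]
            break
    if trigger is None or trigger >= end_time:
        return StimulationSchedule([], "closed_loop", params or StimParams())
    latency = None
    if protocol is not None and protocol.agent != "rest":
        latency = float(trigger - protocol.label_change)
    return StimulationSchedule([(float(trigger), float(end_time))], "closed_loop",
                               params or StimParams(), trigger_latency=latency)


def open_loop_policy(recording_length: float = 500.0, duty: float = 0.2,
                     period: float = 60.0, params: StimParams | None = None,
                     infusion_start: float | None = None,
                     infusion_duration: float = 120.0) -> StimulationSchedule:
    """Preprogrammed periodic duty-cycle schedule, independent of any score.

    ``period`` defaults to 60 s (12 s ON / 48 s OFF at 20 % duty).  When the
    (randomized) infusion window is given, the fraction of it covered by ON
    time is reported in ``meta`` -- its expectation over a uniform onset
    equals the duty cycle.
    """
    if not (0.0 < duty < 1.0):
        raise ValueError("duty must lie in (0, 1)")
    on_len = duty * period
    budget = duty * recording_length      # total ON time the duty implies
    intervals = []
    for s in np.arange(0.0, recording_length, period):
        length = min(on_len, recording_length - s, budget)
        if length <= 0:
            break
        intervals.append((float(s), float(s + length)))
        budget -= length
    sched = StimulationSchedule(intervals, "open_loop", params or StimParams())
    if infusion_start is not None:
        t = np.arange(infusion_start, min(infusion_start + infusion_duration,
                                          recording_length), STEP)
        sched.meta["infusion_on_fraction"] = float(np.mean(sched.is_on(t)))
        sched.meta["infusion_start"] = float(infusion_start)
    return sched


class ClosedLoopController:
    """Streaming controller: standardize -> decode -> trigger, causally.

    Hooked into the simulator's per-step callback.  It accumulates the raw
    feature stream, freezes baseline statistics at decode start (30 s of
    background), then feeds standardized steps through the decoder and
    latches stimulation ON at the first ischemia score above threshold.
    """

    def __init__(self, model, protocol: synth.InfusionProtocol,
                 threshold: float = 0.5, window_steps: int = 40,
                 sd_floor_rel: float = 1e-6, sd_floor_abs: float = 1e-9):
        self.decoder = StreamDecoder(model)
        self.protocol = protocol
        self.threshold = threshold
        self.window_steps = window_steps
        self._sd_floor = (sd_floor_rel, sd_floor_abs)
        self._buffer: list[np.ndarray] = []
        self._windowed: list[np.ndarray] = []
        self._baseline: tuple[np.ndarray, np.ndarray] | None = None
        self.trigger_time: float | None = None
        self.scores: list[float] = []

    def __call__(self, step: int, t: float, vec: np.ndarray) -> bool:
        tl = self.protocol.timeline
        self._buffer.append(np.asarray(vec, dtype=float))
        # trailing 4 s window average, the same smoothing the extractor applies
        self._windowed.append(
            np.mean(self._buffer[-self.window_steps:], axis=0))
        if t < tl["decode_start"]:
            return False
        if self._baseline is None:
            # baseline statistics over the windowed background stream,
            # mirroring the offline standardization
            lo = int(round(tl["window_init"] / STEP))
            bg = np.asarray(self._windowed[lo:])
            mean = bg.mean(axis=0)
            sd = bg.std(axis=0)
            sd = np.maximum(sd, self._sd_floor[0] * np.abs(mean) + self._sd_floor[1])
            res = np.asarray(FeatureConfig().sd_resolution)
            if res.size == sd.size:
                sd = np.maximum(sd, res)
            self._baseline = (mean, sd)
        mean, sd = self._baseline
        z = (self._windowed[-1] - mean) / sd
        out = self.decoder.step(z)
        self.scores.append(out["ischemia_score"])
        if self.trigger_time is None and out["ischemia_score"] > self.threshold:
            self.trigger_time = t
        return self.trigger_time is not None


def run_recording_closed_loop(model, protocol, subject, plant,
                              threshold: float = 0.5,
                              params: StimParams | None = None):
    """Simulate one recording under live decoder-triggered stimulation.

    Returns (record, schedule); the schedule mirrors the simulator's stim
    log with trigger latency filled in.
    """
    controller = ClosedLoopController(model, protocol, threshold=threshold)
    record = synth.generate_recording(protocol, subject, plant=plant,
                                      controller_hook=controller)
    if record.stim_log:
        latency = None
        if protocol.agent != "rest":
            latency = float(record.stim_log[0][0] - protocol.label_change)
        sched = StimulationSchedule(record.stim_log, "closed_loop",
                                    params or StimParams(), trigger_latency=latency)
    else:
        sched = StimulationSchedule([], "closed_loop", params or StimParams())
    return record, sched


def _delta_outcomes(record, schedule: StimulationSchedule | None):
    """Per-feature Delta outcomes: average of the baseline-subtracted
    feature during VNS ON (or during the infusion when no VNS), exactly the
    windows used for the in-vivo arm comparison."""
    frame = extract_features(record)
    delta, _ = baseline_normalize(frame)
    idx = derived_indices(frame)
    proto = record.protocol
    if schedule is not None and schedule.on_time > 0:
        mask = schedule.is_on(frame.step_times)
    else:
        mask = frame.step_times >= proto.label_change
    mask &= ~frame.missing
    out = {f"f{i+1}": float(np.nanmean(delta[mask, i])) for i in range(13)}
    base = frame.step_times < proto.timeline["decode_start"]
    out["rpp"] = float(np.nanmean(idx.rpp[mask]) - np.nanmean(idx.rpp[base]))
    out["qtc"] = float(np.nanmean(idx.qtc[mask]) - np.nanmean(idx.qtc[base]))
    out["qt_tq"] = float(np.nanmean(idx.qt_tq[mask]) - np.nanmean(idx.qt_tq[base]))
    return out


def run_arm(arm: str, model=None, n_runs: int = 3, seed: int = 0,
            reversal_gain: float | dict = 0.85, threshold: float = 0.5,
            open_loop_duty: float = 0.2, open_loop_period: float = 60.0,
            params: StimParams | None = None,
            subject_overrides: dict | None = None) -> dict:
    """Run one experimental arm end to end on D+NE ischemia recordings.

    Returns a dict with per-run Delta outcome tables (feature deltas
    measured while VNS is ON, or during the infusion for the no-VNS arm),
    ON times and charge, and trigger latencies for the closed-loop arms.
    A decoder ``model`` is required for the closed-loop arms.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; choose from {ARMS}")
    if arm in ("isch+ANN-VNS", "isch+ANN-VNS+vagotomy") and model is None:
        raise ValueError(f"arm {arm!r} needs a trained decoder model")
    params = params or StimParams()
    if isinstance(reversal_gain, dict):
        gains = reversal_gain
    else:
        gains = {f: float(reversal_gain) for f in synth.PRIMARY_FEATURES}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    outcomes, schedules = [], []
    for run in range(n_runs):
        subj_seed = int(rng.integers(0, 2**31 - 1))
        subject = synth.draw_subject(rng, seed=subj_seed,
                                     **(subject_overrides or {}))
        if arm == "isch+OL-VNS":
            # ~500 s recording, infusion at a randomized time
            inf_start = float(rng.uniform(100.0, 340.0))
            protocol = synth.InfusionProtocol(
                agent="D+NE",
                timeline={"stream_start": 0.0, "window_init": 4.0,
                          "decode_start": 34.0, "infusion_start": inf_start,
                          "end": 500.0},
                infusion_end=inf_start + 120.0)
            sched = open_loop_policy(500.0, duty=open_loop_duty,
                                     period=open_loop_period, params=params,
                                     infusion_start=inf_start)
            plant = synth.PlantConfig(vagus_intact=True, reversal_gain=gains)
            on = sched.is_on(np.round(np.arange(0, 500.0, STEP), 6))

            def hook(step, t, vec, _on=on):
                return bool(_on[min(step, _on.size - 1)])

            record = synth.generate_recording(protocol, subject, plant=plant,
                                              controller_hook=hook)
        else:
            protocol = synth.InfusionProtocol(agent="D+NE")
            intact = arm != "isch+ANN-VNS+vagotomy"
            plant = synth.PlantConfig(vagus_intact=intact, reversal_gain=dict(gains))
            if arm == "isch":
                record = synth.generate_recording(protocol, subject, plant=plant)
                sched = StimulationSchedule([], "none", params)
            else:
                record, sched = run_recording_closed_loop(
                    model, protocol, subject, plant, threshold=threshold,
                    params=params)
        outcomes.append(_delta_outcomes(record, sched if sched.on_time > 0 else None))
        schedules.append(sched)
    return {
        "arm": arm,
        "outcomes": outcomes,
        "schedules": schedules,
        "on_times": [s.on_time for s in schedules],
        "charges_uc": [s.charge_uc for s in schedules],
        "trigger_latencies": [s.trigger_latency for s in schedules],
    }
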