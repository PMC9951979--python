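"""Synthetic paired EMG/IMU walking recordings with known ground truth.

Real recordings of this kind are clinical data and not redistributable, so
every pipeline stage is exercised on simulated cohorts whose gait events and
EMG→angular-velocity relationship are known by construction.

Angular velocity
    Each leg's shank angular velocity is a piecewise-cosine curve through
    per-cycle control points: the swing peak (SWP, > 150 deg/s) at each cycle
    boundary, a heel-contact trough planted exactly at ``hc_phase`` of the
    cycle, a small mid-stance local maximum, and a toe-off trough exactly at
    ``to_phase``.  Segments are strictly monotone half-cosines, so the
    analytic extrema — and hence the planted events — are exact, and the
    curve is continuously differentiable.  Cycle durations are the nominal
    duration plus i.i.d. Gaussian jitter; the right leg runs half a cycle out
    of phase with the left.

EMG
    Each muscle produces an activation envelope that is either (a) a train of
    raised-cosine bursts phase-locked to its own leg's cycles at a
    muscle-specific phase (vastus lateralis near heel contact, tibialis
    anterior during swing, the plantar flexors during stance), or (b) with
    ``linear_ground_truth`` enabled, an exact affine function of the leg's
    angular velocity delayed by a muscle-specific on-grid lag — which makes
    the decoding problem exactly linear and enables machine-precision
    recovery tests.  The envelope amplitude-modulates a carrier: broadband
    Gaussian noise by default (mirroring surface-EMG statistics at the
    fidelity the pipeline needs), or a deterministic 100 Hz tone in linear
    mode, whose rectification is exact on the decimated 200 Hz grid.

Across-patient variability is applied to EMG gains, burst phases, the
nominal cycle duration and the angular-velocity amplitude, making
leave-one-patient-out validation non-trivial.  All randomness flows through
one seeded generator; identical seed and config give bit-identical output
files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import (GaitEvent, ParameterError, Recording, SignalChannel,
                   write_events, write_recording)
from .regression import MUSCLES

logger = logging.getLogger("emg2gait")


@dataclass(frozen=True)
class GaitTemplate:
    """Shape parameters of one angular-velocity gait cycle.

    Phases are fractions of the cycle; the heel-contact trough must lie in
    the (0.10, 0.45) detection window and the toe-off trough in (0.55, 0.90).
    ``trough_depths`` are positive depths in deg/s for (HC, TO).
    """

    cycle_duration_ms: float = 1100.0
    swp_amplitude: float = 250.0
    hc_phase: float = 0.20
    to_phase: float = 0.80
    trough_depths: tuple[float, float] = (60.0, 80.0)
    mid_phase: float = 0.50
    mid_value: float = -10.0
    rest_value: float = -30.0

    def __post_init__(self) -> None:
        if not self.swp_amplitude > 150:
            raise ParameterError("swing peak amplitude must exceed the "
                                 "150 deg/s detection threshold")
        if not 0.10 < self.hc_phase < 0.45:
            raise ParameterError("hc_phase must lie in (0.10, 0.45)")
        if not 0.55 < self.to_phase < 0.90:
            raise ParameterError("to_phase must lie in (0.55, 0.90)")
        if not self.hc_phase < self.mid_phase < self.to_phase:
            raise ParameterError("mid_phase must separate the two troughs")
        if not (self.trough_depths[0] > 0 and self.trough_depths[1] > 0):
            raise ParameterError("trough depths must be positive")


@dataclass(frozen=True)
class MuscleTemplate:
    """Phase-locked activation template of one muscle on one side.

    ``burst_phase``/``burst_width`` are fractions of the gait cycle;
    ``linear_lag_s`` is the delay of the envelope relative to the same leg's
    angular velocity used in linear-ground-truth mode (multiples of 50 ms
    keep it on the embedding grid).
    """

    muscle: str
    side: str
    burst_phase: float
    burst_width: float = 0.15
    gain: float = 1.0
    baseline: float = 0.05    # tonic activity between bursts
    linear_lag_s: float = 0.15

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ParameterError(f"unknown muscle {self.muscle!r}")
        if not 0 <= self.burst_phase < 1:
            raise ParameterError("burst_phase must lie in [0, 1)")
        if not self.gain >= 0:
            raise ParameterError("gain must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.side[0].upper()}{self.muscle}"


#: Paper-informed default activation timings: Vl bursts around heel contact,
#: Ta during swing (foot clearance), the plantar flexors S/Gm/Gl during
#: stance.  Linear-mode lags are distinct on-grid multiples of 50 ms, with
#: the Vl lag at +150 ms (the empirically dominant same-side delay).
_MUSCLE_DEFAULTS = {
    "Vl": dict(burst_phase=0.20, burst_width=0.12, linear_lag_s=0.15),
    "Ta": dict(burst_phase=0.88, burst_width=0.12, linear_lag_s=-0.10),
    "S": dict(burst_phase=0.40, burst_width=0.18, linear_lag_s=0.05),
    "Gm": dict(burst_phase=0.45, burst_width=0.18, linear_lag_s=0.10),
    "Gl": dict(burst_phase=0.50, burst_width=0.18, linear_lag_s=0.20),
}


def default_muscle_templates() -> list[MuscleTemplate]:
    """Bilateral default templates for all five muscles."""
    return [MuscleTemplate(muscle=m, side=side, **_MUSCLE_DEFAULTS[m])
            for m in MUSCLES for side in ("left", "right")]


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate the reference cohort's scale of gait statistics: six
    patients, nominal cycle durations drawn from 1010–1140 ms, cycle-duration
    jitter of 20 ms, and a few trials of a minute each per patient.
    ``linear_ground_truth`` switches the EMG envelopes to exact affine
    functions of the lagged angular velocity (with a deterministic tone
    carrier), the condition under which the decoder can recover the mapping
    essentially perfectly.
    """

    seed: int
    n_patients: int = 6
    trials_per_patient: int = 4
    trial_duration_s: float = 60.0
    cycle_jitter_ms: float = 20.0
    nominal_duration_range_ms: tuple[float, float] = (1010.0, 1140.0)
    patient_gain_range: tuple[float, float] = (0.7, 1.3)
    patient_amp_range: tuple[float, float] = (0.85, 1.15)
    patient_phase_jitter: float = 0.03
    emg_noise_sd: float = 0.05
    imu_noise_sd: float = 5.0
    linear_ground_truth: bool = False
    carrier: str = "auto"   # "auto" | "noise" | "tone"
    fs_emg: float = 1000.0
    fs_imu: float = 128.0
    walk_start_s: float = 1.0
    ttl_onset_emg_s: float = 0.8
    ttl_onset_imu_s: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_patients", "trials_per_patient", "trial_duration_s"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("cycle_jitter_ms", "emg_noise_sd", "imu_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.carrier not in ("auto", "noise", "tone"):
            raise ParameterError(f"unknown carrier {self.carrier!r}")

    @property
    def effective_carrier(self) -> str:
        if self.carrier != "auto":
            return self.carrier
        return "tone" if self.linear_ground_truth else "noise"


class CycleTrainTrace:
    """Analytic angular-velocity trace: monotone half-cosine segments
    through per-cycle control points, constant-extended outside them."""

    def __init__(self, control_t: np.ndarray, control_v: np.ndarray,
                 cycle_starts: np.ndarray, durations_s: np.ndarray):
        self.control_t = np.asarray(control_t, float)
        self.control_v = np.asarray(control_v, float)
        self.cycle_starts = np.asarray(cycle_starts, float)
        self.durations_s = np.asarray(durations_s, float)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        ct, cv = self.control_t, self.control_v
        idx = np.clip(np.searchsorted(ct, t, side="right") - 1, 0, len(ct) - 2)
        t0, t1 = ct[idx], ct[idx + 1]
        v0, v1 = cv[idx], cv[idx + 1]
        u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))


def _build_cycle_train(tmpl: GaitTemplate, duration_s: float, rng,
                       cycle_jitter_ms: float, amplitude: float,
                       start_s: float) -> tuple[CycleTrainTrace, list[GaitEvent]]:
    nominal = tmpl.cycle_duration_ms / 1000.0
    starts = [start_s]
    durations = []
    while starts[-1] + nominal < duration_s - 0.3 * nominal:
        jitter = rng.normal(0.0, cycle_jitter_ms / 1000.0) if cycle_jitter_ms else 0.0
        dur = max(0.5 * nominal, nominal + jitter)
        durations.append(dur)
        starts.append(starts[-1] + dur)
    if len(durations) < 1:
        raise ParameterError("trial too short for a single gait cycle")
    starts = np.asarray(starts)
    durations = np.asarray(durations)

    peak = amplitude * tmpl.swp_amplitude
    d_hc = amplitude * tmpl.trough_depths[0]
    d_to = amplitude * tmpl.trough_depths[1]
    mid = amplitude * tmpl.mid_value
    rest = amplitude * tmpl.rest_value

    ct = [starts[0] - 0.30 * durations[0]]
    cv = [rest]
    for k, dur in enumerate(durations):
        s = starts[k]
        ct.extend([s, s + tmpl.hc_phase * dur, s + tmpl.mid_phase * dur,
                   s + tmpl.to_phase * dur])
        cv.extend([peak, -d_hc, mid, -d_to])
    ct.append(starts[-1])
    cv.append(peak)
    ct.append(starts[-1] + 0.30 * durations[-1])
    cv.append(rest)

    trace = CycleTrainTrace(np.asarray(ct), np.asarray(cv), starts, durations)
    events: list[GaitEvent] = []
    side = "left"  # relabelled by the caller
    for s in starts:
        events.append(GaitEvent(type="SWP", leg=side, time_s=float(s)))
    for k, dur in enumerate(durations):
        events.append(GaitEvent(type="HC", leg=side,
                                time_s=float(starts[k] + tmpl.hc_phase * dur)))
        events.append(GaitEvent(type="TO", leg=side,
                                time_s=float(starts[k] + tmpl.to_phase * dur)))
    return trace, sorted(events, key=lambda e: e.time_s)


def generate_cycle_train(tmpl: GaitTemplate, duration_s: float, rng,
                         fs: float = 200.0, cycle_jitter_ms: float = 0.0,
                         amplitude: float = 1.0, side: str = "left",
                         noise_sd: float = 0.0, start_s: float = 0.6,
                         ) -> tuple[SignalChannel, list[GaitEvent], CycleTrainTrace]:
    """Sample one leg's angular-velocity cycle train with planted events.

    Returns the sampled channel, the planted SWP/HC/TO events, and the
    analytic trace (for evaluating the same curve on other grids).
    """
    trace, events = _build_cycle_train(tmpl, duration_s, rng,
                                       cycle_jitter_ms, amplitude, start_s)
    t = np.arange(int(round(duration_s * fs))) / fs
    samples = trace(t)
    if noise_sd:
        samples = samples + noise_sd * rng.standard_normal(len(t))
    ch = SignalChannel(label=f"{side[0].upper()}_IMU", side=side,
                       kind="angular_velocity", fs=fs, samples=samples,
                       units="deg/s")
    events = [replace_leg(e, side) for e in events]
    return ch, events, trace


def replace_leg(event: GaitEvent, leg: str) -> GaitEvent:
    return GaitEvent(type=event.type, leg=leg, time_s=event.time_s)


def _burst_envelope(trace: CycleTrainTrace, tmpl: MuscleTemplate,
                    t: np.ndarray) -> np.ndarray:
    env = np.full(len(t), tmpl.baseline)
    for k, dur in enumerate(trace.durations_s):
        center = trace.cycle_starts[k] + tmpl.burst_phase * dur
        width = tmpl.burst_width * dur
        lo = np.searchsorted(t, center - width)
        hi = np.searchsorted(t, center + width)
        u = (t[lo:hi] - center) / width
        env[lo:hi] += tmpl.gain * 0.5 * (1.0 + np.cos(np.pi * u))
    return env


def _linear_envelope(trace: CycleTrainTrace, tmpl: MuscleTemplate,
                     t: np.ndarray, gait: GaitTemplate) -> np.ndarray:
    offset = max(gait.trough_depths) * 1.3 + 20.0
    scale = gait.swp_amplitude + offset
    return tmpl.gain * (trace(t - tmpl.linear_lag_s) + offset) / scale


def generate_emg(traces: dict[str, CycleTrainTrace],
                 templates: Sequence[MuscleTemplate],
                 cfg: SimulationConfig, rng,
                 duration_s: float,
                 gait: GaitTemplate | None = None) -> list[SignalChannel]:
    """Raw EMG channels at ``cfg.fs_emg`` from per-side analytic traces.

    Each muscle's envelope (burst train or exact linear map of the lagged
    angular velocity) amplitude-modulates the carrier; additive Gaussian
    sensor noise of ``cfg.emg_noise_sd`` is superimposed.
    """
    gait = gait or GaitTemplate()
    fs = cfg.fs_emg
    t = np.arange(int(round(duration_s * fs))) / fs
    channels = []
    for tmpl in templates:
        trace = traces[tmpl.side]
        if cfg.linear_ground_truth:
            env = _linear_envelope(trace, tmpl, t, gait)
        else:
            env = _burst_envelope(trace, tmpl, t)
        if cfg.effective_carrier == "tone":
            carrier = np.cos(2 * np.pi * 100.0 * t)
        else:
            carrier = rng.standard_normal(len(t))
        raw = env * carrier
        if cfg.emg_noise_sd:
            raw = raw + cfg.emg_noise_sd * rng.standard_normal(len(t))
        channels.append(SignalChannel(label=tmpl.label, side=tmpl.side,
                                      kind="emg", fs=fs, samples=raw,
                                      units="a.u."))
    return channels


@dataclass
class SyntheticTrial:
    recording: Recording              # raw, with per-stream TTL pre-padding
    truth_events: list[GaitEvent]     # on the walking-cropped timeline
    traces: dict[str, CycleTrainTrace] | None = None  # analytic, per side
    walk_start_s: float = 0.0         # crop offset of the truth timeline


def _generate_trial(cfg: SimulationConfig, gait: GaitTemplate,
                    templates: Sequence[MuscleTemplate],
                    patient_id: str, trial_id: str,
                    nominal_ms: float, amp: float, rng) -> SyntheticTrial:
    walk_start = cfg.walk_start_s
    walk_end = walk_start + cfg.trial_duration_s
    content_end = walk_end + 0.4          # aligned-timeline extent
    tmpl = replace(gait, cycle_duration_ms=nominal_ms)

    traces: dict[str, CycleTrainTrace] = {}
    events: list[GaitEvent] = []
    for side, phase0 in (("left", 0.0), ("right", 0.5)):
        start = walk_start + 0.35 + phase0 * nominal_ms / 1000.0
        trace, evs = _build_cycle_train(tmpl, content_end, rng,
                                        cfg.cycle_jitter_ms, amp, start)
        traces[side] = trace
        for e in evs:
            t_cropped = e.time_s - walk_start
            if 0.0 <= t_cropped <= cfg.trial_duration_s:
                events.append(GaitEvent(type=e.type, leg=side,
                                        time_s=t_cropped))

    channels: list[SignalChannel] = []
    # IMU stream: pre-TTL padding of cfg.ttl_onset_imu_s on its own clock.
    n_imu = int(round((content_end + cfg.ttl_onset_imu_s) * cfg.fs_imu))
    t_imu = np.arange(n_imu) / cfg.fs_imu - cfg.ttl_onset_imu_s
    for side in ("left", "right"):
        samples = traces[side](t_imu)
        if cfg.imu_noise_sd:
            samples = samples + cfg.imu_noise_sd * rng.standard_normal(n_imu)
        channels.append(SignalChannel(label=f"{side[0].upper()}_IMU",
                                      side=side, kind="angular_velocity",
                                      fs=cfg.fs_imu, samples=samples,
                                      units="deg/s"))
    # EMG stream: generated on the aligned timeline, then pre-padded.
    emg = generate_emg(traces, templates, cfg, rng, content_end, gait=tmpl)
    n_pad = int(round(cfg.ttl_onset_emg_s * cfg.fs_emg))
    for ch in emg:
        # pre-TTL samples carry only the sensor noise floor
        pad = cfg.emg_noise_sd * rng.standard_normal(n_pad)
        channels.append(ch.with_samples(np.concatenate([pad, ch.samples])))

    rec = Recording(
        patient_id=patient_id, trial_id=trial_id, channels=channels,
        ttl_onset_s={"emg": cfg.ttl_onset_emg_s, "imu": cfg.ttl_onset_imu_s},
        ttl_offset_s={"emg": cfg.ttl_onset_emg_s + content_end,
                      "imu": cfg.ttl_onset_imu_s + content_end},
        walk_start_s=walk_start, walk_end_s=walk_end)
    return SyntheticTrial(recording=rec, truth_events=sorted(
        events, key=lambda e: (e.time_s, e.type)),
        traces=traces, walk_start_s=walk_start)


def generate_cohort(cfg: SimulationConfig,
                    gait: GaitTemplate | None = None,
                    templates: Sequence[MuscleTemplate] | None = None,
                    out_dir: str | Path | None = None) -> list[SyntheticTrial]:
    """Generate a full synthetic cohort; optionally write it to disk.

    Patients differ in their nominal cycle duration, angular-velocity
    amplitude, per-muscle EMG gains and burst phases; all trials of a
    patient share these parameters.  With ``out_dir`` set, each trial is
    written as ``<pid>_<tid>.csv`` + ``.meta.yaml`` + ``.truth.events.csv``.
    """
    gait = gait or GaitTemplate()
    base_templates = list(templates) if templates is not None \
        else default_muscle_templates()
    rng = np.random.default_rng(cfg.seed)
    trials: list[SyntheticTrial] = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:02d}"
        nominal_ms = rng.uniform(*cfg.nominal_duration_range_ms)
        amp = rng.uniform(*cfg.patient_amp_range)
        patient_templates = []
        for tmpl in base_templates:
            gain = tmpl.gain * rng.uniform(*cfg.patient_gain_range)
            dphase = rng.uniform(-cfg.patient_phase_jitter,
                                 cfg.patient_phase_jitter)
            patient_templates.append(replace(
                tmpl, gain=gain,
                burst_phase=(tmpl.burst_phase + dphase) % 1.0))
        for tr in range(cfg.trials_per_patient):
            tid = f"T{tr + 1:02d}"
            trials.append(_generate_trial(cfg, gait, patient_templates,
                                          pid, tid, nominal_ms, amp, rng))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trial in trials:
            stem = f"{trial.recording.patient_id}_{trial.recording.trial_id}"
            write_recording(trial.recording, out / f"{stem}.csv",
                            out / f"{stem}.meta.yaml")
            write_events(trial.truth_events, out / f"{stem}.truth.events.csv")
    return trials
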