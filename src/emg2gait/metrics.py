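"""Performance analysis: correlation, event matching, error rates, phase F1.

Reconstructed angular-velocity traces are compared with the measured ones per
trial and leg using the Pearson correlation coefficient.  Gait events
extracted from both traces are matched one-to-one when less than 600 ms
apart; unmatched predictions are false detections, unmatched true events are
misses.  Per event type, the false discovery rate (FDR) is false detections
over total detections and the false-negative rate (FNR) is misses over total
true events.  Swing/stance phase segmentations derived from HC/TO events are
compared sample-wise with the F1-score (swing as the positive class).

The matching criterion alone does not determine an algorithm; here matching
is greedy by ascending |Δt| (one-to-one), which equals optimal assignment on
all small instances we test against brute force.  Displacements are signed
predicted − true (positive = late prediction); summaries use absolute values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import (DataError, Emg2GaitError, EVENT_TYPES, GaitEvent,
                   ParameterError, SignalChannel)
from .events import (CycleStats, EventExtractionConfig, PhaseSeries,
                     cycle_statistics, detect_hc_to, detect_swp,
                     events_to_phases)
from .regression import LagGrid

logger = logging.getLogger("emg2gait")


class UndefinedCorrelationError(Emg2GaitError):
    """Correlation of a constant or too-short signal is undefined."""


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_r(a: SignalChannel | np.ndarray,
              b: SignalChannel | np.ndarray) -> float:
    """Product-moment correlation over jointly valid (finite) samples."""
    xa = a.samples if isinstance(a, SignalChannel) else np.asarray(a, float)
    xb = b.samples if isinstance(b, SignalChannel) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise DataError("signals must share the same sample grid")
    mask = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[mask], xb[mask]
    if len(xa) < 2:
        raise UndefinedCorrelationError("need at least 2 jointly valid samples")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedCorrelationError("correlation of a constant signal")
    return float(sstats.pearsonr(xa, xb).statistic)


# ---------------------------------------------------------------------------
# Event matching
# ---------------------------------------------------------------------------

@dataclass
class EventMatchResult:
    """One-to-one matching between true and predicted events of one type."""

    matches: list[tuple[float, float, float]]  # (t_true, t_pred, disp_ms)
    misses: list[float]
    false_detections: list[float]
    max_match_distance_ms: float = 600.0

    @property
    def n_true(self) -> int:
        return len(self.matches) + len(self.misses)

    @property
    def n_pred(self) -> int:
        return len(self.matches) + len(self.false_detections)

    def displacements_ms(self, absolute: bool = True) -> np.ndarray:
        d = np.asarray([m[2] for m in self.matches])
        return np.abs(d) if absolute else d


def _event_times(events: Sequence[GaitEvent] | Sequence[float]) -> np.ndarray:
    if len(events) and isinstance(events[0], GaitEvent):
        types = {e.type for e in events}
        if len(types) > 1:
            raise ParameterError(f"mixed event types in one list: {sorted(types)}")
        return np.asarray(sorted(e.time_s for e in events))
    return np.asarray(sorted(float(t) for t in events))


def match_events(true: Sequence[GaitEvent] | Sequence[float],
                 pred: Sequence[GaitEvent] | Sequence[float],
                 max_ms: float = 600.0) -> EventMatchResult:
    """Greedy one-to-one matching of events less than ``max_ms`` apart.

    Candidate pairs are taken in ascending |Δt| order (ties broken by true
    then predicted index); each event participates in at most one match.
    """
    tt = _event_times(true)
    tp = _event_times(pred)
    if len(true) and len(pred) and isinstance(true[0], GaitEvent) \
            and isinstance(pred[0], GaitEvent) and true[0].type != pred[0].type:
        raise ParameterError("true and predicted event types differ")
    pairs = []
    for i, t in enumerate(tt):
        for j, p in enumerate(tp):
            d_ms = (p - t) * 1000.0
            if abs(d_ms) < max_ms:
                pairs.append((abs(d_ms), i, j, d_ms))
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for _, i, j, d_ms in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        matches.append((float(tt[i]), float(tp[j]), float(d_ms)))
    matches.sort()
    misses = [float(tt[i]) for i in range(len(tt)) if i not in used_t]
    false_det = [float(tp[j]) for j in range(len(tp)) if j not in used_p]
    return EventMatchResult(matches=matches, misses=misses,
                            false_detections=false_det,
                            max_match_distance_ms=max_ms)


def event_rates(match: EventMatchResult) -> tuple[float, float]:
    """(FDR, FNR).  A zero denominator yields NaN, not an exception."""
    fdr = len(match.false_detections) / match.n_pred if match.n_pred else math.nan
    fnr = len(match.misses) / match.n_true if match.n_true else math.nan
    return fdr, fnr


# ---------------------------------------------------------------------------
# Phase segmentation F1
# ---------------------------------------------------------------------------

def phase_f1_detail(true: PhaseSeries, pred: PhaseSeries) -> dict[str, float]:
    """Sample-wise F1 on the joint defined mask; swing is the positive class.

    Returns swing, stance and macro F1 (stance/macro reported for
    transparency).  An empty joint mask, or one with no swing in either
    series, leaves the respective score NaN.
    """
    if true.leg != pred.leg:
        raise ParameterError("phase series are for different legs")
    if true.fs != pred.fs or true.t0 != pred.t0:
        raise ParameterError("phase series are not on the same clock")
    n = min(len(true.labels), len(pred.labels))
    mask = true.defined[:n] & pred.defined[:n]
    if not mask.any():
        return {"f1_swing": math.nan, "f1_stance": math.nan,
                "f1_macro": math.nan, "n_samples": 0}
    a = true.labels[:n][mask]
    b = pred.labels[:n][mask]

    def f1(pos_a, pos_b):
        tp = int(np.sum(pos_a & pos_b))
        fp = int(np.sum(~pos_a & pos_b))
        fn = int(np.sum(pos_a & ~pos_b))
        if tp + fp + fn == 0:
            return math.nan
        return 2 * tp / (2 * tp + fp + fn)

    f_swing = f1(a, b)
    f_stance = f1(~a, ~b)
    macro = np.nanmean([f_swing, f_stance])
    return {"f1_swing": f_swing, "f1_stance": f_stance,
            "f1_macro": float(macro), "n_samples": int(mask.sum())}


def phase_f1(true: PhaseSeries, pred: PhaseSeries) -> float:
    """F1-score of the swing/stance segmentation (swing positive)."""
    return phase_f1_detail(true, pred)["f1_swing"]


# ---------------------------------------------------------------------------
# Cross-correlograms
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Lagged correlations of one EMG channel with one IMU trace.

    The lag convention matches the embedding: ``r[k]`` correlates
    ``emg(t + tau_k)`` with ``imu(t)``, so a *positive* peak lag means the
    EMG activity lags behind the IMU signal by that amount.
    """

    muscle: str
    target_side: str
    lags_ms: np.ndarray
    r_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_tests: int

    @property
    def peak_lag_ms(self) -> float:
        return float(self.lags_ms[int(np.argmax(np.abs(self.r_values)))])


def correlogram(emg: SignalChannel, imu: SignalChannel,
                grid: LagGrid | None = None,
                n_tests: int = 420) -> Correlogram:
    """Correlate temporally shifted EMG with the IMU trace at each grid lag.

    ``n_tests`` is the Bonferroni family size; the default 420 covers the
    full analysis of 10 muscles × 21 lags × 2 IMU sides.
    """
    grid = grid or LagGrid()
    if emg.fs != imu.fs:
        raise DataError("EMG and IMU must share the sampling rate")
    lags = grid.lags_samples(emg.fs)
    x, y = emg.samples, imu.samples
    T = min(len(x), len(y))
    rs, ps = [], []
    for lag in lags:
        a = max(0, -lag)
        b = min(T, T - lag)
        if b - a < 3:
            raise DataError("signals too short for the lag grid")
        res = sstats.pearsonr(x[a + lag:b + lag], y[a:b])
        rs.append(res.statistic)
        ps.append(res.pvalue)
    rs = np.asarray(rs)
    ps = np.asarray(ps)
    return Correlogram(muscle=emg.label, target_side=imu.side,
                       lags_ms=grid.taus_ms(), r_values=rs, p_values=ps,
                       significant=ps * n_tests < 0.05, n_tests=n_tests)


# ---------------------------------------------------------------------------
# Per-trial evaluation and aggregation
# ---------------------------------------------------------------------------

@dataclass
class TrialMetrics:
    """Per-trial, per-leg comparison of predicted vs measured traces."""

    patient_id: str
    trial_id: str
    leg: str
    pearson: float
    f1: float
    f1_detail: dict[str, float]
    per_type: dict[str, dict[str, float]]  # median/iqr displacement, fdr, fnr, counts
    cycle_stats: CycleStats | None

    def row(self) -> dict[str, float]:
        out = {"patient_id": self.patient_id, "trial_id": self.trial_id,
               "leg": self.leg, "pearson_r": self.pearson, "f1": self.f1}
        for etype, d in self.per_type.items():
            for key, val in d.items():
                out[f"{etype.lower()}_{key}"] = val
        return out


def _iqr(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return math.nan, math.nan
    return (float(np.percentile(values, 25)), float(np.percentile(values, 75)))


def evaluate_trial(true_av: SignalChannel, pred_av: SignalChannel,
                   cfg: EventExtractionConfig | None = None,
                   max_match_ms: float = 600.0,
                   patient_id: str = "", trial_id: str = "") -> TrialMetrics:
    """Full per-trial, per-leg evaluation of a reconstructed trace.

    Both traces are restricted to their jointly finite span (prediction
    margins at embedding boundaries are NaN); event extraction then runs
    identically on both.
    """
    cfg = cfg or EventExtractionConfig()
    if true_av.fs != pred_av.fs:
        raise DataError("traces must share the sampling rate")
    fs = true_av.fs
    n = min(true_av.n, pred_av.n)
    joint = np.isfinite(true_av.samples[:n]) & np.isfinite(pred_av.samples[:n])
    idx = np.nonzero(joint)[0]
    if len(idx) < 3:
        raise DataError("no jointly valid span to evaluate")
    i0, i1 = int(idx[0]), int(idx[-1]) + 1
    t_true = true_av.with_samples(true_av.samples[i0:i1])
    t_pred = pred_av.with_samples(pred_av.samples[i0:i1])

    r = pearson_r(t_true, t_pred)
    swp_t = detect_swp(t_true, cfg)
    swp_p = detect_swp(t_pred, cfg)
    ev_t = {"SWP": swp_t, "HC": [], "TO": []}
    ev_p = {"SWP": swp_p, "HC": [], "TO": []}
    for ev, swp, av in ((ev_t, swp_t, t_true), (ev_p, swp_p, t_pred)):
        for e in detect_hc_to(av, swp, cfg):
            ev[e.type].append(e)

    per_type = {}
    for etype in EVENT_TYPES:
        match = match_events(ev_t[etype], ev_p[etype], max_match_ms)
        fdr, fnr = event_rates(match)
        disp = match.displacements_ms(absolute=True)
        q1, q3 = _iqr(disp)
        per_type[etype] = {
            "median_abs_displacement_ms": float(np.median(disp)) if len(disp) else math.nan,
            "iqr_low_ms": q1, "iqr_high_ms": q3,
            "fdr": fdr, "fnr": fnr,
            "n_true": match.n_true, "n_pred": match.n_pred,
            "n_missed": len(match.misses),
            "n_false": len(match.false_detections),
        }

    span = (0.0, t_true.n / fs)
    phases_t = events_to_phases(ev_t["HC"] + ev_t["TO"], span, fs,
                                leg=true_av.side)
    phases_p = events_to_phases(ev_p["HC"] + ev_p["TO"], span, fs,
                                leg=true_av.side)
    detail = phase_f1_detail(phases_t, phases_p)

    stats = None
    if len(swp_t) >= 3:
        stats = cycle_statistics(swp_t)
    return TrialMetrics(patient_id=patient_id, trial_id=trial_id,
                        leg=true_av.side, pearson=r,
                        f1=detail["f1_swing"], f1_detail=detail,
                        per_type=per_type, cycle_stats=stats)


def aggregate(metrics: Sequence[TrialMetrics]) -> dict:
    """Summaries across trials: median (IQR) per metric, pooled error rates.

    Per-trial metrics (Pearson r, F1, median absolute displacement) are
    summarized by their median and 25th–75th percentile across trials.
    FDR/FNR are pooled from event counts across trials, not averaged rates.
    """
    if not metrics:
        raise ParameterError("aggregate needs at least one trial")
    frame = pd.DataFrame([m.row() for m in metrics])

    def med_iqr(col: str) -> dict[str, float]:
        vals = frame[col].dropna().to_numpy()
        if len(vals) == 0:
            return {"median": math.nan, "iqr_low": math.nan, "iqr_high": math.nan}
        lo, hi = _iqr(vals)
        return {"median": float(np.median(vals)), "iqr_low": lo, "iqr_high": hi}

    summary: dict = {
        "n_trials": len(metrics),
        "pearson_r": med_iqr("pearson_r"),
        "f1": med_iqr("f1"),
        "per_type": {},
        "per_trial": frame,
    }
    for etype in EVENT_TYPES:
        key = etype.lower()
        n_true = int(frame[f"{key}_n_true"].sum())
        n_pred = int(frame[f"{key}_n_pred"].sum())
        n_miss = int(frame[f"{key}_n_missed"].sum())
        n_false = int(frame[f"{key}_n_false"].sum())
        summary["per_type"][etype] = {
            "median_abs_displacement_ms":
                med_iqr(f"{key}_median_abs_displacement_ms"),
            "pooled_fdr": n_false / n_pred if n_pred else math.nan,
            "pooled_fnr": n_miss / n_true if n_true else math.nan,
            "n_true": n_true, "n_pred": n_pred,
        }
    return summary
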