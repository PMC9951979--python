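"""Rule-based gait-event extraction from shank angular velocity.

Events are extracted per leg from the angular velocity about the
medio-lateral axis (measured by the IMU or reconstructed from EMG):

* **SWP** (swing peak velocity): local maxima with at least 150 deg/s peak
  height and 0.7 s inter-peak separation.  Two consecutive SWP events define
  one gait cycle.
* **HC** (heel contact): the *earliest* local minimum in the 10–45 %
  sub-interval of the cycle; if the sub-interval contains no local minimum,
  its global minimum is used.
* **TO** (toe-off): the *latest* local minimum in the 55–90 % sub-interval,
  with the same global-minimum fallback.

Tie-break and boundary conventions (fixed here, applied identically to
measured and predicted traces so downstream metrics are unbiased):

* A local extremum is a sample strictly greater/less than both neighbours;
  a plateau resolves to its first sample.
* When two SWP candidates violate the separation rule, the higher peak wins;
  at equal height the earlier peak wins.
* Peak height is absolute amplitude, not prominence.
* Sub-interval percentages are rounded toward the cycle interior.
* Phase intervals are half-open: stance = [HC, next TO), swing = [TO, next
  HC); samples before the first and after the last defining event are
  undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (DataError, Emg2GaitError, GaitCycle, GaitEvent,
                   ParameterError, SignalChannel)

logger = logging.getLogger("emg2gait")


class SequencingError(Emg2GaitError):
    """HC/TO events do not alternate."""


class StatisticsError(Emg2GaitError):
    """Too few events to compute cycle statistics."""


@dataclass
class EventExtractionConfig:
    """Parameters of the rule set.

    ``swp_min_height`` in deg/s, ``swp_min_separation_s`` in seconds;
    ``hc_window`` / ``to_window`` as fractions of the cycle.  ``invert_av``
    flips the trace for sensors mounted with opposite polarity.
    """

    swp_min_height: float = 150.0
    swp_min_separation_s: float = 0.7
    hc_window: tuple[float, float] = (0.10, 0.45)
    to_window: tuple[float, float] = (0.55, 0.90)
    invert_av: bool = False

    def __post_init__(self) -> None:
        if not self.swp_min_separation_s > 0:
            raise ParameterError("swp_min_separation_s must be > 0")
        ok = (0 < self.hc_window[0] < self.hc_window[1]
              < self.to_window[0] < self.to_window[1] < 1)
        if not ok:
            raise ParameterError("HC/TO windows must satisfy "
                                 "0 < hc < to < 1 elementwise")


@dataclass
class PhaseSeries:
    """Per-sample binary swing/stance labels on the common clock.

    ``labels[i]`` is True during swing; ``defined[i]`` marks samples covered
    by the HC–TO alternation (undefined before the first and after the last
    defining event).
    """

    leg: str
    labels: np.ndarray   # bool, True = swing
    defined: np.ndarray  # bool
    fs: float
    t0: float = 0.0


def _local_extrema(x: np.ndarray, minima: bool) -> np.ndarray:
    """Indices of strict local extrema; a plateau yields its first sample."""
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        rising_into = x[i] < x[i - 1] if minima else x[i] > x[i - 1]
        if rising_into:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1:
                falls_out = x[j + 1] > x[i] if minima else x[j + 1] < x[i]
                if falls_out:
                    out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def _signal(av: SignalChannel, cfg: EventExtractionConfig) -> np.ndarray:
    x = av.samples
    if not np.all(np.isfinite(x)):
        raise DataError("event extraction requires a finite trace "
                        "(crop prediction margins first)")
    return -x if cfg.invert_av else x


def detect_swp(av: SignalChannel,
               cfg: EventExtractionConfig | None = None) -> list[GaitEvent]:
    """Detect swing-peak events (thresholded, separated local maxima)."""
    cfg = cfg or EventExtractionConfig()
    if av.n < 3:
        raise DataError("signal too short for peak detection")
    x = _signal(av, cfg)
    cand = _local_extrema(x, minima=False)
    cand = cand[x[cand] >= cfg.swp_min_height]
    min_sep = cfg.swp_min_separation_s * av.fs
    # Greedy selection by descending height (ties: earlier peak), dropping
    # candidates within the separation distance of an already accepted peak.
    order = sorted(range(len(cand)), key=lambda i: (-x[cand[i]], cand[i]))
    keep: list[int] = []
    for i in order:
        if all(abs(cand[i] - k) >= min_sep for k in keep):
            keep.append(cand[i])
    keep.sort()
    return [GaitEvent(type="SWP", leg=av.side, time_s=i / av.fs) for i in keep]


def _window_indices(start: int, span: int, frac: tuple[float, float]) -> tuple[int, int]:
    """Sub-interval sample bounds, rounded toward the cycle interior."""
    lo = start + int(np.ceil(frac[0] * span))
    hi = start + int(np.floor(frac[1] * span))
    return lo, hi


def detect_hc_to(av: SignalChannel, swp: list[GaitEvent],
                 cfg: EventExtractionConfig | None = None) -> list[GaitEvent]:
    """Detect heel-contact and toe-off events within each gait cycle.

    Fewer than two SWP events means no cycles: the result is empty.
    """
    cfg = cfg or EventExtractionConfig()
    x = _signal(av, cfg)
    minima = _local_extrema(x, minima=True)
    events: list[GaitEvent] = []
    starts = [int(round(e.time_s * av.fs)) for e in swp]
    for s0, s1 in zip(starts[:-1], starts[1:]):
        span = s1 - s0
        for etype, frac, earliest in (("HC", cfg.hc_window, True),
                                      ("TO", cfg.to_window, False)):
            lo, hi = _window_indices(s0, span, frac)
            inside = minima[(minima >= lo) & (minima <= hi)]
            if len(inside):
                idx = int(inside[0] if earliest else inside[-1])
            else:
                idx = lo + int(np.argmin(x[lo:hi + 1]))
            events.append(GaitEvent(type=etype, leg=av.side,
                                    time_s=idx / av.fs))
    return events


def extract_events(av: SignalChannel,
                   cfg: EventExtractionConfig | None = None) -> list[GaitEvent]:
    """SWP, HC and TO events of one leg, sorted by time."""
    cfg = cfg or EventExtractionConfig()
    swp = detect_swp(av, cfg)
    hcto = detect_hc_to(av, swp, cfg)
    return sorted(swp + hcto, key=lambda e: (e.time_s, e.type))


def extract_cycles(av: SignalChannel,
                   cfg: EventExtractionConfig | None = None) -> list[GaitCycle]:
    """Typed gait cycles (SWP→SWP with interior HC and TO)."""
    cfg = cfg or EventExtractionConfig()
    swp = detect_swp(av, cfg)
    hcto = detect_hc_to(av, swp, cfg)
    cycles = []
    for i in range(len(swp) - 1):
        hc = hcto[2 * i]
        to = hcto[2 * i + 1]
        cycles.append(GaitCycle(leg=av.side, start_s=swp[i].time_s,
                                end_s=swp[i + 1].time_s,
                                hc_s=hc.time_s, to_s=to.time_s))
    return cycles


def events_to_phases(events: list[GaitEvent], trial_span: tuple[float, float],
                     fs: float = 200.0, leg: str | None = None) -> PhaseSeries:
    """Turn alternating HC/TO events into a binary swing/stance series.

    Stance runs from each HC (inclusive) to the next TO (exclusive), swing
    from each TO (inclusive) to the next HC (exclusive).  Two consecutive
    events of the same type raise :class:`SequencingError`.
    """
    t0, t1 = trial_span
    if not t1 > t0:
        raise ParameterError("trial span must be non-empty")
    defining = sorted((e for e in events if e.type in ("HC", "TO")),
                      key=lambda e: e.time_s)
    if leg is None:
        legs = {e.leg for e in defining}
        if len(legs) > 1:
            raise ParameterError("events from multiple legs; pass leg=...")
        leg = legs.pop() if legs else "left"
    else:
        defining = [e for e in defining if e.leg == leg]
    n = int(round((t1 - t0) * fs))
    labels = np.zeros(n, dtype=bool)
    defined = np.zeros(n, dtype=bool)
    for prev, nxt in zip(defining[:-1], defining[1:]):
        if prev.type == nxt.type:
            raise SequencingError(
                f"two consecutive {prev.type} events without an intervening "
                f"{'TO' if prev.type == 'HC' else 'HC'}")
        i0 = int(round((prev.time_s - t0) * fs))
        i1 = int(round((nxt.time_s - t0) * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        labels[i0:i1] = prev.type == "TO"   # TO starts swing
        defined[i0:i1] = True
    return PhaseSeries(leg=leg, labels=labels, defined=defined, fs=fs, t0=t0)


@dataclass(frozen=True)
class CycleStats:
    median_duration_ms: float
    cadence_cycles_per_min: float
    mad_variability_ms: float
    n_cycles: int


def cycle_statistics(swp: list[GaitEvent]) -> CycleStats:
    """Cycle duration statistics from consecutive SWP events.

    Cadence is ``60000 / median duration`` (cycles per minute); variability
    is the median absolute deviation of durations from their median.
    """
    if len(swp) < 3:
        raise StatisticsError("cycle statistics need at least 3 SWP events")
    times = np.asarray(sorted(e.time_s for e in swp))
    durations_ms = np.diff(times) * 1000.0
    med = float(np.median(durations_ms))
    mad = float(np.median(np.abs(durations_ms - med)))
    return CycleStats(median_duration_ms=med,
                      cadence_cycles_per_min=60000.0 / med,
                      mad_variability_ms=mad,
                      n_cycles=len(durations_ms))
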