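"""Core domain types, on-disk formats, resampling, TTL alignment and cropping.

The package works with synchronized walking recordings consisting of up to ten
surface-EMG channels (native 1000 Hz) and two shank angular-velocity channels
(gyroscope about the medio-lateral axis, native 128 Hz), one per leg.  A
:class:`Recording` bundles the channels with patient/trial identity, the TTL
synchronization marks of each device stream and the manually annotated walking
on/offsets.

On-disk format (plain text, portable):

* ``<trial>.csv`` — UTF-8, comma-delimited, one header row of channel labels,
  one column per channel; columns of unequal length are padded with empty
  cells.  Floats are written with 9 significant digits.
* ``<trial>.meta.yaml`` — patient/trial ids, per-channel ``{side, kind, fs,
  units}``, TTL onset/offset per device stream, walking bounds.
* ``<trial>.events.csv`` — gait events with columns ``leg,type,time_s``.

Timeline conventions: every channel is sampled on a 0-based grid, sample ``i``
at time ``i / fs`` seconds from the start of its own stream.  TTL onsets are
given per stream on the stream's own clock; walking bounds are given on the
TTL-aligned timeline (first TTL rising edge = 0 s).  After cropping, time 0
is the walking onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("emg2gait")

SIDES = ("left", "right")
KINDS = ("emg", "angular_velocity")
EVENT_TYPES = ("SWP", "HC", "TO")

#: Decimal-text precision used by :func:`write_recording`.
FLOAT_FORMAT = "%.9g"


class Emg2GaitError(Exception):
    """Base class for all package errors."""


class FormatError(Emg2GaitError):
    """Malformed or inconsistent on-disk data."""


class DataError(Emg2GaitError):
    """Semantically invalid signal data (non-finite samples, too short, ...)."""


class ParameterError(Emg2GaitError):
    """Invalid processing parameter."""


class AlignmentError(Emg2GaitError):
    """Missing or unusable TTL synchronization information."""


class BoundsError(Emg2GaitError):
    """Crop bounds outside the recording extent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SignalChannel:
    """A single uniformly sampled signal.

    Parameters
    ----------
    label
        Channel name, unique within a recording.  EMG channels follow the
        ``<L|R><muscle>`` convention (e.g. ``"LVl"``), angular velocity
        ``"L_IMU"`` / ``"R_IMU"``.
    side
        ``"left"`` or ``"right"``.
    kind
        ``"emg"`` or ``"angular_velocity"``.
    fs
        Sampling rate in Hz, > 0.
    samples
        Real-valued samples; must be finite.
    units
        ``"a.u."`` for EMG envelopes, ``"deg/s"`` for angular velocity.
    allow_nan
        Permit NaN entries as missing-value markers (used by model
        predictions at embedding boundaries); recorded data must be finite.
    """

    label: str
    side: str
    kind: str
    fs: float
    samples: np.ndarray
    units: str = "a.u."
    allow_nan: bool = False

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise FormatError(f"unknown side {self.side!r}")
        if self.kind not in KINDS:
            raise FormatError(f"unknown kind {self.kind!r}")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DataError("samples must be one-dimensional")
        bad = ~np.isfinite(self.samples)
        if self.allow_nan:
            bad &= ~np.isnan(self.samples)
        if bad.any():
            raise DataError(f"channel {self.label!r} contains non-finite samples")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (0-based grid)."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "SignalChannel":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs)


def _as_stream_map(value, name: str) -> dict[str, float] | None:
    """Normalize a TTL time to a per-device-stream mapping {'emg','imu'}."""
    if value is None:
        return None
    if isinstance(value, Mapping):
        out = {str(k): float(v) for k, v in value.items()}
        for key in out:
            if key not in ("emg", "imu"):
                raise FormatError(f"{name}: unknown device stream {key!r}")
        return out
    return {"emg": float(value), "imu": float(value)}


@dataclass
class Recording:
    """A synchronized multichannel trial.

    ``ttl_onset_s`` / ``ttl_offset_s`` map the device stream (``"emg"`` /
    ``"imu"``) to the TTL time on that stream's own clock; a scalar is
    accepted and applied to both streams.  ``walk_start_s`` / ``walk_end_s``
    delimit the walking period on the TTL-aligned timeline.
    """

    patient_id: str
    trial_id: str
    channels: list[SignalChannel]
    ttl_onset_s: dict[str, float] | None = None
    ttl_offset_s: dict[str, float] | None = None
    walk_start_s: float | None = None
    walk_end_s: float | None = None

    def __post_init__(self) -> None:
        labels = [ch.label for ch in self.channels]
        if len(set(labels)) != len(labels):
            raise FormatError("channel labels must be unique within a recording")
        av = self.av_channels()
        if av:
            sides = sorted(ch.side for ch in av)
            if sides != ["left", "right"]:
                raise FormatError(
                    "a recording with IMU data must have exactly two "
                    "angular-velocity channels, one per side")
        self.ttl_onset_s = _as_stream_map(self.ttl_onset_s, "ttl_onset_s")
        self.ttl_offset_s = _as_stream_map(self.ttl_offset_s, "ttl_offset_s")
        if self.ttl_onset_s and self.ttl_offset_s:
            for key in self.ttl_onset_s:
                off = self.ttl_offset_s.get(key)
                if off is not None and not self.ttl_onset_s[key] < off:
                    raise FormatError("TTL onset must precede TTL offset")

    def channel(self, label: str) -> SignalChannel:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(label)

    def emg_channels(self) -> list[SignalChannel]:
        return [ch for ch in self.channels if ch.kind == "emg"]

    def av_channels(self) -> list[SignalChannel]:
        return [ch for ch in self.channels if ch.kind == "angular_velocity"]

    def av_channel(self, side: str) -> SignalChannel:
        for ch in self.av_channels():
            if ch.side == side:
                return ch
        raise KeyError(f"no angular-velocity channel for side {side!r}")


@dataclass(frozen=True)
class GaitEvent:
    """A typed, timestamped gait event on the common timeline."""

    type: str   # SWP | HC | TO
    leg: str    # left | right
    time_s: float

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise FormatError(f"unknown event type {self.type!r}")
        if self.leg not in SIDES:
            raise FormatError(f"unknown leg {self.leg!r}")


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle: the interval between two consecutive SWP events.

    Invariant: ``start_s < hc_s < to_s < end_s`` — the heel contact falls in
    the 10–45 % sub-interval of the cycle and the toe-off in the 55–90 %
    sub-interval.
    """

    leg: str
    start_s: float
    end_s: float
    hc_s: float
    to_s: float

    def __post_init__(self) -> None:
        if not (self.start_s < self.hc_s < self.to_s < self.end_s):
            raise DataError(
                f"invalid cycle ordering: start={self.start_s} hc={self.hc_s} "
                f"to={self.to_s} end={self.end_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# On-disk I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, signal_file: str | Path,
                    meta_file: str | Path) -> None:
    """Write a recording as a delimited-text signal file plus YAML sidecar.

    Floats are written with 9 significant digits; reading the files back with
    :func:`read_recording` reproduces the recording to that precision.
    """
    if not rec.channels:
        raise FormatError("cannot write a recording with no channels")
    frame = pd.DataFrame({ch.label: pd.Series(ch.samples) for ch in rec.channels})
    frame.to_csv(signal_file, index=False, float_format=FLOAT_FORMAT, na_rep="")

    meta = {
        "patient_id": rec.patient_id,
        "trial_id": rec.trial_id,
        "channels": {
            ch.label: {"side": ch.side, "kind": ch.kind,
                       "fs": float(ch.fs), "units": ch.units}
            for ch in rec.channels
        },
    }
    if rec.ttl_onset_s is not None:
        meta["ttl"] = {"onset_s": dict(rec.ttl_onset_s)}
        if rec.ttl_offset_s is not None:
            meta["ttl"]["offset_s"] = dict(rec.ttl_offset_s)
    if rec.walk_start_s is not None or rec.walk_end_s is not None:
        meta["walk"] = {"start_s": rec.walk_start_s, "end_s": rec.walk_end_s}
    with open(meta_file, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_recording(signal_file: str | Path, meta_file: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The signal file header and the metadata channel table must describe the
    same channel set; any mismatch or missing per-channel metadata raises
    :class:`FormatError`.  Non-finite interior samples raise
    :class:`DataError`.
    """
    try:
        with open(meta_file, "r", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise FormatError(f"missing metadata sidecar: {meta_file}") from exc
    if not isinstance(meta, dict) or "channels" not in meta:
        raise FormatError("metadata sidecar must define a 'channels' table")

    frame = pd.read_csv(signal_file)
    header = list(frame.columns)
    meta_channels = meta["channels"]
    if set(header) != set(meta_channels):
        missing = set(header) ^ set(meta_channels)
        raise FormatError(
            f"signal header and metadata disagree on channels: {sorted(missing)}")

    channels = []
    for label in header:
        info = meta_channels[label]
        for key in ("side", "kind", "fs"):
            if key not in info:
                raise FormatError(f"channel {label!r}: missing metadata {key!r}")
        col = frame[label].to_numpy(dtype=float)
        # Unequal column lengths are padded with empty cells on write; strip
        # the trailing NaN run, then require the interior to be finite.
        finite = np.isfinite(col)
        if finite.all():
            n_valid = len(col)
        else:
            finite_idx = np.nonzero(finite)[0]
            if len(finite_idx) == 0:
                raise DataError(f"channel {label!r} has no finite samples")
            n_valid = int(finite_idx[-1]) + 1
        col = col[:n_valid]
        if not np.all(np.isfinite(col)):
            raise DataError(f"channel {label!r} contains non-finite samples")
        channels.append(SignalChannel(
            label=label, side=info["side"], kind=info["kind"],
            fs=float(info["fs"]), samples=col,
            units=info.get("units", "a.u.")))

    ttl = meta.get("ttl") or {}
    walk = meta.get("walk") or {}
    return Recording(
        patient_id=str(meta.get("patient_id", "")),
        trial_id=str(meta.get("trial_id", "")),
        channels=channels,
        ttl_onset_s=ttl.get("onset_s"),
        ttl_offset_s=ttl.get("offset_s"),
        walk_start_s=walk.get("start_s"),
        walk_end_s=walk.get("end_s"),
    )


def write_events(events: Iterable[GaitEvent], path: str | Path) -> None:
    """Write gait events as a ``leg,type,time_s`` CSV."""
    rows = [(e.leg, e.type, e.time_s) for e in events]
    pd.DataFrame(rows, columns=["leg", "type", "time_s"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_events(path: str | Path) -> list[GaitEvent]:
    frame = pd.read_csv(path)
    for col in ("leg", "type", "time_s"):
        if col not in frame.columns:
            raise FormatError(f"events file missing column {col!r}")
    return [GaitEvent(type=row.type, leg=row.leg, time_s=float(row.time_s))
            for row in frame.itertuples()]


# ---------------------------------------------------------------------------
# Resampling, alignment, cropping
# ---------------------------------------------------------------------------

def upsample_nearest(ch: SignalChannel, target_fs: float) -> SignalChannel:
    """Up-sample a channel to ``target_fs`` by nearest-neighbor interpolation.

    Each output sample takes the value of the input sample whose timestamp is
    nearest to the output timestamp, so the output value set is a subset of
    the input value set.  The duration is preserved to within one output
    sample.
    """
    if not target_fs > 0:
        raise ParameterError("target_fs must be > 0")
    if ch.fs > target_fs:
        raise ParameterError(
            f"upsample_nearest requires fs <= target_fs ({ch.fs} > {target_fs})")
    if ch.fs == target_fs:
        return ch.with_samples(ch.samples.copy())
    n_out = int(round(ch.n / ch.fs * target_fs))
    t_out = np.arange(n_out) / target_fs
    idx = np.clip(np.round(t_out * ch.fs).astype(int), 0, ch.n - 1)
    return ch.with_samples(ch.samples[idx], fs=target_fs)


def align_to_ttl(rec: Recording) -> Recording:
    """Shift every channel so the first TTL rising edge is time zero.

    Each device stream (EMG, IMU) carries its own TTL onset; samples recorded
    before the stream's TTL are dropped, which realigns the streams onto a
    common clock.
    """
    if rec.ttl_onset_s is None:
        raise AlignmentError("recording has no TTL onset annotation")
    channels = []
    for ch in rec.channels:
        stream = "emg" if ch.kind == "emg" else "imu"
        if stream not in rec.ttl_onset_s:
            raise AlignmentError(f"missing TTL onset for {stream!r} stream")
        onset = rec.ttl_onset_s[stream]
        start = int(round(onset * ch.fs))
        if start < 0 or start > ch.n:
            raise AlignmentError(
                f"TTL onset {onset} s outside channel {ch.label!r}")
        channels.append(ch.with_samples(ch.samples[start:]))
    offset = None
    if rec.ttl_offset_s is not None:
        offset = {k: rec.ttl_offset_s[k] - rec.ttl_onset_s.get(k, 0.0)
                  for k in rec.ttl_offset_s}
    return replace(rec, channels=channels,
                   ttl_onset_s={"emg": 0.0, "imu": 0.0}, ttl_offset_s=offset)


def crop_walking(rec: Recording) -> Recording:
    """Restrict every channel to the annotated walking period.

    After cropping, time zero is the walking onset and the stored bounds are
    rebased to ``(0, duration)``, which makes the operation idempotent.
    """
    if rec.walk_start_s is None or rec.walk_end_s is None:
        raise BoundsError("recording has no walking bounds annotation")
    start, end = rec.walk_start_s, rec.walk_end_s
    if not 0 <= start < end:
        raise BoundsError(f"invalid walking bounds [{start}, {end}]")
    channels = []
    for ch in rec.channels:
        i0 = int(round(start * ch.fs))
        i1 = int(round(end * ch.fs))
        if i1 > ch.n:
            raise BoundsError(
                f"walking bounds [{start}, {end}] s exceed channel "
                f"{ch.label!r} extent ({ch.duration_s:.3f} s)")
        channels.append(ch.with_samples(ch.samples[i0:i1]))
    return replace(rec, channels=channels,
                   walk_start_s=0.0, walk_end_s=end - start)
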