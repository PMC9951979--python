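"""Signal preprocessing: filters, resampling and normalization.

Turns raw recordings into smoothed, normalized, synchronized 200 Hz signals.

EMG path
    bandpass (20–450 Hz, 4th-order zero-phase Butterworth) → full-wave
    rectification → decimation to 200 Hz → centered moving median (200 ms) →
    centered moving mean (40 ms) → subtraction of a 10 s centered moving
    minimum (a crude high-pass removing slow baseline drift) → per-recording
    percentile normalization (subtract the 1st percentile, divide by the
    95th).

IMU path
    nearest-neighbor up-sampling to 200 Hz → centered moving median (100 ms)
    → centered moving mean (40 ms).

Both paths are then aligned to the first TTL rising edge and cropped to the
annotated walking period, leaving all channels on a shared 200 Hz clock.

Conventions (the source protocol leaves these open; fixed here and used
consistently):

* Window lengths in ms convert to samples as ``round(ms * fs / 1000)`` forced
  odd, so windows are exactly centered.
* Centered moving filters shrink their window symmetrically at the edges
  (no padding).
* Percentiles use linear interpolation between order statistics and are
  computed per channel, per recording.
* Normalization divides by the 95th percentile of the baseline-subtracted
  signal (baseline subtraction precedes normalization in the pipeline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (DataError, ParameterError, Recording, SignalChannel,
                   align_to_ttl, crop_walking, upsample_nearest)

logger = logging.getLogger("emg2gait")


class DegenerateSignalError(DataError):
    """Signal has no usable spread (e.g. constant) for normalization."""


@dataclass
class PreprocessingConfig:
    """Preprocessing parameters.

    Defaults follow the reference protocol: 200 Hz common clock, 100/40 ms
    IMU smoothing, 200/40 ms EMG smoothing, 10 s moving-minimum baseline
    window and 1st/95th-percentile normalization.  The EMG bandpass corners
    (20–450 Hz, the standard surface-EMG band) are configurable.
    """

    emg_bandpass_hz: tuple[float, float] = (20.0, 450.0)
    emg_target_fs: float = 200.0
    imu_target_fs: float = 200.0
    imu_median_ms: float = 100.0
    imu_mean_ms: float = 40.0
    emg_median_ms: float = 200.0
    emg_mean_ms: float = 40.0
    baseline_window_s: float = 10.0
    norm_low_pct: float = 1.0
    norm_high_pct: float = 95.0
    bandpass_order: int = 4

    def __post_init__(self) -> None:
        low, high = self.emg_bandpass_hz
        if not 0 < low < high:
            raise ParameterError("invalid EMG bandpass corners")
        for name in ("imu_median_ms", "imu_mean_ms", "emg_median_ms",
                     "emg_mean_ms", "baseline_window_s"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 <= self.norm_low_pct < self.norm_high_pct <= 100:
            raise ParameterError("percentile bounds must satisfy 0 <= low < high <= 100")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def rectify(ch: SignalChannel) -> SignalChannel:
    """Full-wave rectification (elementwise absolute value) of an EMG channel."""
    if ch.kind != "emg":
        raise ParameterError(f"rectify expects an EMG channel, got {ch.kind!r}")
    return ch.with_samples(np.abs(ch.samples))


def bandpass(ch: SignalChannel, low: float, high: float,
             order: int = 4) -> SignalChannel:
    """Zero-phase Butterworth bandpass (forward–backward filtering)."""
    if not 0 < low < high < ch.fs / 2:
        raise ParameterError(
            f"bandpass corners must satisfy 0 < low < high < fs/2 "
            f"(got {low}, {high} at fs={ch.fs})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=ch.fs, output="sos")
    return ch.with_samples(sps.sosfiltfilt(sos, ch.samples))


def downsample(ch: SignalChannel, target_fs: float) -> SignalChannel:
    """Decimate to ``target_fs`` by keeping every (fs/target_fs)-th sample.

    The sampling-rate ratio must be an integer; sample 0 is always retained.
    No extra anti-aliasing is applied — in the EMG pipeline the signal has
    already been band-limited and is subsequently median-smoothed.
    """
    if not target_fs > 0:
        raise ParameterError("target_fs must be > 0")
    ratio = ch.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ParameterError(
            f"downsample requires an integer rate ratio (fs={ch.fs}, "
            f"target={target_fs})")
    stride = int(round(ratio))
    return ch.with_samples(ch.samples[::stride].copy(), fs=target_fs)


def window_samples(window_ms: float, fs: float) -> int:
    """Convert a window length in ms to an odd sample count at ``fs``."""
    k = int(round(window_ms * fs / 1000.0))
    if k < 1:
        raise ParameterError(
            f"window of {window_ms} ms is shorter than one sample at {fs} Hz")
    return k if k % 2 == 1 else k + 1


def _rolling_center(x: np.ndarray, k: int, stat: str) -> np.ndarray:
    """Centered rolling statistic with symmetric edge truncation.

    The interior is computed with a full window of ``k`` samples; within
    ``h = k // 2`` samples of either edge the window shrinks symmetrically to
    ``2 * min(h, i, n-1-i) + 1`` samples.
    """
    n = len(x)
    h = k // 2
    if n == 0:
        return x.copy()
    eff_k = min(k, 2 * ((n - 1) // 2) + 1)  # largest odd window that fits
    eff_h = eff_k // 2
    series = pd.Series(x)
    out = getattr(series.rolling(eff_k, center=True, min_periods=eff_k), stat)() \
        .to_numpy()
    func = {"median": np.median, "mean": np.mean, "min": np.min}[stat]
    for i in range(min(eff_h, n)):
        hh = min(eff_h, i)
        out[i] = func(x[i - hh:i + hh + 1])
        j = n - 1 - i
        hh = min(eff_h, n - 1 - j)
        out[j] = func(x[j - hh:j + hh + 1])
    return out


def moving_median(ch: SignalChannel, window_ms: float) -> SignalChannel:
    """Centered moving median; window truncated symmetrically at the edges."""
    k = window_samples(window_ms, ch.fs)
    return ch.with_samples(_rolling_center(ch.samples, k, "median"))


def moving_mean(ch: SignalChannel, window_ms: float) -> SignalChannel:
    """Centered moving mean; window truncated symmetrically at the edges."""
    k = window_samples(window_ms, ch.fs)
    return ch.with_samples(_rolling_center(ch.samples, k, "mean"))


def subtract_moving_min(ch: SignalChannel, window_s: float,
                        truncate: bool = True) -> SignalChannel:
    """Subtract a centered moving minimum (slow-baseline removal).

    With ``truncate=True`` (default) the window shrinks symmetrically at the
    edges and when it exceeds the signal length; with ``truncate=False`` a
    window longer than the signal raises :class:`ParameterError`.
    """
    if not window_s > 0:
        raise ParameterError("window_s must be > 0")
    k = window_samples(window_s * 1000.0, ch.fs)
    if not truncate and k > ch.n:
        raise ParameterError(
            f"moving-minimum window ({window_s} s) exceeds signal length")
    baseline = _rolling_center(ch.samples, k, "min")
    return ch.with_samples(ch.samples - baseline)


def percentile_normalize(ch: SignalChannel, low_pct: float = 1.0,
                         high_pct: float = 95.0,
                         scale_hint: float = 0.0) -> SignalChannel:
    """Normalize as ``(x - P_low(x)) / P_high(x)``.

    Percentiles are computed on this channel alone (per channel, per
    recording).  A channel with no spread between the two percentiles, or
    whose high percentile is zero (or numerically negligible against the
    signal's own scale, so that dividing by it would only amplify rounding
    noise), cannot be scaled and raises :class:`DegenerateSignalError`.
    ``scale_hint`` lets callers supply an external amplitude reference (the
    pipeline passes the pre-baseline-subtraction envelope amplitude, so a
    flat envelope is flagged even though subtraction maps it near zero).
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ParameterError("percentiles must satisfy 0 <= low < high <= 100")
    p_low = np.percentile(ch.samples, low_pct)
    p_high = np.percentile(ch.samples, high_pct)
    scale = np.max(np.abs(ch.samples)) if ch.n else 0.0
    scale = max(scale, scale_hint)
    if p_high == 0 or p_high == p_low or p_high <= 1e-6 * scale:
        raise DegenerateSignalError(
            f"channel {ch.label!r} is degenerate under percentile "
            f"normalization (P{low_pct:g}={p_low:g}, P{high_pct:g}={p_high:g})")
    return ch.with_samples((ch.samples - p_low) / p_high)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _emg_envelope(ch: SignalChannel,
                  cfg: PreprocessingConfig) -> SignalChannel:
    """EMG path up to the smoothed envelope (before baseline subtraction)."""
    low, high = cfg.emg_bandpass_hz
    nyq = ch.fs / 2
    if high >= nyq:
        # Re-running on already down-sampled data: clamp the upper corner.
        high = 0.45 * ch.fs
        logger.warning("EMG bandpass upper corner clamped to %.1f Hz "
                       "(fs=%.0f Hz)", high, ch.fs)
    out = bandpass(ch, low, high, cfg.bandpass_order)
    out = rectify(out)
    out = downsample(out, cfg.emg_target_fs)
    out = moving_median(out, cfg.emg_median_ms)
    out = moving_mean(out, cfg.emg_mean_ms)
    return out


def preprocess_emg_channel(ch: SignalChannel, cfg: PreprocessingConfig,
                           normalize: bool = True) -> SignalChannel:
    """Apply the full EMG path of the preprocessing pipeline to one channel.

    ``normalize=False`` stops after baseline subtraction; the recording-level
    pipeline uses this to defer normalization until after cropping.
    """
    env = _emg_envelope(ch, cfg)
    envelope_scale = float(np.max(np.abs(env.samples))) if env.n else 0.0
    out = subtract_moving_min(env, cfg.baseline_window_s)
    if normalize:
        out = percentile_normalize(out, cfg.norm_low_pct, cfg.norm_high_pct,
                                   scale_hint=envelope_scale)
    return replace(out, units="a.u.")


def preprocess_imu_channel(ch: SignalChannel,
                           cfg: PreprocessingConfig) -> SignalChannel:
    """Apply the IMU path of the preprocessing pipeline to one channel."""
    out = upsample_nearest(ch, cfg.imu_target_fs)
    out = moving_median(out, cfg.imu_median_ms)
    out = moving_mean(out, cfg.imu_mean_ms)
    return out


def preprocess_recording(rec: Recording,
                         cfg: PreprocessingConfig | None = None) -> Recording:
    """Run the full preprocessing pipeline on a raw recording.

    Returns a recording whose channels all live on the shared 200 Hz clock,
    aligned to the first TTL rising edge and cropped to the walking period.

    EMG percentile normalization runs *after* cropping: its purpose is to
    standardize activation scales across patients, so the percentiles must
    describe the walking data being analyzed.  Estimating them on the
    uncropped stream would let pre/post-walk segments — and the boundary
    region where the truncated 10 s moving-minimum window distorts the
    baseline — dominate the scale.  Per channel, per recording as always.

    Not idempotent: re-applying it re-normalizes the already-normalized EMG.
    """
    cfg = cfg or PreprocessingConfig()
    channels = []
    scales: dict[str, float] = {}
    for ch in rec.channels:
        if ch.kind == "emg":
            env = _emg_envelope(ch, cfg)
            scales[ch.label] = float(np.max(np.abs(env.samples))) if env.n else 0.0
            channels.append(replace(
                subtract_moving_min(env, cfg.baseline_window_s), units="a.u."))
        else:
            channels.append(preprocess_imu_channel(ch, cfg))
    out = replace(rec, channels=channels)
    out = align_to_ttl(out)
    out = crop_walking(out)
    normalized = [percentile_normalize(ch, cfg.norm_low_pct,
                                       cfg.norm_high_pct,
                                       scale_hint=scales[ch.label])
                  if ch.kind == "emg" else ch
                  for ch in out.channels]
    return replace(out, channels=normalized)
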