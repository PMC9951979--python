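"""Temporal embedding, ordinary-least-squares fitting and LOPO prediction.

The decoding model approximates the shank angular velocity ``y(t)`` of one
leg as a linear function of temporally embedded EMG envelopes: every EMG
channel ``x_m`` is complemented with time-shifted copies ``x_m(t + tau_k)``
over a grid of K equally spaced lags (default 21 lags from −500 ms to
+500 ms in 50 ms steps), and a constant offset row is appended, giving a
``(K*M + 1)``-dimensional feature vector per time point.  The coefficient
vector ``beta`` minimizes the mean-squared error between measured and
reconstructed angular velocity on training data; predictions are
``y_hat(t) = beta^T x_tilde(t)``.

Because a model fitted on a training cohort is applied to unseen patients
without any per-patient calibration, model selection is performed over the
31 bilateral muscle subsets (every non-empty subset of the five recorded
muscles, always including both sides of each muscle) under leave-one-patient-
out cross-validation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (DataError, Emg2GaitError, ParameterError, Recording,
                   SignalChannel, SIDES)

logger = logging.getLogger("emg2gait")

#: The five recorded muscles: tibialis anterior, soleus, gastrocnemius
#: medialis, gastrocnemius lateralis, vastus lateralis.
MUSCLES = ("Ta", "S", "Gm", "Gl", "Vl")


class ModelMismatchError(Emg2GaitError):
    """Design matrix does not match the model's muscle set or lag grid."""


class CrossValidationError(Emg2GaitError):
    """Invalid cross-validation setup (e.g. a single patient)."""


@dataclass(frozen=True)
class LagGrid:
    """Equally spaced temporal shifts applied to each EMG channel."""

    tau_start_ms: float = -500.0
    tau_end_ms: float = 500.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not self.step_ms > 0 or not self.tau_end_ms >= self.tau_start_ms:
            raise ParameterError("invalid lag grid")
        span = self.tau_end_ms - self.tau_start_ms
        if abs(span / self.step_ms - round(span / self.step_ms)) > 1e-9:
            raise ParameterError("lag grid span must be a multiple of step_ms")

    @property
    def K(self) -> int:
        return int(round((self.tau_end_ms - self.tau_start_ms) / self.step_ms)) + 1

    def taus_ms(self) -> np.ndarray:
        return self.tau_start_ms + self.step_ms * np.arange(self.K)

    def lags_samples(self, fs: float) -> np.ndarray:
        """Lags in samples at ``fs``; every lag must be a whole sample."""
        lags = self.taus_ms() * fs / 1000.0
        rounded = np.round(lags)
        if np.max(np.abs(lags - rounded)) > 1e-6:
            raise ParameterError(
                f"lag grid is not sample-aligned at fs={fs} Hz")
        return rounded.astype(int)


@dataclass
class EmbeddedDesign:
    """Lagged EMG feature matrix paired with its validity mask.

    ``features`` has ``K*M + 1`` rows (muscle-major, lag-minor; last row is
    the constant offset) and one column per sample.  Columns where any
    temporal shift would leave the trial are invalid: their lagged entries
    are NaN and ``valid`` is False there.
    """

    features: np.ndarray
    muscle_labels: tuple[str, ...]
    lag_grid: LagGrid
    valid: np.ndarray
    fs: float

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_samples(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class MuscleSubset:
    """A bilateral muscle subset: both sides of each included muscle."""

    pairs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.pairs) <= len(MUSCLES):
            raise ParameterError("subset must contain between 1 and 5 muscle pairs")
        for m in self.pairs:
            if m not in MUSCLES:
                raise ParameterError(f"unknown muscle {m!r}")
        if len(set(self.pairs)) != len(self.pairs):
            raise ParameterError("duplicate muscles in subset")

    @property
    def channels(self) -> tuple[str, ...]:
        """Channel labels, both sides of each pair (``LVl``, ``RVl``, ...)."""
        return tuple(f"{s}{m}" for m in self.pairs for s in ("L", "R"))

    def __str__(self) -> str:
        return "+".join(self.pairs)


def enumerate_subsets() -> list[MuscleSubset]:
    """All 2^5 − 1 = 31 bilateral subsets of the five recorded muscles."""
    subsets = []
    for size in range(1, len(MUSCLES) + 1):
        for combo in itertools.combinations(MUSCLES, size):
            subsets.append(MuscleSubset(pairs=combo))
    return subsets


@dataclass
class RegressionModel:
    """A fitted linear decoding model for one target side."""

    beta: np.ndarray
    target_side: str
    muscle_labels: tuple[str, ...]
    lag_grid: LagGrid
    training_patients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        expected = self.lag_grid.K * len(self.muscle_labels) + 1
        if self.beta.shape != (expected,):
            raise ModelMismatchError(
                f"beta must have K*M+1 = {expected} entries, got {self.beta.shape}")
        if self.target_side not in SIDES:
            raise ParameterError(f"unknown target side {self.target_side!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "target_side": self.target_side,
            "muscle_labels": list(self.muscle_labels),
            "lag_grid": {"tau_start_ms": self.lag_grid.tau_start_ms,
                         "tau_end_ms": self.lag_grid.tau_end_ms,
                         "step_ms": self.lag_grid.step_ms},
            "training_patients": list(self.training_patients),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        payload = json.loads(Path(path).read_text())
        return cls(beta=np.asarray(payload["beta"]),
                   target_side=payload["target_side"],
                   muscle_labels=tuple(payload["muscle_labels"]),
                   lag_grid=LagGrid(**payload["lag_grid"]),
                   training_patients=tuple(payload["training_patients"]))


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def embed(emg: Sequence[SignalChannel],
          grid: LagGrid | None = None) -> EmbeddedDesign:
    """Build the lagged design matrix from preprocessed EMG channels.

    Row ``(m, k)`` at column ``t`` holds ``x_m(t + tau_k)``.  Columns within
    the embedding span of either trial boundary are invalid (no padding):
    their lagged entries are NaN and they are excluded from fitting.
    """
    grid = grid or LagGrid()
    if not emg:
        raise ParameterError("embed requires at least one EMG channel")
    fs = emg[0].fs
    T = emg[0].n
    for ch in emg:
        if ch.fs != fs or ch.n != T:
            raise DataError("all EMG channels must share fs and length")
    lags = grid.lags_samples(fs)
    lo, hi = int(lags.min()), int(lags.max())
    if T <= max(0, hi) - min(0, lo):
        raise DataError(
            f"trial of {T} samples is shorter than the embedding span")
    M, K = len(emg), grid.K
    features = np.full((K * M + 1, T), np.nan)
    features[-1, :] = 1.0
    for m, ch in enumerate(emg):
        x = ch.samples
        for k, lag in enumerate(lags):
            row = m * K + k
            a = max(0, -lag)
            b = min(T, T - lag)
            features[row, a:b] = x[a + lag:b + lag]
    valid = np.ones(T, dtype=bool)
    valid[:max(0, -lo)] = False
    if hi > 0:
        valid[T - hi:] = False
    return EmbeddedDesign(features=features,
                          muscle_labels=tuple(ch.label for ch in emg),
                          lag_grid=grid, valid=valid, fs=fs)


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

def fit_ols(design: EmbeddedDesign, target: SignalChannel | np.ndarray,
            training_patients: Sequence[str] = ()) -> RegressionModel:
    """Ordinary least squares over the valid columns of the design.

    Solved with an SVD-based least-squares factorization (``numpy.lstsq``)
    rather than the normal-equations inverse; on full-rank data the solution
    is identical, on rank-deficient data the minimum-norm solution is
    returned with a logged warning.
    """
    y = target.samples if isinstance(target, SignalChannel) else np.asarray(target, float)
    if y.shape != (design.n_samples,):
        raise DataError("target length does not match the design")
    cols = design.valid & np.isfinite(y)
    if cols.sum() < design.n_rows:
        raise DataError(
            f"need at least {design.n_rows} valid samples, have {int(cols.sum())}")
    X = design.features[:, cols]
    beta, _, rank, _ = np.linalg.lstsq(X.T, y[cols], rcond=None)
    if rank < design.n_rows:
        logger.warning("rank-deficient design (rank %d < %d); "
                       "minimum-norm solution used", rank, design.n_rows)
    side = "left"
    if isinstance(target, SignalChannel):
        side = target.side
    return RegressionModel(beta=beta, target_side=side,
                           muscle_labels=design.muscle_labels,
                           lag_grid=design.lag_grid,
                           training_patients=tuple(training_patients))


def predict(model: RegressionModel, design: EmbeddedDesign) -> SignalChannel:
    """Reconstruct angular velocity as ``beta^T x_tilde(t)``.

    Invalid boundary columns carry NaN.
    """
    if (model.muscle_labels != design.muscle_labels
            or model.lag_grid != design.lag_grid):
        raise ModelMismatchError(
            "design muscle set / lag grid do not match the model")
    yhat = model.beta @ np.where(np.isfinite(design.features),
                                 design.features, 0.0)
    yhat[~design.valid] = np.nan
    return SignalChannel(label=f"{model.target_side[0].upper()}_pred",
                         side=model.target_side, kind="angular_velocity",
                         fs=design.fs, samples=yhat, units="deg/s",
                         allow_nan=True)


# ---------------------------------------------------------------------------
# Leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LopoPrediction:
    """Held-out prediction for one trial and one target side."""

    patient_id: str
    trial_id: str
    side: str
    predicted: SignalChannel
    measured: SignalChannel


@dataclass
class LopoResult:
    predictions: list[LopoPrediction]
    models: dict[tuple[str, str], RegressionModel]  # (held_out_patient, side)


def _subset_channels(rec: Recording, subset: MuscleSubset | None) -> list[SignalChannel]:
    if subset is None:
        return rec.emg_channels()
    return [rec.channel(label) for label in subset.channels]


def fit_lopo(recordings: Sequence[Recording],
             subset: MuscleSubset | None = None,
             grid: LagGrid | None = None) -> LopoResult:
    """Leave-one-patient-out training and held-out prediction.

    For each patient, one model per target side is fitted on the concatenated
    trials of all *other* patients and applied to every trial of the held-out
    patient.  Trials are concatenated after embedding, keeping only each
    trial's valid columns, so no embedding window ever spans two trials.  The
    held-out patient's angular-velocity traces never enter the fit.
    """
    grid = grid or LagGrid()
    patients = sorted({rec.patient_id for rec in recordings})
    if len(patients) < 2:
        raise CrossValidationError("LOPO requires at least two distinct patients")

    designs = [embed(_subset_channels(rec, subset), grid) for rec in recordings]
    targets = {side: [rec.av_channel(side) for rec in recordings]
               for side in SIDES}

    predictions: list[LopoPrediction] = []
    models: dict[tuple[str, str], RegressionModel] = {}
    for held_out in patients:
        train_idx = [i for i, rec in enumerate(recordings)
                     if rec.patient_id != held_out]
        test_idx = [i for i, rec in enumerate(recordings)
                    if rec.patient_id == held_out]
        train_patients = tuple(p for p in patients if p != held_out)
        X = np.hstack([designs[i].features[:, designs[i].valid]
                       for i in train_idx])
        # one factorization serves both target sides
        Y = np.column_stack([
            np.concatenate([targets[side][i].samples[designs[i].valid]
                            for i in train_idx]) for side in SIDES])
        betas, _, rank, _ = np.linalg.lstsq(X.T, Y, rcond=None)
        if rank < X.shape[0]:
            logger.warning("LOPO fold %s: rank-deficient design", held_out)
        for s_idx, side in enumerate(SIDES):
            model = RegressionModel(beta=betas[:, s_idx], target_side=side,
                                    muscle_labels=designs[0].muscle_labels,
                                    lag_grid=grid,
                                    training_patients=train_patients)
            models[(held_out, side)] = model
            for i in test_idx:
                predictions.append(LopoPrediction(
                    patient_id=held_out,
                    trial_id=recordings[i].trial_id,
                    side=side,
                    predicted=predict(model, designs[i]),
                    measured=targets[side][i]))
    return LopoResult(predictions=predictions, models=models)
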