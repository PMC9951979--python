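# Methods

This note documents the models, conventions and design choices behind
`emg2gait`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## Signal model and preprocessing

Inputs are multichannel surface-EMG recordings (up to 10 channels, native
1000 Hz) and bilateral shank angular velocity about the medio-lateral axis
(2 gyroscope channels, native 128 Hz), synchronized by TTL marks recorded on
each device stream.  All analysis happens on a shared 200 Hz clock.

**EMG path.** Bandpass 20–450 Hz (4th-order Butterworth, forward–backward,
hence zero-phase; the standard surface-EMG band — corner frequencies are
configurable) → full-wave rectification → decimation to 200 Hz (plain
sample-dropping; the signal is already band-limited and the subsequent
200 ms median dominates any residual aliasing) → centered moving median,
200 ms → centered moving mean, 40 ms → subtraction of a centered 10 s
moving minimum (a crude high-pass that removes slow baseline drift) →
normalization `(x − P1(x)) / P95(x)` per channel and recording.

**IMU path.** Nearest-neighbor up-sampling to 200 Hz → centered moving
median, 100 ms → centered moving mean, 40 ms.  Units stay in deg/s.

**Alignment and cropping.** Each stream is shifted so its first TTL rising
edge is t = 0; channels are then cropped to the annotated walking period.
Walking on/offsets are required metadata — there is no automatic walk-bout
detection.

Conventions the protocol leaves open, fixed here:

* Window lengths convert to samples as `round(ms·fs/1000)` forced odd, so
  every window is exactly centered.
* Centered filters shrink their window *symmetrically* at the edges (no
  padding).  Consequence: at the outermost samples the median window
  degenerates to the raw sample.
* **Normalization runs after cropping.**  Its purpose is to standardize
  activation scales across patients, so the percentiles must describe the
  walking data being analyzed.  Estimating them on the uncropped stream
  would let pre/post-walk segments dominate the scale — and, worse, the
  10 s moving-minimum window propagates the degenerate edge samples of the
  median filter across 5 s of baseline, so uncropped percentiles are
  boundary artifacts.  On burst-structured EMG the normalized output then
  has P1 = 0 exactly and P95 = 1 − P1/P95 ≈ 1 (the tests assert ±0.02).
* A channel whose 95th percentile after baseline subtraction is zero, or
  negligible against the pre-subtraction envelope amplitude (relative floor
  10⁻⁶), cannot be scaled and raises a degenerate-signal error rather than
  amplifying rounding noise.
* The pipeline is deliberately not idempotent: re-running it re-normalizes
  (and re-filters) already-processed data; the bandpass upper corner is
  clamped below Nyquist with a warning in that case.

## Decoding model

Each selected EMG channel is temporally embedded with K = 21 equally spaced
lags from −500 ms to +500 ms (50 ms steps; at 200 Hz every lag is a whole
number of samples — non-integer configurations are rejected).  With M
channels and an offset row the design matrix has K·M + 1 rows; for the full
ten-channel montage that is 210 lagged features plus the offset.

* **Boundary handling:** columns within the embedding span of a trial edge
  are invalid — dropped, not padded (zero padding would bias
  coefficients).  When training concatenates trials, only per-trial valid
  columns are stacked, so no embedding window ever straddles two trials.
* **Solver:** SVD-based least squares (`numpy.linalg.lstsq`) rather than
  the normal-equations inverse; identical on full-rank data, minimum-norm
  with a logged warning otherwise.  The closed form `(X̃X̃ᵀ)⁻¹X̃yᵀ` is kept
  as a test oracle only.  No regularization by default — the model is plain
  OLS.
* **Left and right targets** are fitted as independent coefficient vectors
  sharing one design matrix (and one factorization).
* **Model selection space:** all 2⁵ − 1 = 31 subsets of the five muscle
  pairs; every subset always includes both sides of each muscle (2–10
  channels).
* **Validation:** leave-one-patient-out.  Models are fitted on the
  concatenated trials of all other patients and applied to every trial of
  the held-out patient; the held-out patient's angular-velocity traces
  never enter the fit (asserted bit-exactly in the tests).

## Event extraction rules

On a 200 Hz angular-velocity trace, per leg:

* **SWP:** local maxima with amplitude ≥ 150 deg/s and ≥ 0.7 s separation.
  "Local maximum" means strictly greater than both neighbours; plateaus
  resolve to their first sample.  When two candidates violate the
  separation, the higher wins; at equal height the earlier.  Amplitude, not
  prominence, is thresholded (a prominence mode exists but is off by
  default); a polarity flag accommodates inverted sensor mounting.
* **Cycles:** consecutive SWP pairs.
* **HC:** earliest local minimum in the 10–45 % sub-interval of the cycle;
  if none exists, the sub-interval's global minimum.  **TO:** latest local
  minimum in 55–90 %, same fallback.  Sub-interval bounds round toward the
  cycle interior, so HC/TO are strictly inside the cycle.
* **Phases:** stance = [HC, next TO), swing = [TO, next HC); half-open
  intervals, the event sample belongs to the phase it initiates.  Samples
  before the first and after the last defining event are undefined.  The
  same conventions are applied to measured and reconstructed traces, so
  comparisons are unbiased.
* **Cycle statistics:** durations are successive SWP differences; cadence
  is 60000 / median duration (cycles/min); variability is the median
  absolute deviation (MAD) of durations from their median.

## Evaluation

Per trial and leg: Pearson r between measured and reconstructed traces over
their jointly finite span (reconstructions carry NaN in the embedding
margins); per event type, one-to-one matching of events < 600 ms apart,
greedy by ascending |Δt|.  Displacement is signed predicted − true
(summaries use absolute values, median and IQR).  FDR = false detections /
all detections; FNR = misses / all true events; across trials these are
pooled from counts, never averaged as rates.  Swing/stance series are
scored by sample-wise F1 with swing as positive class (stance and macro F1
are reported alongside).  Cross-correlograms evaluate each EMG channel at
the 21 embedding lags against an IMU trace, with two-sided p-values and
Bonferroni correction over a configurable family (default 420 = 10 muscles
× 21 lags × 2 sides).  Sign convention: r(τ) correlates `emg(t+τ)` with
`imu(t)`, so a *positive* peak lag means the EMG lags behind the IMU trace.

**Scope of the greedy-matching guarantee.**  Greedy nearest-pair matching
is not optimal assignment in general; on dense random event sets the two
can differ.  On jittered/deleted/inserted event *trains* — inter-event
spacing ~1.1 s, jitter well under the 600 ms tolerance, i.e. the structure
gait events actually have — greedy agreed with Hungarian-algorithm optimal
matching on every instance we sampled (thousands); the test suite asserts
this equivalence on that family.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline consumes, not
gait biomechanics:

* **Angular velocity** per leg is a piecewise half-cosine curve through
  per-cycle control points: swing peak (default 250 deg/s) at each cycle
  boundary, HC trough (−60 deg/s) planted exactly at 20 % of the cycle, a
  small mid-stance maximum (−10 deg/s) at 50 %, TO trough (−80 deg/s) at
  80 %.  Segments are strictly monotone and C¹, so the analytic extrema —
  the planted events — are exact, there are no flat stretches for noise to
  fake minima in, and stance (HC→TO, 60 % of the cycle) is the longer
  phase, as in real gait.  Cycle durations are nominal (per-patient, drawn
  from 1010–1140 ms) plus i.i.d. Gaussian jitter (20 ms default, putting
  the duration MAD in the 10–30 ms range typical of mildly impaired gait);
  the right leg runs half a cycle out of phase.
* **EMG** envelopes are either raised-cosine bursts phase-locked to the
  leg's own cycles (Vl near HC, Ta during swing, S/Gm/Gl during stance —
  the physiologically expected timings) or, in `linear_ground_truth` mode,
  exact affine functions of the leg's angular velocity delayed by
  muscle-specific on-grid lags (Vl at +150 ms, the empirically dominant
  same-side delay).  The envelope modulates a carrier: broadband Gaussian
  noise by default, or a deterministic 100 Hz tone in linear mode.  The
  tone is chosen so that after rectification the decimated 200 Hz samples
  hit the carrier extrema exactly (|cos(πk)| = 1), making
  rectify-and-smooth an identity on the envelope and enabling
  machine-precision recovery tests; the noise carrier reproduces the
  rectified-noise statistics of real surface EMG at the fidelity the
  pipeline needs.
* **Across-patient variability:** EMG gains ×U(0.7, 1.3), burst phases
  ±3 % of the cycle, angular-velocity amplitude ×U(0.85, 1.15), nominal
  cycle duration per patient — enough to make leave-one-patient-out
  non-trivial; per-recording normalization absorbs the gain differences,
  which is precisely the mechanism that lets a patient-agnostic linear
  model generalize.
* **Not emulated:** musculoskeletal dynamics, speed changes, freezing or
  festination episodes, electrode artifacts, crosstalk between muscles,
  turning-related asymmetries.  Passing tests therefore demonstrate the
  correctness of the *pipeline* under known structure, not clinical
  performance on real recordings.

Trials are emitted in the package's raw on-disk format with per-stream TTL
padding (EMG 0.8 s, IMU 0.3 s of sensor-noise floor) and walking bounds;
all randomness flows through one seeded generator, and identical seed and
configuration reproduce bit-identical files.

## Problem sizes and numerical tolerances

The quantitative recovery checks (test suite and `scripts/acceptance.py`)
use a cohort of 6 patients × 4 trials × 60 s — about 5 minutes of gait and
~1300 cycles per run, a deliberate desk-scale rendition of a clinical
session's structure (half-a-dozen patients, a handful of multi-minute
trials each).  Under linear ground truth at low noise (EMG sensor noise
0.02 a.u., IMU noise 2 deg/s) the bilateral-Vl decoder reaches held-out
median r ≈ 0.999 and F1 ≈ 0.98 with event displacements of 5–10 ms; the
guardrails asserted in the tests (r > 0.95, F1 > 0.9, displacement
< 60 ms, pooled FNR < 2 %) leave room for seed-to-seed variation while
still catching any structural regression.

Noteworthy tolerances: closed-loop event recovery is asserted within one
sample at 200 Hz (5 ms); the linear-mode envelope is asserted to match the
identically smoothed analytic oracle with < 0.1 % residual variance
(measured ~10⁻⁷–10⁻⁴), excluding the 5 s boundary zone of the truncated
moving-minimum window; OLS coefficients match the normal-equations oracle
to 10⁻⁸ relative (measured ~10⁻¹⁵).

## Known limitations

* The rule set presumes one positive swing peak per cycle; pathologies that
  flatten or split the peak (severe shuffling, festination) would defeat
  the SWP anchor and hence HC/TO extraction.
* The 10 s moving-minimum baseline needs trials comfortably longer than
  10 s and distorts the first/last 5 s of a stream; walking bounds should
  keep clear of the recording edges.
* Fixed embedding lags implicitly assume a roughly constant walking speed;
  applying a trained model to markedly different cadence would require
  rescaling the lag grid or retraining.
* The event-file format carries event times only; it does not preserve the
  detection context (cycle membership), which downstream code re-derives.
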