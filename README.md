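# emg2gait

Gait-event prediction from surface electromyography (EMG) by linear
reconstruction of shank angular velocity.

## The problem

Heel-contact (HC) and toe-off (TO) timings define the stance and swing
phases of walking and are usually measured with force plates, optoelectronic
systems or inertial measurement units (IMUs).  In clinical gait studies —
for instance in patients with Parkinson's disease walking unmedicated —
every extra sensor costs preparation time and patient comfort, while EMG
electrodes are often required anyway for their neurophysiological content.
`emg2gait` implements a two-step approach that makes the IMU dispensable at
application time:

1. **Reconstruction.** The angular velocity of each shank about the
   medio-lateral axis, `y(t)`, is approximated from temporally embedded EMG
   envelopes of up to five muscle pairs (tibialis anterior Ta, soleus S,
   gastrocnemius medialis Gm / lateralis Gl, vastus lateralis Vl).  Each
   envelope `x_m(t)` is augmented with K = 21 shifted copies
   `x̃_m(t) = [x_m(t+τ₁), …, x_m(t+τ_K)]ᵀ`, τ ranging from −500 ms to
   +500 ms in 50 ms steps.  With an offset term, the model is the ordinary
   least-squares regression

       y(t) = βᵀ x̃(t),   β_OLS = (X̃X̃ᵀ)⁻¹ X̃ yᵀ,

   fitted on a training cohort and applied to unseen patients without any
   per-patient calibration (leave-one-patient-out validation, LOPO).

2. **Event extraction.** A fixed rule set reads the (measured or
   reconstructed) trace: swing-peak events (SWP) are local maxima ≥ 150 °/s
   at ≥ 0.7 s separation; two consecutive SWP delimit a gait cycle; HC is
   the earliest local minimum in the 10–45 % sub-interval of the cycle and
   TO the latest local minimum in the 55–90 % sub-interval (global-minimum
   fallback in both cases).

Evaluation compares reconstructed against measured traces per trial and leg
(Pearson r), matches events within 600 ms (absolute displacement, false
discovery and false-negative rates), and scores the swing/stance
segmentation sample-wise (F1).

Because recordings of this kind are clinical data, the package ships a
first-class synthetic-data generator (`emg2gait.simulate`) that produces
paired raw EMG/IMU walking trials with analytically planted events and an
optionally *exactly linear* EMG→velocity relationship, so the entire
pipeline is testable end to end.

## Worked example

Simulate a small cohort, then evaluate the bilateral-Vl decoder under
leave-one-patient-out cross-validation:

```bash
emg2gait simulate --seed 42 --patients 3 --trials 2 --duration 40 \
    --linear --out demo/
# wrote 6 trials to demo

emg2gait lopo demo/P01_T01.csv demo/P01_T02.csv demo/P02_T01.csv \
    demo/P02_T02.csv demo/P03_T01.csv demo/P03_T02.csv \
    --muscles Vl --out demo/metrics.csv
# median r = 0.998, median F1 = 0.973 (12 trial-legs); wrote demo/metrics.csv
```

`median r` is the Pearson correlation between measured and reconstructed
angular velocity on held-out patients: 0.998 means the two-channel Vl model
reproduces the velocity profile almost perfectly under the simulator's
linear ground truth.  `median F1` scores the swing/stance segmentation
derived from the reconstructed events (swing as positive class).
`demo/metrics.csv` holds one row per trial and leg with r, F1 and, per
event type, the median/IQR absolute displacement in ms and the error rates
— in this run SWP displacements are ~5 ms with zero missed or spurious
events.

Other subcommands: `emg2gait preprocess`, `emg2gait events`,
`emg2gait train` / `emg2gait predict` (persist and reuse a fitted model),
and `emg2gait subsets` to rank all 31 bilateral muscle combinations.

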