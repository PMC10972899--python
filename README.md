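# crawlemg

EMG-based pattern recognition of inter-limb coordination in human hands-knees
crawling.

## The problem

Hands-knees crawling is a quadrupedal movement: within each crawling cycle the
four limbs — left palm (LP), right palm (RP), left knee (LK), right knee (RK) —
touch the ground in a characteristic order. A cycle runs from one LP touchdown
to the next, and the classical summary of coordination is the **ipsilateral
phase lag**

    IPL = (b / a) × 100 %

where *a* is the cycle duration and *b* the LP→LK touchdown lag: values near
0/100 % indicate pace gait (ipsilateral limbs paired), near 50 % trot gait
(diagonal limbs paired), near 25 %/75 % no-limb-pairing (sequence) gaits. The
IPL cannot separate modes that share a lag — trot (LP+RK → RP+LK) and the
sequential gaits LP→RP→LK→RK and LP→RK→LK→RP all sit at 50 % — so this package
implements a finer, eight-mode classification (M1–M8, defined by the full limb
landing order) from the timing of surface-EMG activation bursts across 30
limb and trunk muscles. A single left-palm pressure channel segments the
cycles; the classification feature is each cycle's EMG envelope, scaled to
unit variance per channel and resampled to 1,000 points.

The package is aimed at researchers in movement science and biomedical signal
processing who want a fully testable replica of this analysis. Because the
underlying human recordings are not public, a first-class synthetic cohort
generator emulates their statistical structure (per-speed cadence and
stance-fraction distributions, per-event timing jitter, participant-level
gains and phase idiosyncrasies, burst-like EMG), so every pipeline stage is
verifiable end to end.

## Pipeline

1. **synth** — synthetic trials: 30-channel EMG + left-palm pressure at
   1,000 Hz, with ground-truth limb timing.
2. **segment** — crawling-cycle detection from the pressure first derivative
   (stance onset at sustained positive crossings, swing onset at negative).
3. **features** — per-cycle envelope: high-pass 20 Hz → demean → rectify →
   low-pass 5 Hz (zero-phase Butterworth), unit-variance per channel,
   1,000-point cycle-length normalization.
4. **classify** — BiLSTM (from-scratch numpy implementation of the standard
   LSTM gate equations, trained with Adam), RBF-SVM and KNN.
5. **evaluate** — participant-specific / multi-participant (stratified 3-fold)
   and participant-independent (leave-one-participant-out) protocols,
   confusion matrices, t-SNE embeddings, per-speed duty-factor statistics
   (duty factor = stance/(stance+swing) × 100 %), and self-selected-mode
   proportions.
6. **gait / sigio / cli** — the mode catalog and IPL machinery, HDF5/CSV
   readers and writers, and a `crawlemg` command-line front end
   (`simulate`, `segment`, `featurize`, `train`, `evaluate`, `gait`,
   `self-selected`, `run-study`).

## Worked example

```python
from crawlemg import (SynthConfig, generate_cohort, build_dataset,
                      ClassifierSpec, run_protocol, summarize_gait,
                      compute_ipl, ideal_schedule)

cfg = SynthConfig()
trials = generate_cohort(cfg, n_participants=3, modes=["M1", "M2", "M3", "M4"],
                         speeds=["fast"], cycles_per_trial=6, seed=42)

sch = ideal_schedule("M4", cycle_duration=2.0, stance_fraction=0.7, n_cycles=3)
print(compute_ipl(sch.touchdowns("LP"), sch.touchdowns("LK")))

dataset = build_dataset(trials)                       # 72 cycles, 1000 x 30 each
result = run_protocol(dataset, "participant_independent",
                      ClassifierSpec(kind="svm"), speed="fast", seed=42)
print(f"SVM leave-one-participant-out accuracy: {result.mean_accuracy:.2f}%")
print(summarize_gait(trials).round(3))
```

prints

```
[75. 75. 75.]
SVM leave-one-participant-out accuracy: 100.00%
       n_cycles  stance_mean_s  stance_sd_s  swing_mean_s  swing_sd_s  duty_mean_pct  duty_sd_pct
speed
fast         72          1.048        0.111         0.719       0.108         59.339        4.796
```

The `[75. 75. 75.]` is mode M4's ideal IPL (its LK touchdown sits at
three-quarters of the cycle); the 100 % accuracy reflects that on a small
fast-speed cohort the four modes' burst-timing patterns are fully separable
even for unseen participants; and the recovered duty factor (59.3 %) matches
the fast-speed stance fraction the generator was configured with (59 %).

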