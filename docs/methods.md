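# Methods

## Coordination modes and gait statistics

Eight inter-limb coordination modes are represented as ordered event groups of
the four limbs {LP, RP, LK, RK}, with LP always opening the cycle. Ideal
schedules space the groups uniformly — halves for the two paired modes
(M1: LP+LK → RP+RK, pace; M2: LP+RK → RP+LK, trot), quarters for the six
sequence modes — which fixes each mode's ideal ipsilateral phase lag (IPL):
0 (≡ 100) for M1, 50 for M2/M3/M8, 75 for M4/M7, 25 for M5/M6 percent. The
IPL of a detected cycle is (LP→LK lag) / (LP→LP interval) × 100; because 0 and
100 label the same pace gait, distances to ideal values are computed modulo
100, which avoids a discontinuity for M1-like cycles at the cycle boundary.
IPL categorization is nearest-ideal over {0, 25, 50, 75, 100}; exact midpoints
(12.5, 37.5, 62.5, 87.5) break toward the larger ideal and raise a warning,
so the tie rule is explicit and symmetric. The duty factor of the stance phase
is stance/(stance+swing) × 100 %.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis exploits, not
the biophysics of EMG. Its defaults define the emulated study conditions:

| parameter | low | medium | fast | notes |
|---|---|---|---|---|
| cycle duration mean (s) | 3.5 | 2.33 | 1.75 | audio-prompted cadence (predefined modes) |
| cycle duration sd (s) | 0.25 | 0.16 | 0.12 | ~7 % of the mean; cadence sds are not reported, this is ordinary human cadence variability |
| stance fraction mean | 0.704 | 0.650 | 0.590 | from the reported per-speed duty factors |
| stance fraction sd | 0.0654 | 0.0532 | 0.0481 | from the reported duty-factor sds |

Self-selected trials use faster cadences (2.0/1.5/1.0 s per cycle) and draw
their executed mode per speed from a distribution dominated by trot (M2),
with the diagonal-sequence mode M3 mostly at fast speed.

Per cycle, duration and stance fraction are drawn from truncated normals;
every non-LP touchdown receives Gaussian jitter (sd 0.02 s) plus the
participant's systematic limb-phase bias, is clamped into its own cycle, and
draws violating the mode's landing order are resampled (generation aborts
after 100 failed attempts — the contract for physically unrealizable
parameter combinations). Participants differ by log-normal channel gains
(sigma 0.25), jitter magnitude, activation-burst width (FWHM 0.40 ± 0.05 of
swing duration) and a limb-phase bias with sd 0.05 cycle fractions, clipped
at ±2 sd so the instructed landing order stays realizable. The phase-bias
magnitude was calibrated so that leave-one-participant-out evaluation is
measurably harder than within-participant cross-validation — the protocol
effect the evaluation module is meant to expose — while all classifiers stay
far above the 12.5 % eight-class chance level.

Pressure is a plateau during LP stance with 50 ms linear ramps at touchdown
and liftoff plus clipped Gaussian sensor noise. Each EMG channel is
participant gain × (baseline white noise + a 20–450 Hz band-limited Gaussian
carrier amplitude-modulated by Gaussian bursts centred at mid-swing of the
channel's limb(s)). Seven channels serve each limb, and two trunk channels
are shared between diagonal limb pairs. Modes therefore differ in the
cross-channel *timing* of envelope bursts, never in marginal amplitude —
exactly the property the envelope feature encodes. Trials place the recorded
window between a lead-in and a lead-out cycle, because a participant is
already crawling when recording starts: without them, bursts belonging to
swings that begin before the first recorded LP touchdown (or end after the
last) are missing from the edge cycles, which turns those cycles into
classification outliers.

What the generator deliberately does not model: motor-unit action potentials,
volume conduction, muscle-synergy co-activation structure, fatigue, and
electrode artifacts. Passing tests therefore demonstrate that the pipeline
recovers timing structure under realistic cadence/jitter/participant
variability — not that any particular accuracy level transfers to real
recordings.

## Segmentation

The pressure first derivative is ideally zero within phases, positive at
swing→stance transitions and negative at stance→swing. Measured signals are
pre-smoothed with a 25 ms moving average; the derivative is thresholded at
10 % of its 99.5th-percentile magnitude (making detection invariant to
positive rescaling); candidate onsets must alternate stance/swing and be at
least 100 ms apart (debouncing). Events before the first stance onset are
discarded — every cycle starts at an LP touchdown — and the sequence is
truncated to end on a stance onset, so cycle *i* is the half-open sample
interval between stance onsets *i* and *i+1* and slicing partitions the
signal exactly. On noiseless synthetic pressure, detected onsets sit within
the transition ramp (+ smoothing window) of the true event times.

## Envelope features

Per trial: zero-phase 4th-order Butterworth high-pass at 20 Hz, demean,
full-wave rectification, zero-phase 4th-order low-pass at 5 Hz. Cutoffs are
conventional surface-EMG envelope settings; zero-phase filtering is essential
because burst *timing* is the discriminative feature. Filtering is applied to
the whole trial before slicing, which avoids per-cycle filter warm-up (a
single fast cycle is shorter than ten low-pass periods) and edge effects.
Each sliced cycle is then scaled to unit variance per channel, linearly
resampled onto a 1,000-point phase axis, and rescaled to unit variance —
interpolation perturbs variance slightly, and the feature contract is exact
unit variance (tolerance 1e-6). Normalization is per cycle, making each
sample self-contained for participant-independent evaluation. Zero-variance
channels are left at zero and flagged rather than producing NaNs. The
composed pipeline is invariant to positive per-channel gain on the raw EMG.

## Classifiers

The BiLSTM is implemented from scratch in numpy. A single unit follows the
standard gate equations (logistic gates, tanh candidate,
c_t = f∘c_{t-1} + u∘c̄_t, h_t = o∘tanh c_t); the network runs one LSTM over
the sequence and another over the reversed sequence, concatenates the two
final hidden states, and applies four dense layers (256-128-64-K by default,
rectifier nonlinearities, softmax output). Training is Adam with the default
hyperparameters: learning rate 0.001, beta1 0.9, beta2 0.999, epsilon 1e-8,
60 epochs, batch size one-tenth of the training-set size, 128 hidden units.
A single seed drives initialization and batch shuffling, so training is
deterministic. The analytic backpropagation-through-time gradient is verified
against central finite differences in the test suite, and the stacked-weight
layer is verified against the per-gate reference implementation. Tests and
smoke runs use reduced specs (16–32 hidden units, 20–40 epochs, sequences
strided to 50–100 steps) — sufficient for the separability checks they make —
while the spec defaults remain the full configuration.

SVM (RBF kernel, C = 1, one-vs-rest) and KNN (k = 5, Euclidean) operate on
each channel's envelope decimated to 100 of the 1,000 points and flattened
(3,000 dimensions); plain strided decimation is safe because the envelope is
band-limited at 5 Hz. Both are scikit-learn estimators behind the package's
train/predict surface.

## Evaluation protocols

Participant-specific: stratified 3-fold cross-validation within each
participant, fold accuracies averaged across participants. Multi-participant:
stratified 3-fold over the pooled cohort, stratifying jointly by mode and
participant (falling back to mode-only when cells are smaller than the fold
count). Participant-independent: leave-one-participant-out. Fold assignment
is seed-controlled; speed conditions are low/medium/fast/mixed (mixed pools
all speeds). Accuracy is the percentage of correctly identified samples; the
pooled confusion matrix conserves counts by construction. t-SNE embeddings
(seed-controlled, perplexity capped at (n−1)/3) are provided for
visualization; the self-selected analysis classifies "self" cycles with a
trained model and reports per-speed mode counts and percentages. The
per-speed ANOVA of protocol/classifier/speed effects is out of scope; the
emitted result tables contain everything needed to run it in any statistics
package.

## Problem sizes and numerical choices

The default synthetic study uses 10 virtual participants × 8 modes × 15
cycles per trial, matching the emulated study's scale; unit tests use smaller
cohorts (2–3 participants, 4–8 modes, 4–8 cycles, mostly fast speed) chosen
to exercise every contract at desk scale. Duty-factor recovery uses 120
segmented low-speed (or fast-speed) cycles and checks the recovered mean
against the configured mean within two standard errors plus half a percentage
point of segmentation granularity. Degenerate inputs fail loudly: flat
pressure, single touchdowns, zero-variance channels, single-class training
sets, infeasible protocols, and unrealizable landing orders all raise typed
errors with messages naming the stage.

## Known limitations

The EMG model is phenomenological; accuracies on synthetic cohorts are upper
bounds shaped by the generator's variability model, not predictions for real
recordings. Only the left palm carries a pressure sensor, so segmentation
assumes the LP cycle structure transfers to all limbs; per-limb stance
fractions are not independently modelled. The BiLSTM is CPU-bound numpy:
adequate at cohort scale, not optimized for large corpora.
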