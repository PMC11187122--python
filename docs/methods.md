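# Methods

`ictalert` implements a patient-specific EEG seizure prediction pipeline
built around transfer learning: a deep convolutional autoencoder (DCAE)
is pretrained, unsupervised, on a multi-patient source corpus; its
encoder is then reused — frozen — as the feature extractor of per-patient
preictal/interictal classifiers, whose per-window outputs are converted
into alarms by firing-power regularisation and scored with seizure
sensitivity (SS), false prediction rate per hour (FPR/h) and a surrogate
chance-level test. This note documents the model, the choices made where
the design was genuinely open, the synthetic test bed, and the scales at
which the shipped experiments run.

## Task timing: SOP, SPH and labels

All timing derives from two constants: the **seizure occurrence period**
(SOP, default 30 min) — the interval in which the predicted seizure is
expected — and the **seizure prediction horizon** (SPH, default 10 min) —
the minimum warning time. The preictal period is their sum (40 min
before onset). Windows are non-overlapping 10-s segments at 256 Hz;
window membership in any interval is judged by the window's *start* time
with half-open intervals, which is unambiguous for non-overlapping
windows.

Labelling per seizure, using only clinician-marked onsets:

- preictal: start in `[onset − (SOP+SPH), onset)`;
- excluded: overlapping `[onset, onset + 30 min]` (ictal + postictal);
- otherwise interictal.

Training uses only the 4 h before each training-seizure onset: the first
3 h 20 min as interictal (1200 windows when gap-free), the SOP span as
preictal (180 windows), and the final SPH discarded — an alarm there
would violate the minimum warning time, so those windows belong to
neither class. Inference is not restricted to the 4-h span.

**Leading seizures.** Only seizures whose onset is ≥ 4.5 h after the
previously kept onset enter the analysis (greedy scan, first seizure
kept). The gap is measured onset-to-onset because onset is the only
clinician-marked time available. Patients with fewer than three leading
seizures are flagged non-conformant.

**Splits.** Seizure-level and chronological: the first `ceil(0.6 n)`
seizures train, the rest test (ceil guarantees at least one test seizure
for n ≥ 3). Each test seizure's segment runs from 30 min after the
previous onset to its own onset. Within the training selection an 80/20
holdout (label-stratified, seeded) provides the early-stopping set. A
leakage assertion — no training window inside any test segment — runs on
every split.

## Architectures

The DCAE encoder is six Conv1D layers (kernel 5, stride 2, filters
32·32·64·64·128·128 by default), each followed by batch normalisation,
a swish activation (x·σ(x)) and spatial dropout (rate 0.2); total
temporal compression ×64, so a 2560-sample window becomes a 40-step
sequence of 128 feature channels. The decoder is three ×4 upsampling
steps interleaved with three Conv1D layers; the last one is linear,
since it reconstructs standardized (unbounded) signals. Strides and
upsampling factors must multiply to the same total, enforced at
configuration time. These layer hyperparameters are package defaults
chosen to satisfy the layer counts and exact shape restoration; all are
configurable.

The predictor stacks a bidirectional LSTM and a dense 2-way softmax on
the encoder. The BiLSTM runs over the encoder's 40 temporal steps
*within* one 10-s window: each window is classified independently, and
integration across windows is the firing-power stage's job. In transfer
mode the encoder weights come from the DCAE and are frozen — batch
normalisation then uses the running statistics learned on the source
corpus and dropout is off, i.e. the encoder is a fixed deterministic
feature map. In standard mode the whole network trains from scratch.

Weights travel as a `WeightBundle` (flat name → array mapping, byte-stable
single-file format) tagged with a hash of the encoder architecture;
loading into a mismatched architecture fails loudly and never partially.

## Training protocols

- **DCAE**: MSE reconstruction, Adam 3e-4, batch 2048, up to 2000 epochs,
  patience 200, 80/20 random holdout across all source windows.
  Standardization uses source-corpus statistics.
- **Predictor**: binary cross-entropy, Adam 3e-4, balanced batches of 64
  (32 per class; the minority class is oversampled with replacement, one
  epoch being one pass over the majority class — the simplest
  reproducible reading of "balanced batches"), up to 500 epochs,
  patience 50, five repeats with distinct recorded seeds, metrics
  averaged over repeats. Standard mode standardizes with the patient's
  training statistics; transfer mode with the source corpus statistics.

Early stopping monitors validation loss and restores the best epoch's
weights (restore-best strictly dominates last-epoch and is the standard
interpretation). Because a frozen encoder is deterministic, transfer
fits encode the training set once and iterate only the BiLSTM and
classifier — this is what makes full-length (500-epoch) fits affordable
on one CPU.

The neural-network layer is an in-package numpy engine (reverse-mode
autodiff; convolutions as one GEMM per kernel tap; the LSTM as a fused
forward/backward-through-time op, verified against an operator-composed
reference to 1e-9). Determinism: every random draw flows through
numpy's PCG64 generator from explicit seeds, so identical configurations
reproduce bit-identical runs on any platform.

## Alarms: firing power with gaps

The firing power at step n is the mean of the last τ classifier outputs,
τ = SOP / 10 s = 180. The probability output is used directly (for hard
0/1 decisions, threshold 0.5 coincides with "majority of preictal
windows in the moving window"; the probability retains more
information). The series is materialised on the nominal 10-s grid;
missing or invalid windows contribute 0 but occupy their calendar slot,
so a gap of ≥ τ steps drives fp to exactly 0. The first τ−1 steps are
flagged warm-up: their average runs over fewer than τ real slots and
never triggers.

An alarm fires when fp reaches the threshold (0.5) with the trigger
*armed*; the trigger starts armed, disarms on firing, and re-arms when
fp dips below the threshold. Alarms are additionally suppressed for one
refractory period (SOP + SPH = 40 min) after each alarm. Consequences:
a sustained plateau alarms exactly once, and a plateau that began during
warm-up alarms at the first eligible step. The re-trigger rule is a
design choice — the plateau case is underdetermined by a threshold rule
alone — and is locked in by oracle tests.

## Evaluation

An alarm at t is true iff some test onset lies in `[t+SPH, t+SPH+SOP]`
(the alarm gave at least SPH warning and the seizure arrived within
SOP). SS is the fraction of test seizures with ≥ 1 true alarm. FPR/h
divides false alarms by the interictal test duration minus the false
alarms' refractory time; interictal duration counts only valid recorded
time outside preictal spans, consistent with the gap-aware firing power.

**Chance level.** The surrogate test redraws each test onset uniformly
within its segment (≥ SOP+SPH from the segment start), re-scores the
*same* alarms, and repeats 19 times; the p-value is
`(1 + #{surrogate SS ≥ observed SS}) / 20`, rejecting at p ≤ 0.05.
Nineteen surrogates is the classical `1/α − 1` construction, which makes
the rank test exact at level α for continuous statistics; the observed
statistic is the mean SS over training repeats, which keeps ties rare.
A one-sample t-test of the observed value against the surrogate sample
was considered and rejected: under the exchangeable null it treats a
single draw as a population mean and its type-I error is far above
nominal (~0.38 analytically), while the rank test measures 0.03–0.04 on
the package's own null study (Poisson alarm processes, 300 synthetic
null patients). The surrogate procedure is a pure function of alarm
times and segments; it never reads the model.

**Approach comparison.** Per-patient repeat-mean SS and FPR/h are
compared between standard and transfer training with a one-tailed
Wilcoxon signed-rank test (α = 0.05, n ≥ 5 pairs; all-zero differences
return p = 1 with a warning).

## Synthetic EEG

Real presurgical EEG is not shareable, so the test bed is simulated with
the structural properties the pipeline relies on:

- background: per channel, the sum of four band-limited Gaussian
  processes (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz) with
  amplitudes ∝ 1/f of the band centre, scaled to 15 µV overall — the
  simplest model with an EEG-like decaying spectrum;
- structure: 19 channels (10–20 montage labels) at 256 Hz, ≥ 3 leading
  seizures ≥ 4.5 h apart, acquisition gaps (masked invalid), sparse
  0.3-s high-amplitude transients at a configurable hourly rate (left
  for the preprocessing stage to mask);
- preictal signature: over the 40 min before each onset the alpha-band
  component (extracted by a zero-phase band-pass) is re-added with a
  weight ramping linearly from 0 to `strength`, i.e. the alpha amplitude
  grows from ×1 to ×(1+strength) at onset.

The ramp shape, band and strength are simulation choices, not claims
about real preictal EEG — no statistical description of the source
patients' preictal changes is available. What passing tests show is that
the *pipeline machinery* works end to end: labels are recoverable (a
plain alpha-power threshold reaches AUC > 0.8 at strength 2, tested),
the models can learn the planted signature, and the alarm/evaluation
arithmetic is exact. They do not show that real preictal signatures are
detectable, that performance on clinical EEG would be similar, or that
transfer from a real multi-patient corpus behaves like transfer from
simulated background.

On-disk format is 16-bit EDF (one-second records, per-channel physical
ranges from the data; round-trip exact to one quantisation step) plus
CSV tables for onsets and gaps. The EDF writer is in-package; reading
goes through `mne`, which doubles as a conformance check.

## Experiment scales

Paper-scale protocol values (2000/200 and 500/50 epochs/patience, batch
2048, filters up to 128) are the defaults. The shipped experiments run
at a reduced scale chosen for one-CPU execution:

- the micro pipeline test: shrunken horizon (SOP 5 / SPH 2 min) and
  minutes-long recordings — exercises every stage and file contract;
- the learnability experiment (`ictalert.pipeline.transfer_smoke_run`):
  a 14-h patient with onsets at 4.6/9.2/13.8 h, strength-2 signature,
  encoder filters (8,8,16,16,32,32), BiLSTM width 24, interictal
  subsampled to 250 windows per training seizure, full 500-epoch
  transfer fits, two repeats per fit seed, three fit seeds. Expected
  behaviour: the held-out (third) seizure is predicted in most fits; an
  undertrained classifier characteristically alarms a minute or two
  inside the SPH and scores a false alarm instead.

Numerical details worth knowing: standardization floors the per-channel
sd at 1e-6 µV; windows are valid only if 100% of their samples are valid
(configurable), so gaps propagate conservatively to the alarm layer;
resampling is polyphase with an exact rational ratio requirement; the
band-pass is a 4th-order zero-phase Butterworth (0.5–100 Hz) plus a
Q=30 notch at 50 Hz, substituting the original study's learned
artifact-removal network — the downstream pipeline needs only a validity
mask, not a specific cleaner.

## Known limitations

- The synthetic signature is a single-band monotone amplitude ramp;
  real preictal dynamics (if present) are not represented.
- Ictal morphology is not modelled; only onset times matter downstream.
- The BiLSTM sees one window at a time; cross-window recurrence is out
  of scope by design (firing power already integrates across windows).
- With few test seizures per patient, SS is coarse and the surrogate
  rank test is conservative (discrete ties count against rejection).
- The numpy engine is CPU-only and sized for the reduced-scale
  experiments; paper-scale training is configuration-compatible but
  slow.
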