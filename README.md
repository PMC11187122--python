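# ictalert

Patient-specific EEG seizure prediction with autoencoder transfer
learning, firing-power alarm generation, and chance-level validation.

Seizure prediction models must be trained per patient, but seizures are
rare, so per-patient data is scarce. `ictalert` implements a transfer
learning remedy: a deep convolutional autoencoder (DCAE) is pretrained —
unsupervised — on multichannel scalp EEG from a multi-patient source
corpus, and its encoder is reused as a *frozen* feature extractor inside
each patient's classifier (encoder → bidirectional LSTM → softmax),
which labels every 10-s window as interictal or preictal. The package
compares this *transfer* approach against the *standard* approach
(identical network trained from scratch per patient), end to end on
synthetic EEG, since the clinical recordings such methods are developed
on cannot be shared.

The core quantities, for SOP = 30 min (seizure occurrence period) and
SPH = 10 min (prediction horizon, so the preictal period is 40 min):

- **Firing power** — the moving average of the classifier outputs
  *o*[*k*] over the last τ = SOP/10 s = 180 windows,

  fp[n] = (1/τ) Σ_{k=n−τ+1..n} o[k],

  with acquisition gaps counted as 0 so fp decays to zero across long
  gaps. An alarm fires when fp crosses 0.5 from below, followed by a
  40-min refractory period.
- **SS** (seizure sensitivity) = predicted test seizures / test
  seizures, where an alarm at *t* predicts an onset in
  [*t*+SPH, *t*+SPH+SOP].
- **FPR/h** = #FA / (interictal hours − #FA × refractory hours).
- **Surrogate validation** — seizure onsets are re-drawn uniformly
  within their test segments 19 times and the same alarms re-scored;
  a patient is above chance when the observed mean SS beats all 19
  surrogates (an exact rank test at α = 0.05).
- Standard vs transfer are compared with one-tailed Wilcoxon
  signed-rank tests on per-patient means.

Training follows a fixed protocol: leading seizures only (≥ 4.5 h
apart), the 4 h before each training onset (3 h 20 min interictal +
30 min preictal, SPH discarded), chronological 60/40 seizure split,
balanced batches of 64, Adam 3e-4, early stopping on an 80/20 holdout,
five repeats. Models run on an in-package numpy autodiff engine —
no GPU or deep-learning framework required.

## Worked example

Simulate one patient (three leading seizures, a strength-2 alpha-band
preictal signature), pretrain the DCAE on a synthetic source corpus,
fit the frozen-encoder classifier, and score the held-out seizure —
three times with independent fit seeds:

```python
from ictalert.pipeline import transfer_smoke_run

for r in transfer_smoke_run(seed=1, n_seeds=3):
    print(r)
```

```
{'seed': 74845286, 'ss': 1.0, 'fpr_h': 0.0, 'above_chance': False}
{'seed': 309580411, 'ss': 1.0, 'fpr_h': 0.0, 'above_chance': True}
{'seed': 1767258089, 'ss': 1.0, 'fpr_h': 0.0, 'above_chance': False}
```

Each line is one fit seed: `ss` is the sensitivity on the held-out test
seizure averaged over two training repeats (1.0 = both repeats raised a
correctly timed alarm, between 40 and 10 minutes before onset) and
`fpr_h` the false-alarm rate over the ~4-h test segment. `above_chance`
is the surrogate verdict; with a single test seizure the rank test has
little statistical power, so `False` alongside a perfect `ss` reflects
the small test set, not a missed seizure.

The same experiment is scriptable stage by stage from the shell
(`ictalert simulate / preprocess / pretrain / fit / predict / evaluate /
compare`), and `ictalert run-all --config cfg.yaml` runs a full
multi-patient standard-vs-transfer comparison from one YAML file,
writing per-patient reports, a comparison table, loss curves and the
DCAE weight bundle.

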