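# eegtcn

Subject-wise epilepsy detection from EEG with a self-attentive temporal
convolutional network, built entirely on a seeded synthetic-EEG simulator so
that every experiment is reproducible offline from a config file and one
master seed.

The package covers the full pipeline:

- **`eegtcn.synthetic`** — surrogate generator for 19-channel 500 Hz
  clinical-style recordings (healthy background vs. interictal spike-and-wave
  complexes with optional ictal bursts) and single-channel 173.61 Hz / 23.6 s
  benchmark-style records. Background is 1/f Gaussian noise plus narrowband
  oscillations; events are a biphasic sharp transient followed by a half-sine
  slow wave repeating at 3 Hz.
- **`eegtcn.preprocessing`** — zero-phase 1.6 Hz high-pass / 70 Hz low-pass /
  50 Hz band-stop filtering at the native rate, anti-aliased polyphase
  resampling to 100 Hz, non-overlapping 2 s (clinical) or 1 s (single-channel)
  windowing, and per-channel min-max scaling to [0, 1]. The resulting segments
  are 19×200 or 1×100.
- **`eegtcn.models`** — the classifier: stacked residual blocks of two
  weight-normalised causal dilated convolutions (level *i* uses dilation
  2^*i*; one layer spans d·(k−1) past samples), a single-head scaled
  dot-product self-attention layer with learned Q/K/V projections and a
  residual merge, global average pooling and a 2-unit softmax head. The
  reference configuration (kernel 4, 2 levels, width 164) counts exactly
  420,662 = 0.42 M trainable parameters. Baselines: plain TCN (no attention),
  attention-only network, and a standard non-causal CNN.
- **`eegtcn.nn`** — a compact numpy reverse-mode autodiff engine (dilated
  conv, batched matmul, softmax, fused cross-entropy, dropout, weight
  normalisation), gradient-checked against finite differences. No deep
  learning framework is required.
- **`eegtcn.training`** — group-stratified subject-level splitting
  (70/30 with a 20 % validation share), grouped k-fold cross-validation
  plans, a subject-leakage guard, and plain mini-batch SGD (lr 0.01,
  batch 12, cross-entropy) with deterministic seeding.
- **`eegtcn.evaluation`** — confusion matrices (EP positive), accuracy /
  sensitivity / specificity / precision / F1, threshold-sweep ROC with
  trapezoidal AUC, vertically averaged ROC across folds (mean ± sample std),
  per-participant segment accuracy with 0.8/0.9 threshold counts, and the
  cohort statistics (2×2 Pearson chi-square, Mann-Whitney U).
- **`eegtcn.io` / `eegtcn.cli`** — plain-text readers and writers
  (one-sample-per-line single-channel records; header + matrix tabular text
  for multichannel), a YAML experiment config, and a CLI.

## CLI

```sh
eegtcn count-params                      # reference model: 420662 (0.42 M)
eegtcn simulate   --config exp.yaml --out cohort/
eegtcn preprocess --in cohort/ --out segments/
eegtcn crossval   --config exp.yaml --model tcnsa --folds 5 --out run/
eegtcn evaluate   --pred scores.txt --labels labels.txt
```

`exp.yaml` sections mirror the dataclasses (`simulation`, `preprocessing`,
`model`, `training`, `evaluation`, plus `n_healthy`, `n_ep`, `model_kind`,
`seed`, `output_dir`); omitted keys take the reference defaults. A run writes
metrics (JSON + TSV), per-fold confusion matrices, averaged ROC points,
per-participant accuracies, training histories and a `run_info.json` with the
master seed, derived seeds and config hash — everything regenerable from the
config alone.

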