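# Methods

## Problem and model

The package predicts the sensitivity of a cancer cell line to a drug,
expressed as a normalized log-IC50, from two inputs only: the drug's
canonical SMILES string and a binary genomic profile of the cell line
(mutation states followed by copy-number alterations). No engineered
chemical descriptors are used; the drug is consumed as raw text.

A SMILES string is tokenized into chemical symbols — bracket atoms such as
`[nH]` or `[Au]` are single tokens, the two-letter halogens `Cl`/`Br`
outside brackets are single tokens, every other character stands alone —
and laid onto a binary symbol × position grid, left-aligned, right-padded
with a dedicated space token so every column activates exactly one row.
Token grouping matters because the drug branch convolves along the position
axis with each symbol row as a separate input channel: chemically atomic
symbols must occupy single rows for "convolution within one symbol" to be
meaningful. The vocabulary and grid width are always derived from the
corpus at hand (sorted lexicographically for reproducibility), never
hard-coded; on the full 223-drug GDSC panel they happen to be 72 symbols and
188 positions.

Two convolutional branches distil features independently and are fused by a
fully connected regressor:

* each branch stacks three layers of [conv width 7, stride 1,
  length-preserving padding] → ReLU → [max pool width 3, stride 3, ceiling
  output length], with 40, 80, 60 output channels;
* the cell branch treats the feature vector as one channel;
* flattened branch outputs (420 dims for a 188-column drug grid, 1680 dims
  for a 735-feature cell vector) are concatenated and passed through three
  1024-unit ReLU layers with dropout 0.5, ending in a single logistic
  output matching the (0, 1) label range.

The length-preserving ("same") convolution padding is a deliberate choice:
it is the unique standard padding convention under which the stack
reproduces the 420/1680 embedding widths (valid-padding arithmetic gives
different numbers). Hidden activations are rectifiers and the output is
logistic; these are conventional choices where no single convention is
forced by the architecture itself.

Labels are log-IC50 values x mapped into (0, 1) by y ↦ 1/(1 + y^(−0.1))
with y = e^x — equivalently the logistic function of 0.1·x. The exponent
−0.1 (configurable `alpha`) spreads the typically tiny molar IC50 values
more evenly over the unit interval. The closed-form inverse is provided for
reporting predictions on the log scale; the pair round-trips to below 1e−9
across the working range.

## Training

The loss is mean squared error, minimized with Adam. Training monitors RMSE
on a validation partition once per epoch and stops when it has not improved
for `patience_epochs` (default 10) consecutive epochs; the parameters from
the best-validation epoch are restored. All randomness (initialization,
batch order, dropout) flows from explicit seeds, so a run is exactly
repeatable.

The network, its layers and backpropagation are implemented directly on
NumPy (im2col convolution, ceiling max pooling with argmax scatter,
inverted dropout, Adam with bias correction). Gradient correctness is
pinned by central-difference tests; the check avoids inputs that put conv
pre-activations exactly on the ReLU kink (an all-zero input window with a
zero bias), where finite differences legitimately disagree with the
subgradient.

`TrainConfig` defaults (learning rate 1e−4, batch 128, up to 500 epochs)
are sized for a full-panel run. The shipped experiment profile
`experiments.DESK_TRAIN` (learning rate 1e−3, batch 64, up to 60 epochs,
150 warmup steps) is the package's desk-scale choice for the bundled
synthetic corpora, where the signal is strong and a higher learning rate
converges in a few epochs.

Aggressive learning rates expose a real failure mode of this
architecture: early Adam steps move every weight by roughly the full
learning rate irrespective of gradient magnitude, which can slam the
logistic output into saturation, where the squared-error gradient
vanishes and the run is dead from epoch one (constant predictions,
undefined Pearson correlation). `warmup_steps` linearly ramps the
learning rate from zero over the first optimizer steps and removes this
failure mode; it is off by default at the conservative full-panel rate
and on in the desk profile.

## Split protocols

Four protocols assign measured (drug, cell) pairs to train/validation/test:

* **pair** — pairs shuffled and cut 80/10/10 (floor for validation/test,
  remainder to train); drugs and cell lines may recur across partitions.
* **drug-blind / cell-blind** — whole entities held out: every pair of the
  sampled test entities is test, the rest split 90/10. The full-panel
  held-out counts 23/223 drugs and 94/948 cells are shipped as presets;
  because these two printed counts round a 10% fraction in opposite
  directions, the API takes an explicit entity count with
  round-to-nearest as the fraction fallback.
* **tissue-blind** — all pairs of one of the 13 tissue types held out;
  tissue types rather than the 49 sub-tissues, which keeps held-out sets
  large and dissimilar from training.

`validate_split` re-checks disjointness, membership and entity leakage and
is part of the public API, not only of the tests. Learning-curve
subsampling draws the first k pairs of one seeded ordering, so subsets at
nested fractions are nested — adjacent curve points then differ by data
volume only, not by sampling noise.

## Metrics

R² = 1 − SS_res/SS_tot, Pearson correlation (population moments), and
RMSE. Constant predictions leave Pearson 0/0 and are reported as NaN rather
than an error so the R² of a null model remains usable; zero label variance
raises. Repetition batteries are summarized by mean and 75th percentile
(linear interpolation).

## Synthetic corpus

The generator emits the exact CSV schemas the loaders consume, from a
planted generative model:

log-IC50(d, c) = baseline + Σ_m motif_effect·motif_present(d) +
Σ_k feature_effect·feature(c) + interaction·motif₁·feature₁ + N(0, noise_sd²).

Drug-side signal lives in short *contiguous* token motifs inserted into
random SMILES-like strings (and re-detected on the final string, so
accidental occurrences count identically) — a composition-level signal
would be learnable without convolution, whereas motifs specifically
exercise the pattern-matching the drug branch exists for. Noise is Gaussian
on the log scale, before normalization, where assay noise plausibly lives.

Defaults define the standard desk-scale study corpus: 60 drugs × 120 cells,
120 binary features (≈42% "mutations", the rest "copy-number" columns,
mirroring the 310/425 split of the full panel), SMILES of 20–60 tokens,
three motifs with effects (−2.5, 1.8, −1.2), six causal features with
effects ±(1.5, 1.0, 0.8), interaction strength 1.0, noise SD 0.25,
measured density 0.8 and below-max_conc probability 0.37 (matching the
81.4%/37% marginals of the real screen). Tissues cycle over six labels so
tissue-blind splits are exercisable.

What the corpus does **not** emulate: chemical validity of molecules,
realistic IC50 marginals or drug/cell correlation structure, feature
linkage disequilibrium, or heteroscedastic assay noise. Passing tests on
this corpus demonstrates that the pipeline recovers a recoverable signal
end to end and that the protocols rank as expected (entity-blind harder
than pair-level); it does not certify accuracy on real screening data.

## Experiments

The harness reproduces the evaluation battery as configured runs:
rediscovery (repeated pair splits), missing-pair prediction with per-drug
ranking by median predicted response, retraining on the below-max_conc
subset, drug/cell-blind batteries, leave-one-tissue-out, feature-count
reduction, encoding perturbations (symbol-row shuffle, position rotation,
position shuffle — one fixed seeded perturbation per run, applied before
training), and learning curves. Repetition seeds are `base_seed + index`
so any repetition is re-runnable in isolation; every run can write its
resolved configuration, per-repetition metrics and summary.

Shipped profiles use 5 repetitions (the full-scale battery used 50 for
rediscovery and 150 for blind tests) and the desk-scale corpus; the
acceptance battery trains with `max_epochs` 10 (6 for the 5-seed
protocol-comparison runs), which the strong planted signal makes ample.

## Numerical and degenerate-input choices

* Inputs longer than the grid width are rejected, not truncated.
* Duplicate (drug, cell) IC50 rows are an error naming the pair; duplicate
  drug rows keep the first occurrence; drugs without a SMILES mapping are
  dropped with a warning.
* The below-max_conc flag defaults to 1 when its column is absent;
  restricting to the flagged subset AND-combines it into the known mask and
  leaves values untouched.
* Ceiling pooling right-pads with −inf, so partial windows never invent
  values; every pooling window contains at least one real element.
* Checkpoints and serialized tables carry JSON manifests (configs, shapes,
  SHA-256 checksums) beside the raw arrays.

## Known limitations

* Single CPU, dense NumPy: full-panel training (172k pairs, 500 epochs) is
  out of desk scope, and the full-panel headline metrics are not
  reproduced here — they require the external screen download and long
  training.
* No hyperparameter search, ensembling or uncertainty estimation.
* The SMILES tokenizer assumes canonical input; it validates bracket
  balance only and does not canonicalize or verify chemistry.
* Pool width 2 (instead of 3) is configurable and tends to score higher at
  full scale but is known to destabilize training; the stable default is 3.
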