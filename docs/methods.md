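# Methods

## Model and training procedures

All classifiers here are single-hidden-layer feedforward networks scored as
`β h(ΩX − B)` with the classes-by-samples orientation (`X` is n×N, targets
`T` are m×N one-hot in {0,1}, `B = b·1ᵀ` tiles one bias per hidden neuron
across samples). Three trainers share this container:

* **ELM** — `Ω`, `b` i.i.d. uniform on `[a₁, a₂]` (default `[−1, 1]`), then
  `β = T H†` with `H = h(ΩX − B)`: the minimum-norm least-squares solution
  of `βH = T`. With the m×N target layout this is the transpose of the
  textbook `Hβ = T` convention; the fitted network is identical.
* **DPELM** — `β₀` (m×L) and `b` uniform on `[a₁, a₂]`; the input weights are
  solved analytically as `Ω = (h⁻¹(β₀†T) + B) X†`, then the output weights
  are refit as `β = T (h(ΩX − B))†`. The double solve is applied exactly
  once. `β₀` is re-drawn (up to 50 times, singular-value threshold 1e-10
  relative) until it has full row rank m whenever m ≤ L, because the
  derivation uses `β₀β₀† = I_m`; when L < m full row rank is unattainable and
  the draw is used as-is (the refit still minimizes the residual).
* **Voting ensembles** — K members trained with seeds
  `master_seed + 1 … master_seed + K`; prediction is the argmax of hard vote
  counts, ties to the smallest class index (a deterministic stand-in for the
  random tie-breaks sometimes used with voting ELMs; the rule is isolated in
  one argmax call). K defaults to 7 in the CLI; the single-model case is
  K = 1 and reduces exactly to the member's argmax-score rule.

Two regimes of the analytic solve matter:

* **Exact interpolation.** If `rank(X) = N ≤ n` and `rank(β₀) = m`, then
  `X†X = I_N` makes `ΩX = h⁻¹(β₀†T) + B` exact, so
  `β₀ h(ΩX − B) = β₀β₀†T = T` and the training residual is zero for *any*
  finite target matrix; the refit can only keep it at zero. The test suite
  checks this to 1e-6 relative over random instances up to n = 30.
* **Tall data (N ≫ n).** `Ω` is the least-squares solution of
  `ΩX = h⁻¹(β₀†T) + B`; the equality becomes an approximation and the second
  pseudo-inverse does the heavy lifting. Refit dominance — the refit residual
  never exceeds the `β₀` residual — holds unconditionally because the refit
  is itself a least-squares solve over the same hidden features.

## Activations

Registered invertible pairs: tan/arctan (default), sigmoid/logit,
tanh/artanh, sin/arcsin. The circular tangent is an unusual neural
activation; it is the default because its inverse is defined on all of ℝ, so
`h⁻¹(β₀†T)` needs no projection. (Hyperbolic tangent is registered for users
who prefer it.) Bounded-range activations clip the argument into the open
range shrunk by `clip_eps` (default 1e-6) of its width before inversion —
the minimal projection that keeps the solve computable; clipping never
triggers for tan. Forward evaluation of tan raises a domain error if an
entry lies within 1e-8 of an odd multiple of π/2. The trained-model forward
pass only evaluates tan on pre-activations the pipeline produced, which for
DPELM lie in the principal branch by construction.

A practical caveat the stability study exposes: with *random* input weights
(classical ELM) and unscaled features, pre-activations routinely cross tan's
poles and the hidden features degenerate to noise. This is a property of the
activation, not of either trainer, so comparative experiments on blob data
min-max scale features into [0, 1] first. The scaler is available
(`datasets.minmax_scale`) but off by default for user data.

## Data handling

Labels are one-hot in {0, 1} (the coding is isolated in `datasets.one_hot`
so a ±1 coding can be swapped in); classes are numbered by first appearance
in the file, which makes loading dialect-free and deterministic. Missing
values and unparseable cells are hard errors — no imputation. Stratified
splits apportion the requested training count across classes by largest
remainder (ties: larger remainder first, then smaller class index); with
class counts (357, 212) and 450 training samples this yields exactly
(282, 168) train and (75, 44) test — the split composition of the
benign/malignant diagnosis protocol. Non-stratified splits are a seeded
permutation. Either way both partitions must contain every class.

## Synthetic data

* **Teacher datasets** draw `X` (re-drawn until full column rank, which
  requires N ≤ n), a teacher network uniform on the interval, and emit
  targets exactly equal to the teacher's forward pass — the ground truth for
  interpolation and recovery tests. They carry real-valued targets, not
  one-hot labels.
* **Blob datasets** place m classes at `separation · u_c` for orthonormal
  directions `u_c` (pairwise 90°, satisfying the ≥ 60° spacing requirement;
  hence m ≤ n), add isotropic Gaussian noise `noise_sd`, near-equal class
  sizes (±1; explicit `class_sizes` override for imbalanced designs such as
  the 357/212 tumor composition), and shuffle sample order. At separation 50
  and unit noise a nearest-centroid rule is exact; at separation 0 the
  features carry no label information.

What these emulate — and what they do not: blobs are isotropic, linearly
separable-ish, noise-homogeneous clusters. Real clinical tabular data have
correlated features, heavier tails and label noise; passing tests on blobs
demonstrates the *algorithms* (fit, growth, voting, stability machinery),
not clinical performance. The diagnosis protocol is therefore exercised on a
synthetic stand-in, and real data must be supplied by the user as CSV.

## Model selection and evaluation

* **Growth**: hidden width grows from L = 1; the run stops once the
  improvement of the running-best validation accuracy has stayed below
  `threshold` (default 0.001) for `patience` (default 3) consecutive widths,
  or at `L_max`. The plateau wording leaves both knobs open; without
  patience a single flat step on a noisy validation curve would stop growth
  prematurely. `L_best` is the smallest width achieving the best accuracy
  seen. One seeded model per width (seed = base seed + L) keeps the sweep
  deterministic; a `repeats_per_L` knob averages over seeds when curves are
  noisy.
* **Repeated runs**: run r trains with master seed `base + 1000·r` and
  records test accuracy; summaries are the mean, *population* variance
  (divide by the number of runs; the sample convention is a one-line change)
  and range (max − min).
* **Diagnosis metrics**: per-class rate = class-conditional recall
  `cm[c,c] / row_sum(c)`; average accuracy = trace/total. A class absent
  from the test set yields NaN plus a warning, never a silent zero.
* **Diagnosis protocol** (`repeated_diagnosis_runs`): each of 20 runs draws
  a fresh stratified 450/119 split and a fresh training seed, then averages
  accuracy and per-class rates.

## The growth/stability study

`model_selection.blob_trend_study` compares the trainers under fixed,
pre-registered conditions: 20 master seeds; per seed a two-class blob task
(n = 8, N = 600, separation 2.5, noise 1.0, min-max scaled), split 400/200
train/test and the training part 300/100 for growth; growth with L_max = 40,
threshold 0.001, patience 3 on single models; then, at the fixed comparison
width L* = median ELM plateau width, 20 repeated trainings of the K = 7
voting ensembles per seed. Reported: median plateau widths per trainer and
the median (across seeds) of the per-seed run-to-run accuracy variances,
plus mean accuracies. Separation 2.5 puts the Bayes accuracy near 96 % — 
hard enough that hidden width matters, easy enough that both trainers learn.
The problem sizes keep the full study around two seconds on one CPU while
leaving the compared effects (plateau width, variance ratio ≈ 60×) far above
seed-to-seed jitter.

## Numerical choices

* Pseudo-inverse by SVD with a cutoff relative to the largest singular value
  (default rtol = 1e-12 × max(rows, cols)), so behaviour is scale-invariant
  and rank-deficient hidden matrices (L > N) are handled; computed via
  `numpy.linalg.pinv`, with the four Moore–Penrose conditions verified
  independently in the tests.
* Model and ensemble serialization is JSON with full-precision float repr,
  so a reloaded model predicts bit-identically.
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; every derived seed is an additive offset of the master seed.

## Known limitations

* No regularized/ridge or online variants; the double solve is applied once
  and the bias vector is never optimized (out of scope by design).
* Non-invertible activations (ReLU, thresholds) are incompatible with the
  analytic solve and deliberately unsupported.
* The circular-tan default requires sensible feature scales for the
  *classical* ELM baseline (see Activations above).
* The growth rule evaluates one model per width by default; very noisy
  validation curves may stop early — raise `patience` or `repeats_per_L`.
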