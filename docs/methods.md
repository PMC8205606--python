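# Methods

## Problem and data model

The task is five-level ordinal maturity grading of fresh tobacco leaves
(*unripe → mature → ripe → mellow → overmature*) from NIR reflectance,
with an independent discriminant model per stalk position (lower, middle,
upper). A leaf is measured at six spots; the per-wavelength arithmetic
mean of the spot spectra is the working spectrum. Averaging happens on raw
reflectance before preprocessing; `SpectrumRecord.mean_spectrum` exposes
it, and because every operator in the pipeline is row-wise this ordering
only matters for the nonlinear steps (SNV/MSC), where averaging first is
the stated acquisition convention.

The acquisition grid is 900–2500 nm at 3.125 nm. Under a half-open
convention [start, end) this is exactly 512 points; a closed convention
would give 513, so half-open is part of the format contract and
`make_grid` enforces divisibility of the range by the step to 1e−9.

## Preprocessing

Operators act on an `n × p` matrix, one spectrum per row:

- **Savitzky–Golay** (`sg_filter`): local least-squares polynomial
  fitting via `scipy.signal.savgol_filter`; derivatives are divided by the
  grid step so they carry reflectance/nm. `mode="valid"` keeps only points
  with a full fitting window, shortening rows by `window − 1`. The default
  pipeline uses window 59, polynomial order 2, first derivative, valid
  mode: the unique valid-mode window that maps the 512-point grid onto the
  classifiers' 454-point input. How the original workflow reduced 512
  acquisition points to 454 is not documented; this filter is our
  reconstruction, and window/order/mode are all configuration keys.
- **SNV**: per-row centering and scaling by the sample (n−1) standard
  deviation. The n−1 form is the package convention for all dispersion
  statistics (see Aggregation below); population scaling is available via
  `ddof=0`.
- **MSC**: ordinary least squares of each row on `[1, reference]`,
  corrected row = (x − a)/b. The reference is the training-set mean
  spectrum, fitted once and frozen for test rows (`msc_fit`/`msc_apply`,
  or an `msc` pipeline step). Slopes below 1e−12 in magnitude raise a
  non-correctable-spectrum error.
- **Normalization**: per-row affine map to [0, 1] (`minmax_norm`);
  unit-vector scaling exists under `unit_norm`. Normalization follows the
  derivative in the default pipeline.
- **PCA scores** center but do not scale columns, since all channels share
  reflectance units (scikit-learn full SVD solver).

The synthetic scatter model (below) is chosen so SNV, MSC and the first
derivative are its exact inverses at zero noise, which turns pretreatment
comparisons into directional tests rather than arbitrary rankings.

## Kennard–Stone partitioning

`train_size(n, f)` is round-half-up of `f·n`, computed in decimal
arithmetic on the printed value of `f` (binary floating point would turn
0.7·1085 = 759.5 into 759.4999…, losing the exact-half round-up). The
selector seeds with a globally farthest pair and then repeatedly adds the
candidate maximizing its minimum distance to the selected set. All ties
break to the lowest row index, making splits bit-identical across
platforms. Distances default to Euclidean on the preprocessed spectra
(`split.on = preprocessed|raw` in configs); when MSC is in the pipeline the
split-basis pipeline is fitted on all rows for the distance computation
only, and the modeling pipeline is refitted on the training rows so the
test set never leaks into the MSC reference.

## Classifiers

All five expose `fit(X, y)` / `predict(X)` and an NER convenience scorer,
and are interchangeable in the evaluation harness.

**1D CNN.** Implemented directly on numpy arrays, channels-last
`(batch, length, channels)`:

- valid-padding convolution by im2col (`sliding_window_view` + matmul),
  Xavier-normal weight initialization (σ² = 2/(fan_in + fan_out));
- batch normalization per channel over batch and length, then ReLU
  ("conv → BN → ReLU"). Inference uses moving statistics (momentum 0.9),
  seeded from the first training batch so short runs predict sensibly;
- max pooling with output length ⌊(L − size)/stride⌋ + 1 and optional
  multiplicative/additive pooling biases, identity (1, 0) by default; an
  optional global-max-pool layer exists but is off by default;
- flatten → dense(100, ReLU) → dense(n_classes) → softmax, trained by
  mini-batch Adam (lr 1e−3) on categorical cross-entropy. The optimizer,
  rate and loss are the community defaults for this architecture family
  and are configurable. Backward passes for every layer are hand-derived
  and checked against central-difference gradients in the test suite.

The default architecture is conv(128, k) → pool(2, 2) → conv(64, k) →
pool(1, 1) with k = 5 and a 454-point input, giving layer lengths
450/225/221/221 and a 14144-wide flatten (221 × 64). The published
parameter table is internally inconsistent — it prints kernel 13 × 1 and a
pool stride of 1 alongside output shapes that force kernel 5 and pool
stride 2 — so the default follows the printed shapes, whose flatten width
confirms them arithmetically; kernel 13 (the value selected by the tuning
sweep) is one argument away and equally tested. `cnn_output_shapes`
propagates shapes symbolically and is cross-checked against live tensors
for random architectures. Default training runs 300 epochs at batch 64
(the tuned values); tests and examples use far fewer epochs because the
synthetic benchmark saturates within ten.

**ELM.** Input weights and hidden biases ~ seeded uniform(−1, 1), hidden
layer `H = sigmoid(XW + b)`, output weights `β = pinv(H)·Y` on one-hot
targets. With hidden width ≥ the number of distinct training rows the
pseudo-inverse interpolates (training NER 100 %), and capacity is monotone
in width for nested weight draws — both tested.

**KNN.** Class score = Σ 1/(d + ε) over the k nearest neighbors of that
class, ε = 1e−12, so exact matches dominate; Euclidean or Mahalanobis
(pseudo-inverse of the training covariance) distances.

**BPNN.** One sigmoid hidden layer, sigmoid outputs, squared error on
one-hot targets, full-batch gradient descent, seeded Xavier-uniform
initialization. The baseline default learning rate is 1e−4; toy problems
(XOR) and the synthetic benchmark use a larger rate through the config,
since the conservative default needs very many epochs.

**SVM.** One-vs-one RBF soft margin, delegated to scikit-learn's SVC; the
package's contract is the decision rule and the powers-of-two tuning grid,
not the quadratic-programming solver.

## Evaluation

`NER = 100 × trace(C)/n` for the G × G confusion matrix C (true class on
the row). Reports round half-up to two decimals; full precision is kept
internally. Repeated runs aggregate to mean ± sample (n−1) standard
deviation — the n−1 form is used because it reproduces the published
summary (±0.26) from the corresponding per-run values, where the
population form would print 0.25. "Improvement" between models is relative
percent change 100·(a − b)/b, which matches the published comparison
arithmetic (96.18 vs 84.02 → 14.47 %). Deterministic models (KNN, SVM)
are single-run and report no sd.

Protocol drivers mirror the original experiments with sizes as arguments:
`compare_preprocessing` (450-sample subset, 2:1 split, 5 repeats by
default), `tune_cnn` (one-factor-at-a-time kernel → batch → epochs sweep
against 150 held-out validation samples, 5 repeats, best-mean value fixed
before the next factor, first value on ties), and `tune_baselines` (k by
stratified 10-fold CV; SVM C/γ by grid search over 2⁻¹⁰…2¹⁰ with the same
folds; ELM/BPNN hidden widths by one seeded validation split, smallest
width on ties). Tests exercise these at reduced sizes; the defaults are
the study's.

## Synthetic data

`simulate_dataset` draws, per spot scan,

    observed = b·pure(position, maturity) + a + c·(λ − mean λ) + ε

with `b ~ U(0.8, 1.2)`, `a ~ N(0, 0.05)`, `c ~ N(0, 1e−4)` and pointwise
`ε ~ N(0, 0.005)` by default, six spots per leaf, exact per-class counts.
`pure` is a sum of Gaussian bands whose centers sit on typical NIR
overtone regions (water ~970/1450/1940 nm, C–H ~1200/1700/2300 nm);
ripening is encoded as per-band center drift (up to ~18 nm across the five
levels) and amplitude change, with slightly shifted band libraries per
stalk position. This reproduces the *structure* the pipeline assumes —
smooth class-dependent curves under scatter — not leaf chemistry: there
are no real absorption line shapes, no instrument drift, no
class-imbalance or label noise. Passing tests therefore validate the
algorithms and their inverses, not field-level accuracy, and the published
field accuracies are deliberately not targets (the underlying data are
embargoed).

`easy_benchmark` is the canonical seeded fixture: one position, 56 leaves
per class (280 total, the study's per-position size scaled down about
four-fold so the suite runs in minutes on one CPU), maturity shifts tripled
and baseline drift reduced so that after SNV the class centroids are more
than ten times the within-class spread apart. Every classifier is required
to reach ≥ 95 % testing NER on it.

## Numerical conventions and edge cases

- Half-up decimal rounding everywhere a report prints two decimals
  (`round_half_up`, `decimal`-based).
- Constant rows raise degenerate-spectrum errors in SNV/min-max; MSC
  raises on near-zero regression slopes; pipelines propagate operator
  errors with the step index.
- Every stochastic component (ELM/BPNN/CNN initialization, batch
  shuffling, the generator, protocol subsampling) takes a seed through
  `numpy.random.default_rng`; `run_experiment` derives run seeds as
  `master_seed + run` and emits byte-identical reports for identical
  configs.
- CNN training validates input width and requires every class present in
  the training labels; divergence (non-finite loss) raises a training
  error rather than returning a broken model.

## Known limitations

- The CNN is CPU-bound numpy; it is meant for the ~10²–10³-sample,
  ~500-point regime of this workflow, not for large images or datasets.
- BPNN uses plain full-batch gradient descent (no momentum), faithful to
  the baseline description but slow at its 1e−4 default rate.
- The generator's band/scatter parameters are plausible but not fitted to
  any real leaf spectra; conclusions about pretreatment rankings on real
  data require real data.
- JCAMP-DX and other instrument formats are out of scope; CSV is the only
  interchange format.
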