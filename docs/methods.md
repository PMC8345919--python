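# Methods

## The evaluation protocol

The package measures how test-data normalization affects the external
validation of a two-group molecular classifier when the test data carry
handling effects. The performance measure is the pair
(Error_HE, Error_noHE): the misclassification error of a frozen classifier
on simulated test data with handling effects, and on the biologic-only
reference test data, both passed through the same normalization method. A
method performs well when Error_HE ≈ Error_noHE (no handling-induced
assessment bias) and Error_HE is small. Summaries report, per scenario and
method, the means of both errors across runs and the mean per-run
|Error_HE − Error_noHE|; the per-run absolute difference is used rather
than the difference of means because it is stricter (a method cannot cancel
positive and negative per-run bias) and has lower Monte-Carlo variance.

## Virtual rehybridization

The simulator assumes handling effects are **additive to biologic effects
on the log2 scale** — the standard working assumption for microarray data.
Given paired profiles of the same n samples (uniformly and nonuniformly
handled), biologic effects are the log2 uniformly handled values and the
handling effect of array j is `log2(nonuniform[, j]) − log2(uniform[, j])`.

Per scenario:

- **Sample split** — random 2:1 train:test, stratified by tumor group
  (128/64 at n = 192); re-drawn every run.
- **Array split** — nonrandom and fixed across runs: first ⌊n/3⌋ and last
  ⌊n/3⌋ arrays (collection order) train, middle block test. Handling
  effects are by nature irreproducible across datasets, so training and
  test handling effects must not be exchangeable.
- **Magnitude adjustment** — training handling columns get `+c`, test
  columns `×f`; settings high (2, 2), moderate (1, 1.5), slight (0.5, 1.25).
- **Allocation** — partial confounding assigns round(0.9 × half) arrays of
  the set's first (collection-order) half plus the complement from the last
  half to the favored group: 58 + 6 of 64-halves for training (favored:
  ovarian), 29 + 3 of 32-halves for test (favored: endometrial). The
  reversal of the favored group between training and test is what makes
  confounded handling actively misleading. Stratification splits each
  batch's arrays evenly between groups; leftover arrays of odd batches are
  distributed at random subject to exact group capacity. Within every
  stratum the concrete arrays and the array–sample pairing are uniform
  random. 90% of a half that is not a multiple of ten rounds to nearest
  (round-half-up), which preserves the group totals.
- **Composition** — simulated profile = biologic column + allocated
  handling column; the noHE reference is the biologic column alone.

Per-run seeds are `scenario_seed + run_index`, so any single run can be
reproduced bitwise without re-running its predecessors.

## Signal attenuation

Markers differentially expressed between the groups are flagged by a
two-sided Welch t-test on marker-level (replicate-median) log2 values at
raw P < .01 — no multiplicity correction, since the flagging step is meant
to capture the ~10% most separating markers, not to control an error rate.
For each flagged marker, half of the marker-level group-mean difference is
subtracted from every replicate probe in every sample of the
higher-expressing target group, leaving (1 − f) of the original difference
and reducing the significant fraction to the ~2% typical of classification
studies. The test statistic is configurable; Welch is the default because only the
significance threshold is fixed by the protocol and unequal-variance
robustness is the safer choice.

## Normalization methods

Preprocessing order is fixed: log2 → across-sample normalization at probe
level → marker-replicate summarization by the median. Training data use QN
(primary) or MN (alternative). The six test-data methods:

| method | parameters from | applied per sample? |
|--------|-----------------|---------------------|
| NN | — (identity) | — |
| MN | test set (median of per-sample medians) | shift only |
| QN | test set (mean of sorted columns) | needs the cohort |
| fMN | frozen: grand median of normalized training data | yes |
| fQN | frozen: reference quantile vector of normalized training data | yes |
| pQN | pooled QN of train + test columns, test columns returned | needs the cohort |

fMN/fQN honor the prospective-use contract: parameters come from training
data only and a single test sample can be normalized in isolation. QN ties
receive the mean of the reference values at the tied rank positions, and
fQN uses the same mapping, so fQN of a training column against its own
frozen model reproduces its QN values exactly. When a test matrix has a
different probe count than the frozen reference, fQN falls back to linear
interpolation of the reference empirical quantile function; with matched
probes the mapping is exact. pQN refits the pooled reference whenever test
data arrive, but the classifier is never refit.

## Classifiers

Nearest shrunken centroids is implemented from first principles:
`d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0))` with `m_k = sqrt(1/n_k − 1/n)`,
pooled within-class SD `s_i`, offset `s0 = median(s_i)`, soft-thresholded
`d′_ik`, shrunken centroids `x̄_i + m_k (s_i + s0) d′_ik` and discriminant
`δ_k(x*) = Σ_i (x*_i − x̄′_ik)²/(s_i + s0)² − 2 log π_k` with empirical
priors. Δ is tuned over 30 equally spaced values in [0, max|d_ik|] by
stratified 5-fold CV on misclassification error, ties broken toward the
largest Δ (sparsest model); the final model is refit on all training data.
Prediction ties break to the first class in label order.

The L1-penalized logistic alternative standardizes markers with training
means/SDs and delegates the solver to scikit-learn's liblinear; this
package owns the glmnet-style λ grid (100 log-spaced points from
`max|Xᵀ(y − ȳ)|/n` down by 10⁻⁴), the CV protocol, the sparsest-model tie
break and the 0.5 probability threshold. Grid points where the solver fails
to converge are skipped with a warning.

Both classifiers consume marker-level data only.

## The synthetic generator

`SyntheticSpec` emulates the paired study: 192 samples in two balanced
groups interleaved at random along the collection order, 3,523 markers with
10–40 replicate probes, batches 40/40/38/37/37 across technicians A (80
arrays) and B (112), slides of 8 arrays in a 2 × 4 layout.

Biologic effects are parametric: marker-level value
`~ Normal(μ_m + group·δ_m, σ_m²)` with `μ_m ~ U(4, 12)` log2 units,
`σ_m ~ U(0.3, 1.0)`; replicate probes add `Normal(0, 0.25²)` noise; 10% of
markers carry `|δ_m| ~ U(0.3, 0.9)·σ_m` with random sign. With n = 96/96
the Welch test at P < .01 detects roughly effects above 0.37σ, so ~9–10% of
markers are flagged before attenuation and ~2–3% remain significant after
halving — the same 10% → 2% structure as the motivating data.

Handling effects for an array in batch b are
`tech(b) + α_b + β_b·t_p + Normal(0, (γ_b τ)²)` per probe p: technician
offsets (0, 1.5) log2 units, batch location shifts `α_b ~ N(0, 0.9²)`,
probe trend `t_p ~ N(0, 1)` shared across batches with batch coefficients
`β_b ~ N(0, 0.04²)`, batch noise scales `γ_b ~ U(0.5, 1.5)` and τ = 0.06.
The uniform profile adds `Normal(0, 0.05²)` measurement noise. Magnitudes
were chosen once so that, under the high setting, the no-normalization
error lies in the intended 0.3–0.5 regime (realizations range roughly
0.16–0.38 at full size because the five batch shifts are random) and the
location/technician structure — which frozen methods remove and
test-anchored methods translate into a reference mismatch — dominates the
probe-level terms, as in real inter-batch array differences.

What the generator deliberately does **not** emulate: marker–marker
correlation (parametric simulation therefore yields lower absolute error
rates than empirically resampled effects), probe-sequence (GC) effects, and
within-slide spatial gradients. Passing tests on synthetic data establish
the pipeline's correctness and the qualitative method ranking
(fQN/fMN bias < pQN < QN/MN; Error_HE(fQN) < Error_HE(NN) under strong
confounded handling), not the real data's absolute error levels.

## Problem sizes

The default `SyntheticSpec` is full-size (3,523 markers, ~88k probes).
`benchmark_spec()` keeps the full study design — 192 samples, the 2:1/2:1
splits, the batch plan and all handling magnitudes — on a 2,000-marker
panel with 8–16 replicates (~24k probes), the package's standard problem
size for 100-run scenarios; one such scenario takes about four minutes.
Reducing the panel further weakens the attenuated signal enough that the
method ordering, while intact in expectation, is no longer sharply
separated run to run.

## Numerical and degenerate-input choices

- Missing values abort immediately with a count; the pipeline assumes
  complete matrices.
- log2 transform refuses nonpositive values (reports the first offending
  cell) and a scale flag guards against double transformation.
- QN requires ≥ 2 columns; MN/fMN/fQN accept a single column.
- Replicate summarization is vectorized per replicate-count class; a marker
  with zero probes is an error.
- NSC guards against zero pooled SDs through the `s0` offset; degenerate CV
  folds (single-class) are re-drawn up to five times before erroring.
- Stratification raises when the batch plan cannot meet group capacities;
  partial confounding raises when a quota exceeds the favored group's size.
- All allocation randomness flows through one per-run generator, so runs
  are reproducible bitwise from (scenario seed, run index).

## Known limitations

- Two classes only; no multi-class or survival endpoints.
- No complete-confounding design; no background correction or raw
  feature-extraction file parsing.
- Error_noHE for NN uses the untouched biologic reference; whether a
  validation study would normalize an idealized handling-free test set is a
  convention, and it is fixed here so that NN's reference is normalization-
  free by definition.
- The conventional QN of test data normalizes the full test cohort jointly;
  batch-wise test arrival is not modeled.
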