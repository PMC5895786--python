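# Methods

## The data model

Epigenomic signal tracks are organized as a third-order tensor `D` with
axes cell type (`j = 0..J−1`), assay (`k = 0..K−1`) and genomic bin
(`i = 0..I−1`). Tracks arrive as 4-column bedGraph on the −log10 p
scale, are averaged into constant-width bins (default 25 bp) with
base-pair-weighted means — bases covered by no interval count as signal
0 — and are then variance stabilized with `asinh(x) = ln(x + √(x²+1))`,
which behaves like a log for large signal but is defined at zero. The
transform is applied after binning and is never reversed for evaluation:
squared-error training and squared-error evaluation then share the same
Gaussian error model.

Missingness is strictly fiber-wise: an experiment (j, k) is either
present along the entire genome axis or absent. Cell types and assays
with fewer than `min_count` completed experiments (default 5) are removed
before modeling; because removing a cell type can strand an assay below
threshold, the filter iterates to a fixed point.

Observed experiments are split into `n_test` disjoint test sets (default
5) by a stratified draw — keys are shuffled by seed and dealt per cell
type to the test set with the lightest load on that assay, so per-cell
counts differ by at most one — and each test set's training keys are
further partitioned into `n_folds` validation folds (default 8). One
model is trained per fold; the final imputation is the element-wise mean
over fold models, with negative consensus values clamped to zero (they
are invalid on the −log10 p scale). The clamp is an output-formatting
rule, not part of the model; benchmarks on signed synthetic tensors
bypass it.

## The factorization and its objective

The model predicts entry (j, k, i) as
`Σ_l C[j,l]·A[k,l]·G[i,l] + c[j] + a[k] + g[i]`. The bias vectors absorb
per-axis offsets so the latent factors explain residual structure rather
than trivial scale differences. Training minimizes the squared error
over training entries plus `λ_C‖C‖² + λ_A‖A‖² + λ_G‖G‖²`; the biases are
unpenalized. There are no non-negativity or orthogonality constraints.

Stochastic gradients are exact per-entry gradients of this objective:
with residual `e = prediction − observation`, each factor row receives
`2e ×` (the elementwise product of the other two rows) and each bias
`2e`; the L2 term is apportioned as `2λ/n_row` per entry, where `n_row`
counts the training entries touching that parameter row, so the entry
gradients sum exactly to the batch gradient. This bookkeeping requires
every row to participate in training at least once — guaranteed in
practice by the min-support filter.

## Initialization

Factor matrices start i.i.d. uniform on (−0.33, 0.33). Biases start at
centered plane means: `c_j = μ_j − μ`, `a_k = μ_k − μ`, `g_i = μ_i`,
where `μ` is the global observed mean and `μ_j, μ_k, μ_i` the per-plane
observed means. Using raw plane means for all three vectors would
triple-count the global mean; this centering makes the bias-only
prediction equal the additive plane-mean estimate.

## The optimizer

Updates use Adam with a Nesterov look-ahead (the Nadam rule):

```
m ← β1_t·m + (1−β1_t)·grad        v ← β2·v + (1−β2)·grad²
m̂ = m / (1−Π_s β1_s)              v̂ = v / (1−β2^t)
θ ← θ − η_t · (β1_{t+1}·m̂ + (1−β1_t)·ĝ) / (√v̂ + ε)
```

where `ĝ` is the bias-corrected raw gradient and the corrections use the
running product of the scheduled β1 values. Both rates decay per update:
`η_t = η·φ_η^{t−1}`, `β1_t = β1·φ_β1^{t−1}` with `φ = 1−10⁻⁶`. The
schedule counter `t` is kept per parameter row (rows updated different
numbers of times sit at different points of the schedule), and ε = 10⁻⁸.
Limiting cases are unit-tested: with β1 = β2 = 0 a step reduces to
`η_t · sign(grad)`, and under a constant gradient the per-step
displacement converges to `η_t`.

## Training procedure

1. **Locus subset.** A seed-chosen fraction of loci (default 1 %) is used
   for the main phase. The 1 % default targets a genome-scale axis
   (~10⁶ bins); desk-scale benchmarks in this package use all loci.
2. **Burn-in.** One single-partition pass over a random half of the
   training entries restricted to at most `burnin_loci` (8000) loci
   updates all blocks, followed by a catch-up pass over every training
   entry updating only G and g. This gives the latent factors a
   consistent identity before parameter averaging starts.
3. **Parallel rounds.** Loci are divided into partitions of
   `partition_size` (default 1000). Each round, every partition receives
   copies of C, c, A, a and their optimizer state, performs `local_iters`
   (default 5000) single-entry updates on entries sampled with
   replacement from its own loci — its exclusively owned G, g rows are
   updated in place — and the shared blocks (and their Adam state,
   schedule counters included) are averaged element-wise over non-empty
   partitions. Each partition draws from its own seed-derived RNG
   stream, so a round is independent of processing order and the whole
   run is bit-reproducible; execution is sequential, the "parallel"
   contract being purely average-of-independent-local-updates.
4. **Recording and checkpointing.** Every `mse_record_every` (3) rounds
   the train/validation/test MSE is recorded (restricted to the training
   loci during the main phase); the parameters with the lowest
   validation MSE so far are checkpointed.
5. **Convergence.** With window size w = 6 records, a one-sided
   Mann–Whitney test (asymptotic, tie-corrected) asks whether the last w
   records plus a shift of 10⁻⁵ are stochastically greater than the
   preceding w; p < 0.05 declares convergence. A minimum number of
   rounds (default 50) must elapse per phase; the standalone detector
   enforces the minimum only when the caller supplies the elapsed-round
   count, so it can be used on bare series.
6. **Line search.** On convergence the model restarts from the best
   checkpoint with `η ← η/2` and `β1 ← β1 − (1−β1)`, up to
   `line_search_len` (3) times. The Adam state (moments and schedule
   counters) is reset at each restart and the recorded series restarts,
   so each phase converges on its own history. After the final restart
   converges (or `max_rounds` is reached) the main phase ends.
7. **Second-order genome solve.** With C, c, A, a frozen at the best
   checkpoint the objective is convex in the genome parameters, so
   (G_i, g_i) at every locus is obtained in closed form by ridge normal
   equations with penalty `λ_G2` on G_i only (the intercept g_i is
   unpenalized; it is re-fit jointly rather than preserved). Because
   missingness is fiber-wise the design matrix is shared across loci and
   one factorization solves the whole axis; rank-deficient unpenalized
   systems take the minimum-norm solution. Stationarity of the solved
   sub-problem (gradient max-norm < 10⁻⁶) is asserted in tests.

Default hyperparameters: η = 0.0045, φ_η = φ_β1 = 1−10⁻⁶, β1 = 0.9,
β2 = 0.999, L = 100, λ_C = 4.792, λ_A = λ_G = 8.757×10⁻²⁷,
λ_G2 = 0.4122. These are tuned values for a Roadmap-scale tensor
(127 cell types × 24 assays × ~1.3M bins) and are kept as defaults;
benchmark-specific choices are documented below.

## The additive baseline

The "main effects" model computes the global mean μ of all observed
entries, then per genome slice the row residuals
`r[j,i] = mean_k(D[j,k,i] − μ)` and column residuals
`q[k,i] = mean_j(D[j,k,i] − μ − r[j,i])`, and imputes
`μ + r[j,i] + q[k,i]`. Row residuals are computed first (the order is a
fixed convention; additive exactness holds either way): on any fully
observed tensor of the form `u_j + v_k + w_i` the imputation is exact,
which the tests assert to 10⁻¹⁰. Empty rows/columns in degenerate
fixtures get residual 0.

## Quality measures

All measures operate on asinh-transformed tracks. "Top 1 %" sets contain
the `max(1, round(0.01·N))` largest positions (round half-up), ties
broken by ascending index for determinism; whether the original analyses
used rank cutoffs or strict thresholds under ties is not documented, so
this deterministic convention is fixed here.

- MSEglobal — mean squared error over all positions;
- MSE1obs / MSE1imp — MSE over the top 1 % of positions ranked by
  observed / imputed signal (cross-ranking variants rank by another
  method's track);
- GWcorr — Pearson correlation (undefined for constant tracks, e.g. an
  all-clamped imputation; recorded as unavailable);
- Match1 / Catch1obs / Catch1imp — overlap fractions between top-ranked
  sets at 1 % and 5 % cutoffs;
- AucObs1 / AucImp1 / CatchPeakObs — ROC AUC (midrank tie handling) for
  recovering top-1 % observed, top-1 % imputed, or peak-called positions
  from the continuous ranking; peak calls come from BED intervals mapped
  to bins by ≥ 1 bp overlap.

Cross-method comparison reports, per measure, the Pearson correlation of
the two methods' per-experiment vectors and the mean and SD of natural
log ratios over experiments where both values are strictly positive
(others are excluded from the ratios, kept for the correlation, and
counted). Three-way comparisons are projected onto the ternary simplex,
`x′ = x/(x+y+z)` etc., so equal performance maps to (1/3, 1/3, 1/3).

## Synthetic data

The generator draws true factors i.i.d. uniform(−1, 1) and biases
uniform(−0.5, 0.5) — chosen so latent signal variance dominates the
default noise σ = 0.1 and recovery is testable — forms the model
prediction, and adds i.i.d. Gaussian(0, σ²) noise to observed fibers
only. The fiber mask holds exactly `round(observed_fraction·J·K)`
fibers and is sampled to keep at least `min_support` observed
experiments per cell type and assay (infeasible demands raise). Toy
peak calls label the top fraction of each noiseless fiber; bedGraph
emission writes raw-scale values (sinh of stored values for
asinh-tagged tensors) on a single synthetic chromosome `chrS`, so
binning plus the transform reproduces the tensor (exactly for raw
tensors, to ~10⁻⁹ through the sinh/asinh round trip).

What the generator does *not* emulate: peak-shaped signal with realistic
autocorrelation along the genome, heavy-tailed noise, cross-assay
correlation beyond the low-rank structure, or mappability artifacts.
Passing recovery tests therefore demonstrate that the estimator solves
the model's own inverse problem at realistic noise levels — not that
real epigenomes are low-rank.

## The recovery benchmark

`epitensor.experiments.parameter_recovery` generates a 30 × 12 × 2000
tensor of true rank 4 with σ = 0.1 and 40 % of fibers observed
(min-support 3), trains models with L = 8, partition size 250, and 1000
local updates per round for two validation folds of test set 0, and
scores the unclamped consensus on the held-out test fibers: mean MSE
against the noisy observations (floor σ² = 0.01) and the fraction of
fibers correlating r ≥ 0.9 with the noiseless truth.

Two deliberate desk-scale choices:

- the main phase uses **all loci** rather than a 1 % subsample (2000
  bins are already fewer than the ~13 000 a 1 % genome sample provides);
- a **uniform ridge of 4.792** (the published cell-type penalty) is
  applied to C, A, G and the genome refit. With the model rank above
  the true rank, fiber-wise completion is non-unique unless the excess
  rank is suppressed; the published near-zero assay/genome penalties
  are a dataset-specific tuning outcome and leave the synthetic
  completion unidentifiable. The value was calibrated with an
  independent alternating-least-squares probe of the same objective
  before the benchmark thresholds were exercised.

The validation partition keeps its default 8 folds, so each model trains
on 7/8 of the non-test fibers; "consensus of two folds" averages the
fold-0 and fold-1 models. Typical results (one CPU, ~40 s): held-out
MSE 0.01–0.03 and 95–100 % of fibers above r = 0.9.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.SeedSequence` lists keyed
  by the user seed plus fixed tags; identical (data, config, seed) give
  bit-identical models.
- A training fold with an empty partition skips it with a warning; an
  all-empty round raises. A locus with no observations gets G_i = 0,
  g_i = 0 with a warning.
- `local_iters = 0` turns burn-in and rounds into no-ops (the zero-
  iteration limit).
- The convergence test returns not-converged when all window records are
  identical (the rank-sum statistic is degenerate there).
- Tolerances asserted in tests: gradient vs finite differences, relative
  10⁻⁵; genome solve vs dense oracle, absolute 10⁻⁸; additive baseline
  exactness, 10⁻¹⁰.

## Known limitations

- Sequential execution only; the partition-averaging semantics are
  preserved but no actual concurrency is provided.
- bigWig input is out of scope (convert to bedGraph upstream); no
  liftover or assembly handling.
- Hyperparameter search (the original auto-tuning protocol) is out of
  scope; defaults are the published tuned values and transfer poorly to
  very small tensors, as the ridge discussion above illustrates.
- The main-effects baseline and the factorization share the evaluation
  stack, so comparisons are internally consistent, but no external
  method implementations are bundled.
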