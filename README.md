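# epitensor

Imputation of missing epigenomic signal tracks by tensor completion.

Consortium-scale epigenome mapping (ChIP-seq of histone modifications,
DNase-seq) produces a panel of genome-wide signal tracks indexed by cell
type and assay — but most (cell type, assay) pairs have never been
assayed. Arranged as a third-order tensor `D` of shape `J × K × I`
(cell types × assays × 25 bp genomic bins), the missing experiments are
whole fibers along the genome axis. `epitensor` fills those fibers in by
fitting a PARAFAC/CANDECOMP factorization with per-axis bias terms:

```
D[j,k,i] ≈ Σ_l C[j,l]·A[k,l]·G[i,l] + c[j] + a[k] + g[i]
```

with `C ∈ R^{J×L}`, `A ∈ R^{K×L}`, `G ∈ R^{I×L}` the cell-type, assay and
genome factor matrices, `c, a, g` additive biases that center each axis,
and `L` latent factors. The parameters minimize the squared error over
observed training entries plus L2 penalties `λ_C‖C‖² + λ_A‖A‖² + λ_G‖G‖²`
(biases unpenalized). Signal is variance-stabilized with the inverse
hyperbolic sine, `asinh(x) = ln(x + √(x²+1))`, before fitting, and all
evaluation stays on that scale.

The package is aimed at computational epigenomics groups who want to
impute, benchmark, or study this model without cluster infrastructure: it
contains the full training procedure (burn-in, partition-parallel SGD
with Adam/Nesterov momentum and element-wise parameter averaging,
rank-sum convergence detection, learning-rate line search, and a
closed-form second-order solve of the genome parameters), the additive
"main effects" baseline, ten imputation quality measures with
cross-method comparison statistics, and a seeded synthetic-tensor
generator so everything is testable end to end without downloads.

## Worked example

Generate a rank-3 synthetic tensor with Gaussian noise (σ = 0.1), train a
two-model consensus on one test split, and score a held-out experiment
against the additive baseline:

```python
import numpy as np
from epitensor import generate_tensor, make_splits, ParafacImputer, metrics
from epitensor.training import impute_consensus
from epitensor.main_effects import MainEffectsImputer

tensor, truth = generate_tensor(J=12, K=6, I=400, L_true=3, sigma=0.1,
                                observed_fraction=0.6, min_support=2, seed=4)
split = make_splits(tensor.observed_keys, n_test=5, n_folds=4, seed=4)

imputer = ParafacImputer(latent_factors=6, partition_size=100, local_iters=500,
                         training_locus_fraction=1.0, lam_C=2.0, lam_A=2.0,
                         lam_G=2.0, lam_G2=2.0, min_rounds=15, max_rounds=150,
                         line_search_len=1, n_folds=4, seed=4)
imputer.fit(tensor, split=split, test_id=0, folds=[0, 1])

test_keys = sorted(k for k, t in split.test_set.items() if t == 0)
pred = impute_consensus(imputer.models_, test_keys, clamp=False)
baseline = MainEffectsImputer().fit(
    tensor.restrict([k for k in tensor.observed_keys if split.test_set[k] != 0]))

key = test_keys[0]
rep = metrics.evaluate_experiment(pred[key], tensor.values[key])
rep_b = metrics.evaluate_experiment(baseline.predict_fiber(*key), tensor.values[key])
for m in ("MSEglobal", "GWcorr", "Match1", "AucObs1"):
    print(f"{m:10s} parafac={rep[m]:.4f} baseline={rep_b[m]:.4f}")
```

prints

```
MSEglobal  parafac=0.0996 baseline=0.1880
GWcorr     parafac=0.8173 baseline=0.5588
Match1     parafac=0.5000 baseline=0.2500
AucObs1    parafac=0.9949 baseline=0.9470
```

The factorization halves the baseline's mean squared error on this
held-out experiment, correlates at r = 0.82 with the observed fiber, and
recovers its top-1% positions almost perfectly (AUC 0.99). `Match1` is
the fraction of the top-1% observed positions that are also top-1% in the
imputation; on a 400-bin toy track that set has only four positions, so
its resolution is coarse. `clamp=False` keeps raw predictions — on real
−log10 p tracks the consensus clamps negative values to zero.

Larger tensors recover better: the benchmark in
`epitensor.experiments.parameter_recovery` (J=30, K=12, I=2000, true rank
4, 40 % of fibers observed) reaches a held-out-fiber MSE close to the σ²
= 0.01 noise floor with per-fiber r ≥ 0.9 on essentially all test fibers.

A command-line workflow covers the same ground for track files:
`epitensor simulate | prepare | split | train | impute | evaluate |
compare` (see `epitensor --help`).

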