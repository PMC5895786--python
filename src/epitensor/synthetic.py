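"""Seeded generator of low-rank-plus-biases tensors with fiber missingness.

The generator draws ground-truth factor matrices and bias vectors, forms
the model prediction at every (cell type, assay, locus), adds i.i.d.
Gaussian noise to the observed fibers, and samples a fiber mask that keeps
at least ``min_support`` observed experiments per retained cell type and
assay — exactly the statistical structure the factorization model assumes.
Toy peak calls and bedGraph tracks make the metric and I/O paths testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parafac import FactorModel
from .tensor import (
    ExperimentKey,
    GenomicBinIndex,
    ObservedTensor,
    SignalTrack,
    write_bedgraph,
    _experiment_filename,
)
from .metrics import top_fraction_set

_CHROM = "chrS"  # single synthetic chromosome for track emission


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated tensor: model, noise level, mask."""

    model: FactorModel
    sigma: float
    mask: list[ExperimentKey]
    seed: int

    def noiseless_fiber(self, j: int, k: int) -> np.ndarray:
        return self.model.predict_fiber(j, k)


def _sample_fiber_mask(rng, J, K, n_obs, min_support):
    """Fiber mask with >= min_support observed entries per row and column."""
    if n_obs > J * K:
        raise ValueError("observed fraction exceeds the grid size")
    chosen: set[tuple[int, int]] = set()
    # seed each row and column up to min_support before random fill
    for j in rng.permutation(J):
        ks = rng.permutation(K)
        for k in ks[:min_support]:
            chosen.add((int(j), int(k)))
    col_counts = np.zeros(K, dtype=int)
    for _, k in chosen:
        col_counts[k] += 1
    for k in np.flatnonzero(col_counts < min_support):
        need = min_support - col_counts[k]
        free = [j for j in range(J) if (j, k) not in chosen]
        for j in rng.permutation(np.array(free))[:need]:
            chosen.add((int(j), int(k)))
    if len(chosen) > n_obs:
        raise ValueError(
            f"min_support={min_support} needs {len(chosen)} fibers but only "
            f"{n_obs} requested; raise observed_fraction"
        )
    remaining = [
        (j, k) for j in range(J) for k in range(K) if (j, k) not in chosen
    ]
    extra = rng.permutation(len(remaining))[: n_obs - len(chosen)]
    for idx in extra:
        chosen.add(remaining[int(idx)])
    return sorted(chosen)


def generate_tensor(
    J: int = 30,
    K: int = 12,
    I: int = 2000,
    L_true: int = 4,
    factor_scale: float = 1.0,
    bias_scale: float = 0.5,
    sigma: float = 0.1,
    observed_fraction: float = 0.4,
    min_support: int = 3,
    seed: int = 0,
    bin_width: int = 25,
) -> tuple[ObservedTensor, SyntheticTruth]:
    """Generate an observed tensor from a known low-rank model plus noise.

    True factors are i.i.d. uniform(-factor_scale, factor_scale), biases
    uniform(-bias_scale, bias_scale); each observed fiber is the model
    prediction plus i.i.d. Gaussian(0, sigma^2) noise. The number of
    observed fibers is round(observed_fraction * J * K) exactly.
    """
    if not 0 < observed_fraction <= 1:
        raise ValueError("observed_fraction must lie in (0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA17]))
    model = FactorModel(
        rng.uniform(-factor_scale, factor_scale, size=(J, L_true)),
        rng.uniform(-factor_scale, factor_scale, size=(K, L_true)),
        rng.uniform(-factor_scale, factor_scale, size=(I, L_true)),
        rng.uniform(-bias_scale, bias_scale, size=J),
        rng.uniform(-bias_scale, bias_scale, size=K),
        rng.uniform(-bias_scale, bias_scale, size=I),
    )
    n_obs = max(1, int(round(observed_fraction * J * K)))
    mask = _sample_fiber_mask(rng, J, K, n_obs, min_support)
    values = {}
    for j, k in mask:
        clean = model.predict_fiber(j, k)
        noise = rng.normal(0.0, sigma, size=I) if sigma > 0 else 0.0
        values[(j, k)] = clean + noise
    bins = GenomicBinIndex.tile(_CHROM, I * bin_width, bin_width)
    tensor = ObservedTensor(
        [f"cell{j:03d}" for j in range(J)],
        [f"assay{k:02d}" for k in range(K)],
        bins,
        values,
        transform="asinh",
    )
    return tensor, SyntheticTruth(model, sigma, mask, int(seed))


def generate_peaks(truth: SyntheticTruth, top_frac: float = 0.05):
    """Binary peak labels: top-fraction bins of each noiseless fiber."""
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must lie in (0, 1)")
    peaks = {}
    I = truth.model.shape[2]
    for j, k in truth.mask:
        labels = np.zeros(I, dtype=int)
        labels[top_fraction_set(truth.noiseless_fiber(j, k), top_frac)] = 1
        peaks[(j, k)] = labels
    return peaks


def emit_tracks(tensor: ObservedTensor, directory) -> list[Path]:
    """Write one bedGraph per observed experiment on the synthetic chromosome.

    Values are written on the raw signal scale (sinh of the stored values
    when the tensor is asinh-transformed), so binning plus the transform
    reproduces the tensor.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    w = tensor.bins.width
    paths = []
    for j, k in tensor.observed_keys:
        vec = tensor.values[(j, k)]
        raw = np.sinh(vec) if tensor.transform == "asinh" else vec
        track = SignalTrack(
            tensor.bins.chroms[0],
            tensor.bins.starts,
            tensor.bins.starts + w,
            raw,
        )
        path = d / _experiment_filename(tensor.cell_types[j], tensor.assays[k]).replace(
            ".txt", ".bedGraph"
        )
        write_bedgraph(path, [track])
        paths.append(path)
    return paths
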