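"""PARAFAC factorization with per-axis biases: prediction, objective, gradients.

The model reconstructs tensor entry (j, k, i) as

    sum_l C[j,l] * A[k,l] * G[i,l] + c[j] + a[k] + g[i]

where C (J x L), A (K x L), G (I x L) are the cell-type, assay, and genome
factor matrices and c, a, g are additive bias vectors that center each
axis. Training minimizes the squared error over observed training entries
plus L2 penalties on the three factor matrices (the biases are not
penalized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .tensor import ExperimentKey, ObservedTensor


@dataclass
class RegularizationWeights:
    """L2 penalty weights for the factor matrices and the final genome solve."""

    lam_C: float = 4.792
    lam_A: float = 8.757e-27
    lam_G: float = 8.757e-27
    lam_G2: float = 0.4122

    def __post_init__(self):
        if min(self.lam_C, self.lam_A, self.lam_G, self.lam_G2) < 0:
            raise ValueError("regularization weights must be non-negative")


@dataclass
class FactorModel:
    """Factor matrices C, A, G and bias vectors c, a, g."""

    C: np.ndarray  # J x L
    A: np.ndarray  # K x L
    G: np.ndarray  # I x L
    c: np.ndarray  # J
    a: np.ndarray  # K
    g: np.ndarray  # I

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if not (self.C.shape[1] == self.A.shape[1] == self.G.shape[1]):
            raise ValueError("C, A, G must share the latent dimension L")
        if (
            self.c.shape != (self.C.shape[0],)
            or self.a.shape != (self.A.shape[0],)
            or self.g.shape != (self.G.shape[0],)
        ):
            raise ValueError("bias vector lengths must match factor matrix rows")
        for arr in (self.C, self.A, self.G, self.c, self.a, self.g):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters must be finite")

    @property
    def L(self) -> int:
        return int(self.C.shape[1])

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.C.shape[0], self.A.shape[0], self.G.shape[0])

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.C.copy(), self.A.copy(), self.G.copy(),
            self.c.copy(), self.a.copy(), self.g.copy(),
        )

    def predict_fiber(self, j: int, k: int, loci=None) -> np.ndarray:
        """Predict the genome vector of experiment (j, k) at the given loci."""
        G = self.G if loci is None else self.G[loci]
        g = self.g if loci is None else self.g[loci]
        return G @ (self.C[j] * self.A[k]) + self.c[j] + self.a[k] + g

    def save(self, directory, metadata: Mapping | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("C", "A", "G", "c", "a", "g"):
            np.savetxt(d / f"{name}.txt", getattr(self, name), fmt="%.17g")
        meta = {"L": self.L, "shape": list(self.shape)}
        if metadata:
            meta.update(metadata)
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "FactorModel":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        arrs = {n: np.loadtxt(d / f"{n}.txt", ndmin=1) for n in "CAGcag"}
        for n in "CAG":
            arrs[n] = arrs[n].reshape(-1, meta["L"])
        return cls(**arrs)


def predict_entry(model: FactorModel, j: int, k: int, i: int) -> float:
    """Model prediction for one tensor entry."""
    J, K, I = model.shape
    if not (0 <= j < J and 0 <= k < K and 0 <= i < I):
        raise IndexError(f"entry ({j}, {k}, {i}) out of range for shape {model.shape}")
    return float(
        np.dot(model.C[j] * model.A[k], model.G[i]) + model.c[j] + model.a[k] + model.g[i]
    )


def objective(
    model: FactorModel,
    tensor: ObservedTensor,
    train_entries: Iterable[tuple[int, int, int]],
    lam: RegularizationWeights,
) -> float:
    """Penalized squared-error objective over the training entries.

    Bias vectors carry no penalty; only the Frobenius norms of C, A, G do.
    """
    total = 0.0
    for j, k, i in train_entries:
        if (j, k) not in tensor.values:
            raise KeyError(f"training entry ({j}, {k}, {i}) is not observed")
        resid = tensor.values[(j, k)][i] - predict_entry(model, j, k, i)
        total += resid * resid
    total += lam.lam_C * np.sum(model.C**2)
    total += lam.lam_A * np.sum(model.A**2)
    total += lam.lam_G * np.sum(model.G**2)
    return float(total)


@dataclass(frozen=True)
class ParticipationCounts:
    """Per-row counts of training entries touching each parameter row.

    Used to apportion the L2 gradient across per-entry stochastic updates
    so that the entry gradients sum exactly to the batch gradient.
    """

    n_C: np.ndarray  # length J
    n_A: np.ndarray  # length K
    n_G: np.ndarray  # length I

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[int, int, int]], shape: tuple[int, int, int]
    ) -> "ParticipationCounts":
        J, K, I = shape
        n_C = np.zeros(J, dtype=np.int64)
        n_A = np.zeros(K, dtype=np.int64)
        n_G = np.zeros(I, dtype=np.int64)
        for j, k, i in entries:
            n_C[j] += 1
            n_A[k] += 1
            n_G[i] += 1
        return cls(n_C, n_A, n_G)


def entry_gradients(
    model: FactorModel,
    d_jki: float,
    j: int,
    k: int,
    i: int,
    lam: RegularizationWeights,
    counts: ParticipationCounts,
):
    """Exact gradient contribution of one training entry.

    With residual e = prediction - observation, the data term contributes
    2e * (partner product) to each factor row and 2e to each bias; the L2
    term is spread evenly over the entries touching each row, so summing
    over all training entries recovers the gradient of :func:`objective`.
    """
    if counts.n_C[j] <= 0 or counts.n_A[k] <= 0 or counts.n_G[i] <= 0:
        raise ValueError("participation counts must be positive for touched rows")
    e = predict_entry(model, j, k, i) - d_jki
    gC = 2.0 * e * (model.A[k] * model.G[i]) + (2.0 * lam.lam_C / counts.n_C[j]) * model.C[j]
    gA = 2.0 * e * (model.C[j] * model.G[i]) + (2.0 * lam.lam_A / counts.n_A[k]) * model.A[k]
    gG = 2.0 * e * (model.C[j] * model.A[k]) + (2.0 * lam.lam_G / counts.n_G[i]) * model.G[i]
    gb = 2.0 * e
    return gC, gA, gG, gb, gb, gb
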