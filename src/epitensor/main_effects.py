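"""Additive "main effects" baseline imputer.

The baseline decomposes each genome slice of the tensor additively: a
single global mean over all observed entries, a per-(cell type, locus) row
residual, and a per-(assay, locus) column residual computed against the
mean plus row residual. An entry is imputed as mu + r[j, i] + q[k, i].
On exactly additive data (u_j + v_k + w_i) this reproduces the tensor;
it serves as the comparison floor for the factorization model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .tensor import EmptyTensorError, ObservedTensor


class MainEffectsImputer(BaseEstimator):
    """Closed-form additive baseline: global mean + row/column residuals.

    Fitted attributes
    -----------------
    mu_ : float
        Global mean over all observed tensor entries.
    row_resid_ : (J, I) ndarray
        Per genome slice, mean of (D - mu) over observed assays for each
        cell type (0 where the cell type has no observation).
    col_resid_ : (K, I) ndarray
        Per genome slice, mean of (D - mu - row residual) over observed
        cell types for each assay (0 where empty).
    """

    def fit(self, tensor: ObservedTensor, y=None):
        if not tensor.values:
            raise EmptyTensorError("cannot fit main effects on an empty tensor")
        J, K, I = tensor.J, tensor.K, tensor.I
        self.mu_ = tensor.global_mean()
        row = np.zeros((J, I))
        row_n = np.zeros(J, dtype=np.int64)
        for (j, k), vec in tensor.values.items():
            row[j] += vec - self.mu_
            row_n[j] += 1
        nz = row_n > 0
        row[nz] /= row_n[nz, None]
        col = np.zeros((K, I))
        col_n = np.zeros(K, dtype=np.int64)
        for (j, k), vec in tensor.values.items():
            col[k] += vec - self.mu_ - row[j]
            col_n[k] += 1
        nz = col_n > 0
        col[nz] /= col_n[nz, None]
        self.row_resid_ = row
        self.col_resid_ = col
        self.shape_ = (J, K, I)
        return self

    def predict_entry(self, j: int, k: int, i: int) -> float:
        J, K, I = self.shape_
        if not (0 <= j < J and 0 <= k < K and 0 <= i < I):
            raise IndexError(f"entry ({j}, {k}, {i}) out of range for {self.shape_}")
        return float(self.mu_ + self.row_resid_[j, i] + self.col_resid_[k, i])

    def predict_fiber(self, j: int, k: int, loci=None) -> np.ndarray:
        """Imputed genome vector for experiment (j, k); defined for any pair."""
        J, K, _ = self.shape_
        if not (0 <= j < J and 0 <= k < K):
            raise IndexError(f"experiment ({j}, {k}) out of range")
        r = self.row_resid_[j] if loci is None else self.row_resid_[j, loci]
        q = self.col_resid_[k] if loci is None else self.col_resid_[k, loci]
        return self.mu_ + r + q


def fit_main_effects(tensor: ObservedTensor) -> MainEffectsImputer:
    return MainEffectsImputer().fit(tensor)


def impute_main_effects(model: MainEffectsImputer, j: int, k: int, i: int) -> float:
    return model.predict_entry(j, k, i)
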