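"""Imputation quality measures and cross-method comparison statistics.

All measures operate on the variance-stabilized (asinh) scale — the
transform is never reversed for evaluation. The panel covers global and
top-1% mean squared errors, genome-wide Pearson correlation, overlap
fractions between top-ranked position sets, and ROC areas for recovering
top-ranked or peak-called positions from a continuous ranking.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

MEASURE_NAMES = (
    "MSEglobal",
    "MSE1obs",
    "MSE1imp",
    "GWcorr",
    "Match1",
    "Catch1obs",
    "Catch1imp",
    "AucObs1",
    "AucImp1",
    "CatchPeakObs",
)


class UndefinedMeasureError(ValueError):
    """A measure is undefined for the given input (e.g. zero variance)."""


def top_fraction_set(values: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the max(1, round(frac*N)) largest values.

    Rounding is half-up; ties are broken by ascending index so the set is
    deterministic.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("top_fraction_set requires a non-empty vector")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = max(1, int(math.floor(frac * values.size + 0.5)))
    order = np.argsort(-values, kind="stable")  # ties keep ascending index
    return np.sort(order[:n])


def _check_lengths(imp, obs):
    imp = np.asarray(imp, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if imp.shape != obs.shape:
        raise ValueError(f"length mismatch: {imp.shape} vs {obs.shape}")
    return imp, obs


def mse_global(imp, obs) -> float:
    """Mean squared error over all available positions."""
    imp, obs = _check_lengths(imp, obs)
    return float(np.mean((imp - obs) ** 2))


def mse_top1(imp, obs, ranking, frac: float = 0.01) -> float:
    """MSE restricted to the top positions of a ranking vector.

    ranking = obs gives MSE1obs; ranking = imp gives MSE1imp; ranking by
    another method's track gives the cross-ranking variants.
    """
    imp, obs = _check_lengths(imp, obs)
    idx = top_fraction_set(np.asarray(ranking, dtype=float), frac)
    return float(np.mean((imp[idx] - obs[idx]) ** 2))


def gw_corr(imp, obs) -> float:
    """Genome-wide Pearson correlation of imputed and observed signal."""
    imp, obs = _check_lengths(imp, obs)
    if np.std(imp) == 0 or np.std(obs) == 0:
        raise UndefinedMeasureError("correlation undefined for constant vector")
    return float(np.corrcoef(imp, obs)[0, 1])


def overlap_catch(rank_a, rank_b, frac_a: float, frac_b: float) -> float:
    """Fraction of the top-frac_a set of a found in the top-frac_b set of b.

    Match1 = (obs, imp, 0.01, 0.01); Catch1obs = (obs, imp, 0.01, 0.05);
    Catch1imp = (imp, obs, 0.01, 0.05).
    """
    rank_a, rank_b = _check_lengths(rank_a, rank_b)
    set_a = top_fraction_set(rank_a, frac_a)
    set_b = top_fraction_set(rank_b, frac_b)
    inter = np.intersect1d(set_a, set_b, assume_unique=True)
    return float(inter.size / set_a.size)


def auc_recovery(labels, scores) -> float:
    """ROC AUC for recovering a binary label set from a continuous ranking.

    Equivalent to the normalized Mann-Whitney U statistic with midrank
    tie handling.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if labels.min() == labels.max():
        raise UndefinedMeasureError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def evaluate_experiment(imp, obs, peaks=None) -> dict[str, float | None]:
    """Assemble the full quality-measure panel for one experiment.

    ``peaks`` is an optional binary per-bin vector; CatchPeakObs is
    recorded as None when peaks are absent or single-class.
    """
    imp, obs = _check_lengths(imp, obs)
    top_obs = np.zeros(obs.size, dtype=int)
    top_obs[top_fraction_set(obs, 0.01)] = 1
    top_imp = np.zeros(imp.size, dtype=int)
    top_imp[top_fraction_set(imp, 0.01)] = 1
    try:
        corr = gw_corr(imp, obs)
    except UndefinedMeasureError:
        corr = None  # constant track (e.g. an all-clamped imputation)
    report: dict[str, float | None] = {
        "MSEglobal": mse_global(imp, obs),
        "MSE1obs": mse_top1(imp, obs, obs),
        "MSE1imp": mse_top1(imp, obs, imp),
        "GWcorr": corr,
        "Match1": overlap_catch(obs, imp, 0.01, 0.01),
        "Catch1obs": overlap_catch(obs, imp, 0.01, 0.05),
        "Catch1imp": overlap_catch(imp, obs, 0.01, 0.05),
        "AucObs1": auc_recovery(top_obs, imp) if top_obs.any() and not top_obs.all() else None,
        "AucImp1": auc_recovery(top_imp, obs) if top_imp.any() and not top_imp.all() else None,
    }
    if peaks is None:
        report["CatchPeakObs"] = None
    else:
        peaks = np.asarray(peaks)
        if peaks.min() == peaks.max():
            report["CatchPeakObs"] = None
        else:
            report["CatchPeakObs"] = auc_recovery(peaks, imp)
    return report


def compare_methods(
    report_a: Mapping[str, Mapping[str, float]],
    report_b: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Per-measure comparison of two methods across shared experiments.

    Reports the Pearson correlation of the per-experiment measure vectors
    and the mean and standard deviation of ln(mA/mB) over experiments
    where both values are strictly positive (others are excluded from the
    log ratios but kept for the correlation; the exclusion count is
    reported).
    """
    shared = sorted(set(report_a) & set(report_b))
    out: dict[str, dict[str, float]] = {}
    measures = set()
    for exp in shared:
        measures.update(m for m, v in report_a[exp].items() if v is not None)
    for measure in sorted(measures):
        pairs = [
            (report_a[exp].get(measure), report_b[exp].get(measure))
            for exp in shared
        ]
        pairs = [(x, y) for x, y in pairs if x is not None and y is not None]
        if len(pairs) < 3:
            raise ValueError(
                f"compare_methods requires >= 3 shared experiments for {measure}"
            )
        va = np.array([p[0] for p in pairs])
        vb = np.array([p[1] for p in pairs])
        if np.std(va) == 0 or np.std(vb) == 0:
            corr = 1.0 if np.array_equal(va, vb) else np.nan
        else:
            corr = float(stats.pearsonr(va, vb)[0])
        pos = (va > 0) & (vb > 0)
        ratios = np.log(va[pos] / vb[pos])
        out[measure] = {
            "corr": corr,
            "mean_log_ratio": float(np.mean(ratios)) if ratios.size else np.nan,
            "std_log_ratio": float(np.std(ratios)) if ratios.size else np.nan,
            "n_excluded": int(np.sum(~pos)),
        }
    return out


def ternary_project(x: float, y: float, z: float) -> tuple[float, float, float]:
    """Project a non-negative 3-vector onto the ternary simplex.

    Each coordinate is divided by the sum, so the output sums to 1; the
    all-equal point maps to the center (1/3, 1/3, 1/3) and points on a
    Cartesian axis map to the simplex corners.
    """
    if min(x, y, z) < 0:
        raise ValueError("ternary projection requires non-negative coordinates")
    s = x + y + z
    if s == 0:
        raise ValueError("ternary projection undefined for the zero vector")
    return (x / s, y / s, z / s)


def average_tracks(imp_a, imp_b) -> np.ndarray:
    """Element-wise mean of two imputed tracks."""
    imp_a, imp_b = _check_lengths(imp_a, imp_b)
    return (imp_a + imp_b) / 2.0


def peaks_to_labels(
    peak_intervals: Sequence[tuple[str, int, int]], bins
) -> np.ndarray:
    """Binary per-bin labels from peak intervals, by >= 1 bp overlap."""
    labels = np.zeros(len(bins), dtype=int)
    w = bins.width
    chroms = np.array(bins.chroms)
    for chrom, start, end in peak_intervals:
        on = chroms == chrom
        b = bins.starts[on]
        hit = (b < end) & (b + w > start)
        idx = np.flatnonzero(on)[hit]
        labels[idx] = 1
    return labels
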