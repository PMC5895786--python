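"""Signal-tensor data model: tracks, binning, filtering, and data splits.

Genome-wide signal tracks (one per completed cell type / assay experiment,
on the -log10 p scale) are averaged into fixed-width bins, variance
stabilized with the inverse hyperbolic sine, and assembled into a
J x K x I tensor (cell types x assays x genomic bins). Missingness is
always fiber-wise: an experiment is either present along the whole genome
axis or absent entirely. Coordinates are 0-based half-open (bedGraph
convention) throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ExperimentKey = tuple[int, int]  # (cell type index j, assay index k)


class EmptyTensorError(ValueError):
    """Raised when filtering or construction leaves no observed experiments."""


def asinh_transform(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)).

    A variance-stabilizing, log-like transform that is defined at zero and
    for negative values; applied to binned signal before model fitting.
    Scalars and arrays are both accepted.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("asinh_transform requires finite input")
    out = np.arcsinh(arr)
    return out if arr.ndim else float(out)


@dataclass(frozen=True)
class SignalTrack:
    """A sorted, non-overlapping set of scored intervals on one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        if not (starts.shape == ends.shape == values.shape):
            raise ValueError("starts, ends, values must have equal length")
        if np.any(ends <= starts):
            raise ValueError("intervals must satisfy end > start")
        if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError("intervals must be sorted and non-overlapping")
        if not np.all(np.isfinite(values)):
            raise ValueError("interval values must be finite")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_intervals(cls, chrom: str, intervals: Iterable[tuple[int, int, float]]):
        ivals = sorted(intervals)
        if ivals:
            s, e, v = (np.array(x) for x in zip(*ivals))
        else:
            s = e = v = np.array([])
        return cls(chrom, s, e, v)


@dataclass(frozen=True)
class GenomicBinIndex:
    """Ordered index of constant-width genomic bins; its length is I."""

    chroms: tuple[str, ...]
    starts: np.ndarray
    width: int = 25

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        if len(self.chroms) != starts.size:
            raise ValueError("chroms and starts must have equal length")
        if self.width < 1:
            raise ValueError("bin width must be positive")
        seen = set()
        prev = None
        for c, s in zip(self.chroms, starts):
            if (c, int(s)) in seen:
                raise ValueError("bin entries must be unique")
            seen.add((c, int(s)))
            if prev is not None and prev[0] == c and s <= prev[1]:
                raise ValueError("bins must be sorted within chromosomes")
            prev = (c, s)
        object.__setattr__(self, "chroms", tuple(self.chroms))
        object.__setattr__(self, "starts", starts)

    def __len__(self) -> int:
        return int(self.starts.size)

    @classmethod
    def tile(cls, chrom: str, length_bp: int, width: int = 25) -> "GenomicBinIndex":
        """Tile [0, length_bp) on one chromosome with full bins."""
        starts = np.arange(0, length_bp - width + 1, width, dtype=np.int64)
        return cls((chrom,) * len(starts), starts, width)


def bin_track(track: SignalTrack, bins: GenomicBinIndex) -> np.ndarray:
    """Average a track into bins, weighting by base pairs covered.

    Bases covered by no interval contribute value 0, so each bin value is
    sum(value * overlap_bp) / bin_width. Bins on chromosomes absent from
    the track get 0 with a logged warning.
    """
    out = np.zeros(len(bins), dtype=float)
    chrom_arr = np.array(bins.chroms)
    on_chrom = chrom_arr == track.chrom
    if not on_chrom.all():
        missing = sorted(set(chrom_arr[~on_chrom]))
        logger.warning(
            "bins on %s not covered by track on %s; set to 0", missing, track.chrom
        )
    idx = np.flatnonzero(on_chrom)
    if idx.size == 0 or track.starts.size == 0:
        return out
    bstarts = bins.starts[idx]
    w = bins.width
    for s, e, v in zip(track.starts, track.ends, track.values):
        lo = np.searchsorted(bstarts, s - w + 1, side="left")
        hi = np.searchsorted(bstarts, e, side="left")
        if hi <= lo:
            continue
        b = bstarts[lo:hi]
        overlap = np.minimum(e, b + w) - np.maximum(s, b)
        out[idx[lo:hi]] += v * overlap / w
    return out


@dataclass
class ObservedTensor:
    """The J x K x I signal tensor with fiber-wise missingness.

    ``values`` maps an observed (j, k) experiment key to its full length-I
    signal vector; an unobserved experiment simply has no entry.
    """

    cell_types: list[str]
    assays: list[str]
    bins: GenomicBinIndex
    values: dict[ExperimentKey, np.ndarray]
    transform: str = "asinh"

    def __post_init__(self):
        if not self.cell_types or not self.assays or len(self.bins) == 0:
            raise ValueError("tensor dimensions must all be >= 1")
        if self.transform not in ("raw", "asinh"):
            raise ValueError("transform must be 'raw' or 'asinh'")
        I = len(self.bins)
        for (j, k), vec in self.values.items():
            if not (0 <= j < self.J and 0 <= k < self.K):
                raise ValueError(f"experiment key {(j, k)} out of range")
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (I,):
                raise ValueError(
                    f"fiber {(j, k)} has length {vec.shape}, expected ({I},)"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"fiber {(j, k)} contains non-finite values")
            self.values[(j, k)] = vec

    @property
    def J(self) -> int:
        return len(self.cell_types)

    @property
    def K(self) -> int:
        return len(self.assays)

    @property
    def I(self) -> int:
        return len(self.bins)

    @property
    def observed_keys(self) -> list[ExperimentKey]:
        return sorted(self.values.keys())

    def global_mean(self) -> float:
        if not self.values:
            raise EmptyTensorError("tensor has no observed experiments")
        return float(np.mean([v.mean() for v in self.values.values()]))

    def restrict(self, keys: Iterable[ExperimentKey]) -> "ObservedTensor":
        """A view-like copy holding only the given observed experiments."""
        keys = set(keys)
        missing = keys - set(self.values)
        if missing:
            raise KeyError(f"keys not observed: {sorted(missing)}")
        return ObservedTensor(
            self.cell_types,
            self.assays,
            self.bins,
            {k: self.values[k] for k in keys},
            self.transform,
        )

    def stacked(self, keys: Sequence[ExperimentKey] | None = None) -> np.ndarray:
        """Observed fibers as an (n_keys, I) matrix, in key order."""
        keys = self.observed_keys if keys is None else list(keys)
        return np.array([self.values[key] for key in keys])


def filter_min_support(
    observed_keys: Iterable[ExperimentKey],
    n_cell_types: int,
    n_assays: int,
    min_count: int = 5,
) -> tuple[list[int], list[int]]:
    """Drop cell types/assays supported by too few experiments, to a fixed point.

    Removal of a weakly supported cell type can strand an assay below the
    threshold (and vice versa), so removal iterates until every retained
    cell type and assay has at least ``min_count`` observed experiments
    among the retained rows/columns of the availability grid.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    grid = np.zeros((n_cell_types, n_assays), dtype=bool)
    for j, k in observed_keys:
        grid[j, k] = True
    keep_j = np.ones(n_cell_types, dtype=bool)
    keep_k = np.ones(n_assays, dtype=bool)
    while True:
        sub = grid & keep_j[:, None] & keep_k[None, :]
        bad_j = keep_j & (sub.sum(axis=1) < min_count)
        bad_k = keep_k & (sub.sum(axis=0) < min_count)
        if not bad_j.any() and not bad_k.any():
            break
        keep_j &= ~bad_j
        keep_k &= ~bad_k
    if not keep_j.any() or not keep_k.any():
        raise EmptyTensorError("no cell types or assays survive min-support filter")
    return list(np.flatnonzero(keep_j)), list(np.flatnonzero(keep_k))


@dataclass
class SplitAssignment:
    """Test-set and validation-fold assignment of observed experiments.

    Each observed key belongs to exactly one of ``n_test`` disjoint test
    sets; for each test set, the remaining (training) keys are partitioned
    into ``n_folds`` validation folds.
    """

    test_set: dict[ExperimentKey, int]
    folds: dict[int, dict[ExperimentKey, int]]
    n_test: int
    n_folds: int
    seed: int

    def keys_for(self, test_id: int, fold: int):
        """Return (train, valid, test) key lists for one test set and fold."""
        test = sorted(k for k, t in self.test_set.items() if t == test_id)
        fold_map = self.folds[test_id]
        valid = sorted(k for k, f in fold_map.items() if f == fold)
        train = sorted(k for k, f in fold_map.items() if f != fold)
        return train, valid, test

    def to_frame(self):
        import pandas as pd

        rows = []
        for key, t in sorted(self.test_set.items()):
            for tid, fold_map in self.folds.items():
                if key in fold_map:
                    rows.append((key[0], key[1], t, tid, fold_map[key]))
        return pd.DataFrame(
            rows, columns=["cell_type", "assay", "test_set", "for_test_set", "fold"]
        )


def make_splits(
    observed_keys: Sequence[ExperimentKey],
    n_test: int = 5,
    n_folds: int = 8,
    seed: int = 0,
) -> SplitAssignment:
    """Stratified split of experiments into test sets and validation folds.

    Keys are shuffled with the seed, grouped by cell type, and dealt to
    test sets greedily (fewest-assigned first, preferring sets not yet
    holding the key's assay within this cell type), so that per-cell-type
    test-set counts differ by at most one. Validation folds then partition
    each test set's training keys round-robin into near-equal folds.
    """
    keys = sorted(set(observed_keys))
    if n_test < 2:
        raise ValueError("n_test must be >= 2")
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if len(keys) < n_test:
        raise ValueError("fewer observed keys than test sets")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    by_cell: dict[int, list[ExperimentKey]] = {}
    for key in keys:
        by_cell.setdefault(key[0], []).append(key)

    totals = np.zeros(n_test, dtype=int)
    assay_load = [dict() for _ in range(n_test)]  # test set -> assay -> count
    test_set: dict[ExperimentKey, int] = {}
    cell_order = sorted(by_cell)
    rng.shuffle(cell_order)
    for j in cell_order:
        group = by_cell[j]
        rng.shuffle(group)
        used = set()
        for key in group:
            k = key[1]
            # among test sets least-used within this cell type, prefer the one
            # with the lightest load on this assay, then the lightest overall
            candidates = [t for t in range(n_test) if t not in used]
            if not candidates:
                used.clear()
                candidates = list(range(n_test))
            t = min(
                candidates,
                key=lambda t: (assay_load[t].get(k, 0), totals[t], t),
            )
            used.add(t)
            test_set[key] = t
            totals[t] += 1
            assay_load[t][k] = assay_load[t].get(k, 0) + 1

    folds: dict[int, dict[ExperimentKey, int]] = {}
    for t in range(n_test):
        train_keys = [key for key in keys if test_set[key] != t]
        perm = list(train_keys)
        rng_t = np.random.default_rng(np.random.SeedSequence([int(seed), 1, t]))
        rng_t.shuffle(perm)
        folds[t] = {key: idx % n_folds for idx, key in enumerate(perm)}
    return SplitAssignment(test_set, folds, n_test, n_folds, int(seed))


# ---------------------------------------------------------------------------
# bedGraph and tensor-container I/O


def read_bedgraph(path) -> dict[str, SignalTrack]:
    """Read a 4-column bedGraph into one SignalTrack per chromosome.

    Track/browser lines and comments are ignored; no header is required.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            per_chrom.setdefault(chrom, []).append(
                (int(start), int(end), float(value))
            )
    return {
        chrom: SignalTrack.from_intervals(chrom, ivals)
        for chrom, ivals in per_chrom.items()
    }


def write_bedgraph(path, tracks: Iterable[SignalTrack]) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for s, e, v in zip(track.starts, track.ends, track.values):
                fh.write(f"{track.chrom}\t{s}\t{e}\t{float(v)!r}\n")


def _experiment_filename(cell_type: str, assay: str) -> str:
    safe = lambda s: "".join(c if c.isalnum() or c in "._-" else "_" for c in s)
    return f"{safe(cell_type)}__{safe(assay)}.txt"


def save_tensor(tensor: ObservedTensor, directory) -> None:
    """Write a tensor container: label files, bin index, manifest, arrays."""
    d = Path(directory)
    (d / "data").mkdir(parents=True, exist_ok=True)
    (d / "cell_types.txt").write_text("".join(c + "\n" for c in tensor.cell_types))
    (d / "assays.txt").write_text("".join(a + "\n" for a in tensor.assays))
    with open(d / "bins.bed", "w") as fh:
        for c, s in zip(tensor.bins.chroms, tensor.bins.starts):
            fh.write(f"{c}\t{s}\t{s + tensor.bins.width}\n")
    meta = {"transform": tensor.transform, "bin_width": tensor.bins.width}
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    with open(d / "manifest.tsv", "w") as fh:
        fh.write("cell_type\tassay\tfile\n")
        for j, k in tensor.observed_keys:
            name = _experiment_filename(tensor.cell_types[j], tensor.assays[k])
            fh.write(f"{tensor.cell_types[j]}\t{tensor.assays[k]}\t{name}\n")
            np.savetxt(d / "data" / name, tensor.values[(j, k)], fmt="%.17g")


def load_tensor(directory) -> ObservedTensor:
    d = Path(directory)
    cell_types = (d / "cell_types.txt").read_text().splitlines()
    assays = (d / "assays.txt").read_text().splitlines()
    meta = json.loads((d / "meta.json").read_text())
    chroms, starts = [], []
    for line in (d / "bins.bed").read_text().splitlines():
        c, s, _ = line.split("\t")
        chroms.append(c)
        starts.append(int(s))
    bins = GenomicBinIndex(tuple(chroms), np.array(starts), meta["bin_width"])
    values: dict[ExperimentKey, np.ndarray] = {}
    lines = (d / "manifest.tsv").read_text().splitlines()[1:]
    for line in lines:
        ct, assay, name = line.split("\t")
        key = (cell_types.index(ct), assays.index(assay))
        values[key] = np.loadtxt(d / "data" / name, ndmin=1)
    return ObservedTensor(cell_types, assays, bins, values, meta["transform"])
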