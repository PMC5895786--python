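"""Training procedure for the biased PARAFAC model.

The procedure mirrors a cluster-parallel SGD design but runs sequentially
and reproducibly: the genomic loci used for training are divided into
partitions; each round, every partition receives copies of the shared
cell-type and assay parameters (C, c, A, a), performs a fixed number of
single-entry Adam/Nesterov SGD updates on entries sampled from its own
loci (also updating its privately owned genome rows G, g), and the shared
parameters are then averaged element-wise across partitions. Training
starts with a single-partition burn-in pass so latent factors acquire a
consistent identity before averaging. Validation MSE is recorded
periodically; a one-sided rank-sum test on two recent windows detects
convergence, which triggers a restart-from-best "line search" with halved
learning rate and reduced first-moment weight. After the main phase the
cell-type and assay parameters are frozen and the genome parameters are
recomputed at every locus by a closed-form ridge least-squares solve (the
sub-problem is convex once C, A, c, a are fixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .parafac import (
    FactorModel,
    ParticipationCounts,
    RegularizationWeights,
)
from .tensor import EmptyTensorError, ExperimentKey, ObservedTensor, SplitAssignment

logger = logging.getLogger(__name__)

_BURNIN_TAG = 11
_ROUND_TAG = 12
_LOCI_TAG = 13
_INIT_TAG = 14


@dataclass
class TrainingConfig:
    """All hyperparameters of the model and optimizer.

    Defaults are the published tuned values for the Roadmap-scale tensor;
    ``max_rounds`` bounds the main phase for small-scale runs.
    """

    eta: float = 0.0045          # base learning rate
    phi_eta: float = 1 - 1e-6    # learning-rate decay per update
    beta1: float = 0.9           # Adam first-moment weight
    phi_beta1: float = 1 - 1e-6  # beta1 decay per update
    beta2: float = 0.999         # Adam second-moment weight
    adam_eps: float = 1e-8
    latent_factors: int = 100
    lam_C: float = 4.792
    lam_A: float = 8.757e-27
    lam_G: float = 8.757e-27
    lam_G2: float = 0.4122
    init_range: float = 0.33
    partition_size: int = 1000       # loci per partition
    local_iters: int = 5000          # local SGD updates per partition per round
    burnin_loci: int = 8000
    training_locus_fraction: float = 0.01
    mse_record_every: int = 3        # rounds between MSE records
    min_rounds: int = 50             # before convergence testing, per phase
    window_records: int = 6          # records per convergence window
    convergence_shift: float = 1e-5
    convergence_alpha: float = 0.05
    line_search_len: int = 3
    max_rounds: int = 2000           # hard cap on total parallel rounds
    n_folds: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("eta", "phi_eta", "beta1", "phi_beta1", "beta2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in (
            "latent_factors", "partition_size", "burnin_loci",
            "mse_record_every", "window_records", "n_folds", "max_rounds",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.lam_C, self.lam_A, self.lam_G, self.lam_G2) < 0:
            raise ValueError("regularization weights must be non-negative")
        if not 0 < self.training_locus_fraction <= 1:
            raise ValueError("training_locus_fraction must lie in (0, 1]")

    @property
    def regularization(self) -> RegularizationWeights:
        return RegularizationWeights(self.lam_C, self.lam_A, self.lam_G, self.lam_G2)


@dataclass
class AdamState:
    """First/second moment estimates and schedule counters for one block.

    ``t`` and ``beta1_prod`` are kept per row (per element for bias
    vectors) so that rows updated different numbers of times sit at
    different points of the decay schedule. Averaging states across
    partitions averages these counters too, which keeps the result
    independent of partition order.
    """

    m: np.ndarray
    v: np.ndarray
    t: np.ndarray
    beta1_prod: np.ndarray

    @classmethod
    def zeros_like(cls, param: np.ndarray) -> "AdamState":
        rows = param.shape[0]
        return cls(
            np.zeros_like(param, dtype=float),
            np.zeros_like(param, dtype=float),
            np.zeros(rows, dtype=float),
            np.ones(rows, dtype=float),
        )

    def copy(self) -> "AdamState":
        return AdamState(self.m.copy(), self.v.copy(), self.t.copy(), self.beta1_prod.copy())


def make_adam_states(model: FactorModel) -> dict[str, AdamState]:
    return {name: AdamState.zeros_like(getattr(model, name)) for name in "CAGcag"}


def schedule(t: int, eta: float, phi_eta: float, beta1: float, phi_beta1: float):
    """Decayed learning rate and first-moment weight at update count t (1-based)."""
    if t < 1:
        raise ValueError("schedule counter t must be >= 1")
    return eta * phi_eta ** (t - 1), beta1 * phi_beta1 ** (t - 1)


def adam_nag_step(
    param: np.ndarray,
    grad: np.ndarray,
    state: AdamState,
    eta_t: float,
    beta1_t: float,
    beta2: float,
    adam_eps: float,
    beta1_next: float | None = None,
) -> tuple[np.ndarray, AdamState]:
    """Apply one Adam/Nesterov update to a whole parameter block.

    ``beta1_next`` is the scheduled first-moment weight of the next update
    (the look-ahead weight); it defaults to ``beta1_t``.
    """
    param = np.asarray(param, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise ValueError("gradient must be finite")
    if beta1_next is None:
        beta1_next = beta1_t
    t_new = state.t + 1.0
    # per-row counters broadcast against 2-D moment arrays on the row axis
    expand = (lambda x: x[:, None]) if param.ndim == 2 else (lambda x: x)
    m = beta1_t * state.m + (1.0 - beta1_t) * grad
    v = beta2 * state.v + (1.0 - beta2) * grad * grad
    prod = state.beta1_prod * beta1_t
    denom = np.maximum(1.0 - prod, adam_eps)
    m_hat = m / expand(denom)
    g_hat = grad / expand(denom)
    v_hat = v / expand(1.0 - beta2 ** t_new)
    step = eta_t * (beta1_next * m_hat + (1.0 - beta1_t) * g_hat) / (np.sqrt(v_hat) + adam_eps)
    return param - step, AdamState(m, v, t_new, prod)


def split_mse(model: FactorModel, tensor: ObservedTensor, entries) -> float:
    """Mean squared residual of the model over an entry set (jj, kk, ii)."""
    jj, kk, ii, dd = entries
    if jj.size == 0:
        raise ValueError("split_mse requires a non-empty entry set")
    pred = (
        np.einsum("nl,nl->n", model.C[jj] * model.A[kk], model.G[ii])
        + model.c[jj] + model.a[kk] + model.g[ii]
    )
    return float(np.mean((pred - dd) ** 2))


def check_convergence(
    valid_mse_records: Sequence[float],
    config: TrainingConfig,
    rounds_elapsed: int | None = None,
) -> bool:
    """Rank-sum convergence test on two recent windows of validation MSE.

    With w = ``window_records``, window 1 is records [-2w:-w] and window 2
    is records [-w:]; training has converged when a one-sided
    Mann-Whitney test finds window 2 + ``convergence_shift`` stochastically
    greater than window 1 at level ``convergence_alpha`` (i.e. the MSE has
    stopped decreasing). ``min_rounds`` is enforced only when the caller
    supplies ``rounds_elapsed``.
    """
    w = config.window_records
    records = np.asarray(valid_mse_records, dtype=float)
    if records.size < 2 * w:
        return False
    if rounds_elapsed is not None and rounds_elapsed < config.min_rounds:
        return False
    window1 = records[-2 * w: -w]
    window2 = records[-w:] + config.convergence_shift
    if np.ptp(np.concatenate([window1, window2])) == 0:
        return False
    res = stats.mannwhitneyu(
        window2, window1, alternative="greater", use_continuity=False,
        method="asymptotic",
    )
    return bool(res.pvalue < config.convergence_alpha)


def line_search_restart(
    checkpoint: FactorModel, eta_current: float, beta1_current: float
) -> tuple[FactorModel, float, float]:
    """Restart from the best checkpoint with halved eta and reduced beta1.

    beta1_new = beta1_old - (1 - beta1_old); the caller also resets the
    Adam moment state.
    """
    if checkpoint is None:
        raise ValueError("line search requires a best checkpoint")
    return checkpoint.copy(), eta_current / 2.0, beta1_current - (1.0 - beta1_current)


# ---------------------------------------------------------------------------
# Second-order (closed-form) genome solve


def second_order_genome_solve(C, A, c, a, observations, lam_G2: float):
    """Ridge least-squares solution for one locus's genome parameters.

    ``observations`` is a sequence of (j, k, value). With x_jk = C_j * A_k
    (elementwise), minimizes sum (d - x_jk . G_i - c_j - a_k - g_i)^2 +
    lam_G2 ||G_i||^2 over (G_i, g_i); the intercept g_i is unpenalized.
    Rank-deficient unpenalized systems take the minimum-norm solution.
    """
    observations = list(observations)
    L = np.shape(C)[1]
    if not observations:
        logger.warning("no observations at locus; genome parameters set to 0")
        return np.zeros(L), 0.0
    jj = np.array([o[0] for o in observations])
    kk = np.array([o[1] for o in observations])
    y = np.array([o[2] for o in observations], dtype=float)
    X = np.asarray(C)[jj] * np.asarray(A)[kk]
    Z = np.column_stack([X, np.ones(len(y))])
    rhs = y - np.asarray(c)[jj] - np.asarray(a)[kk]
    theta = _ridge_solve(Z, rhs[:, None], lam_G2)[:, 0]
    return theta[:L], float(theta[L])


def _ridge_solve(Z: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (Z'Z + lam*diag(1..1,0)) Theta = Z'Y; min-norm when singular."""
    p = Z.shape[1]
    if lam == 0.0:
        return np.linalg.lstsq(Z, Y, rcond=None)[0]
    M = Z.T @ Z + lam * np.diag(np.r_[np.ones(p - 1), 0.0])
    B = Z.T @ Y
    try:
        return np.linalg.solve(M, B)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(M, B, rcond=None)[0]


def solve_genome_all_loci(
    model: FactorModel,
    tensor: ObservedTensor,
    train_keys: Sequence[ExperimentKey],
    lam_G2: float,
) -> None:
    """Second-order solve of G and g at every locus, in place.

    Missingness is fiber-wise, so the design matrix is shared by all loci
    and a single factorization imputes the whole genome axis.
    """
    keys = sorted(train_keys)
    if not keys:
        raise EmptyTensorError("genome solve requires training experiments")
    jj = np.array([j for j, _ in keys])
    kk = np.array([k for _, k in keys])
    X = model.C[jj] * model.A[kk]
    Z = np.column_stack([X, np.ones(len(keys))])
    D = tensor.stacked(keys)  # n_keys x I
    Y = D - (model.c[jj] + model.a[kk])[:, None]
    theta = _ridge_solve(Z, Y, lam_G2)  # (L+1) x I
    model.G[:] = theta[: model.L].T
    model.g[:] = theta[model.L]


# ---------------------------------------------------------------------------
# SGD kernel


def build_entries(tensor: ObservedTensor, keys: Sequence[ExperimentKey], loci: np.ndarray):
    """Flatten fibers x loci into parallel (jj, kk, ii, dd) arrays."""
    keys = sorted(keys)
    loci = np.asarray(loci, dtype=np.int64)
    n = len(keys) * loci.size
    jj = np.repeat([j for j, _ in keys], loci.size)
    kk = np.repeat([k for _, k in keys], loci.size)
    ii = np.tile(loci, len(keys))
    dd = np.concatenate([tensor.values[key][loci] for key in keys]) if n else np.array([])
    return jj.astype(np.int64), kk.astype(np.int64), ii, dd


class _SGDKernel:
    """Single-entry Adam/Nesterov SGD over flattened training entries.

    Operates in place on the arrays it is given; the caller controls
    which blocks (C/c/A/a vs G/g) are updated and supplies the entry
    visit order, so the same kernel serves burn-in, catch-up, and the
    partition-local rounds.
    """

    def __init__(self, model: FactorModel, states: dict[str, AdamState],
                 counts: ParticipationCounts, config: TrainingConfig,
                 eta: float, beta1: float):
        self.model = model
        self.states = states
        self.cfg = config
        self.eta = eta
        self.beta1 = beta1
        # per-row regularization gradient coefficients (2*lam / n_row)
        with np.errstate(divide="ignore"):
            self.reg_C = np.where(counts.n_C > 0, 2.0 * config.lam_C / counts.n_C, 0.0)
            self.reg_A = np.where(counts.n_A > 0, 2.0 * config.lam_A / counts.n_A, 0.0)
            self.reg_G = np.where(counts.n_G > 0, 2.0 * config.lam_G / counts.n_G, 0.0)

    def run(self, entries, order, update_ca: bool = True, update_g: bool = True):
        from ._kernels import sgd_entry_updates

        jj, kk, ii, dd = entries
        md, st = self.model, self.states
        cfg = self.cfg
        sgd_entry_updates(
            md.C, md.A, md.G, md.c, md.a, md.g,
            st["C"].m, st["C"].v, st["C"].t, st["C"].beta1_prod,
            st["A"].m, st["A"].v, st["A"].t, st["A"].beta1_prod,
            st["G"].m, st["G"].v, st["G"].t, st["G"].beta1_prod,
            st["c"].m, st["c"].v, st["c"].t, st["c"].beta1_prod,
            st["a"].m, st["a"].v, st["a"].t, st["a"].beta1_prod,
            st["g"].m, st["g"].v, st["g"].t, st["g"].beta1_prod,
            self.reg_C, self.reg_A, self.reg_G,
            jj, kk, ii, dd, np.asarray(order, dtype=np.int64),
            float(self.eta), float(self.beta1),
            cfg.phi_eta, cfg.phi_beta1, cfg.beta2, cfg.adam_eps,
            update_ca, update_g,
        )


# ---------------------------------------------------------------------------
# Initialization, burn-in, parallel rounds


def init_model(tensor: ObservedTensor, L: int, init_range: float = 0.33,
               seed: int = 0) -> FactorModel:
    """Random uniform factors plus plane-mean bias initialization.

    Biases start at the centered plane means (c_j and a_k relative to the
    global mean, g_i at the raw position mean) so the bias-only prediction
    already equals the additive plane-mean estimate.
    """
    if L < 1:
        raise ValueError("latent factor count must be >= 1")
    if not tensor.values:
        raise EmptyTensorError("cannot initialize from an empty tensor")
    J, K, I = tensor.J, tensor.K, tensor.I
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _INIT_TAG]))
    C = rng.uniform(-init_range, init_range, size=(J, L))
    A = rng.uniform(-init_range, init_range, size=(K, L))
    G = rng.uniform(-init_range, init_range, size=(I, L))
    mu = tensor.global_mean()
    c = np.zeros(J)
    a = np.zeros(K)
    g = np.zeros(I)
    cnt_j = np.zeros(J)
    cnt_k = np.zeros(K)
    for (j, k), vec in tensor.values.items():
        c[j] += vec.mean()
        cnt_j[j] += 1
        a[k] += vec.mean()
        cnt_k[k] += 1
        g += vec
    nz = cnt_j > 0
    c[nz] = c[nz] / cnt_j[nz] - mu
    c[~nz] = 0.0
    nz = cnt_k > 0
    a[nz] = a[nz] / cnt_k[nz] - mu
    a[~nz] = 0.0
    g /= max(len(tensor.values), 1)
    return FactorModel(C, A, G, c, a, g)


def burn_in(
    tensor: ObservedTensor,
    train_keys: Sequence[ExperimentKey],
    loci: np.ndarray,
    model: FactorModel,
    states: dict[str, AdamState],
    config: TrainingConfig,
) -> FactorModel:
    """Single-partition burn-in pass, then a genome catch-up pass.

    Half an epoch of single-entry SGD on a seed-chosen subset of at most
    ``burnin_loci`` training loci updates all parameter blocks; a second
    pass over every training entry then updates only G and g so the genome
    dimension reaches a comparable number of updates. A zero-iteration
    optimizer (``local_iters == 0``) disables both passes.
    """
    if len(train_keys) == 0:
        raise EmptyTensorError("burn-in requires training experiments")
    if config.local_iters == 0:
        return model
    loci = np.asarray(loci, dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _BURNIN_TAG]))
    n_burn = min(config.burnin_loci, loci.size)
    burn_loci = np.sort(rng.permutation(loci)[:n_burn])
    entries = build_entries(tensor, train_keys, burn_loci)
    counts = ParticipationCounts.from_entries(zip(*entries[:3]), model.shape)
    kernel = _SGDKernel(model, states, counts, config, config.eta, config.beta1)
    n = entries[0].size
    order = rng.permutation(n)[: n // 2]
    kernel.run(entries, order)
    # catch-up: genome parameters only, across all training loci
    all_entries = build_entries(tensor, train_keys, loci)
    counts_all = ParticipationCounts.from_entries(zip(*all_entries[:3]), model.shape)
    kernel_all = _SGDKernel(model, states, counts_all, config, config.eta, config.beta1)
    order_all = rng.permutation(all_entries[0].size)
    kernel_all.run(all_entries, order_all, update_ca=False, update_g=True)
    return model


def _average_states(states_list: list[AdamState]) -> AdamState:
    return AdamState(
        np.mean([s.m for s in states_list], axis=0),
        np.mean([s.v for s in states_list], axis=0),
        np.mean([s.t for s in states_list], axis=0),
        np.mean([s.beta1_prod for s in states_list], axis=0),
    )


def parallel_round(
    model: FactorModel,
    states: dict[str, AdamState],
    partitions: list[tuple],
    counts: ParticipationCounts,
    config: TrainingConfig,
    eta: float,
    beta1: float,
    round_index: int,
) -> None:
    """One round of partition-local SGD with element-wise parameter averaging.

    Each non-empty partition gets private copies of C, c, A, a (and their
    optimizer state), runs ``local_iters`` updates on entries sampled with
    replacement from its own loci — updating its exclusively owned G, g
    rows in place — and the shared blocks are replaced by the unweighted
    element-wise mean over partitions. Each partition draws from its own
    seed-derived RNG stream, so the result is independent of processing
    order.
    """
    results = []
    for p, entries in enumerate(partitions):
        n = entries[0].size
        if n == 0:
            logger.warning("partition %d has no training entries; skipped", p)
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _ROUND_TAG, int(round_index), p])
        )
        local_model = FactorModel(
            model.C.copy(), model.A.copy(), model.G,
            model.c.copy(), model.a.copy(), model.g,
        )
        local_states = {
            "C": states["C"].copy(), "c": states["c"].copy(),
            "A": states["A"].copy(), "a": states["a"].copy(),
            "G": states["G"], "g": states["g"],
        }
        kernel = _SGDKernel(local_model, local_states, counts, config, eta, beta1)
        order = rng.integers(0, n, size=config.local_iters)
        kernel.run(entries, order)
        results.append((local_model, local_states))
    if not results:
        raise EmptyTensorError("all partitions empty")
    for name in ("C", "A", "c", "a"):
        avg = np.mean([getattr(m, name) for m, _ in results], axis=0)
        getattr(model, name)[:] = avg
        states[name] = _average_states([s[name] for _, s in results])


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class TrainingLog:
    """Round-indexed MSE series plus best-checkpoint bookkeeping."""

    records: list = field(default_factory=list)  # (round, train, valid, test, eta, event)
    best_round: int | None = None
    best_valid: float = np.inf

    def add(self, round_index, train_mse, valid_mse, test_mse, eta, event):
        self.records.append(
            (int(round_index), float(train_mse), float(valid_mse),
             float(test_mse), float(eta), str(event))
        )

    @property
    def valid_series(self) -> list[float]:
        return [r[2] for r in self.records if r[5] == "round"]

    def best_so_far(self) -> list[float]:
        out, best = [], np.inf
        for r in self.records:
            if r[5] in ("round", "checkpoint"):
                best = min(best, r[2])
                out.append(best)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.records,
            columns=["round", "train_mse", "valid_mse", "test_mse", "eta", "event"],
        )


def train(
    tensor: ObservedTensor,
    split: SplitAssignment,
    test_id: int,
    fold: int,
    config: TrainingConfig,
) -> tuple[FactorModel, TrainingLog]:
    """Full training of one model for one (test set, validation fold).

    Selects the training-locus subset, initializes, burns in, then runs
    parallel SGD rounds with periodic MSE recording, best-validation
    checkpointing, convergence testing, and up to ``line_search_len``
    restarts; finally restores the best checkpoint, freezes C, c, A, a,
    and solves the genome parameters at every locus in closed form.
    """
    train_keys, valid_keys, test_keys = split.keys_for(test_id, fold)
    if not train_keys or not valid_keys:
        raise ValueError("training and validation key sets must be non-empty")
    cfg = config
    base_seed = np.random.SeedSequence([cfg.seed, int(test_id), int(fold)])
    derived = int(base_seed.generate_state(1)[0] % (2**31))
    cfg = TrainingConfig(**{**asdict(config), "seed": derived})

    I = tensor.I
    rng_loci = np.random.default_rng(np.random.SeedSequence([cfg.seed, _LOCI_TAG]))
    n_loci = max(1, int(round(cfg.training_locus_fraction * I)))
    loci = np.sort(rng_loci.permutation(I)[:n_loci])

    train_tensor = tensor.restrict(train_keys)
    model = init_model(train_tensor, cfg.latent_factors, cfg.init_range, cfg.seed)
    states = make_adam_states(model)
    log = TrainingLog()

    train_entries = build_entries(tensor, train_keys, loci)
    valid_entries = build_entries(tensor, valid_keys, loci)
    test_entries = build_entries(tensor, test_keys, loci) if test_keys else None
    counts = ParticipationCounts.from_entries(zip(*train_entries[:3]), model.shape)

    burn_in(tensor, train_keys, loci, model, states, cfg)
    log.add(0, split_mse(model, tensor, train_entries),
            split_mse(model, tensor, valid_entries),
            split_mse(model, tensor, test_entries) if test_entries is not None else np.nan,
            cfg.eta, "burnin")

    partitions = []
    for start in range(0, loci.size, cfg.partition_size):
        chunk = loci[start: start + cfg.partition_size]
        partitions.append(build_entries(tensor, train_keys, chunk))

    eta, beta1 = cfg.eta, cfg.beta1
    best_model = model.copy()
    log.best_valid = split_mse(model, tensor, valid_entries)
    log.best_round = 0
    restarts = 0
    phase_records: list[float] = []
    phase_start = 0

    for r in range(1, cfg.max_rounds + 1):
        parallel_round(model, states, partitions, counts, cfg, eta, beta1, r)
        if r % cfg.mse_record_every != 0:
            continue
        tr = split_mse(model, tensor, train_entries)
        va = split_mse(model, tensor, valid_entries)
        te = split_mse(model, tensor, test_entries) if test_entries is not None else np.nan
        log.add(r, tr, va, te, eta, "round")
        phase_records.append(va)
        if va < log.best_valid:
            log.best_valid = va
            log.best_round = r
            best_model = model.copy()
            log.add(r, tr, va, te, eta, "checkpoint")
        if check_convergence(phase_records, cfg, rounds_elapsed=r - phase_start):
            if restarts < cfg.line_search_len:
                model, eta, beta1 = line_search_restart(best_model, eta, beta1)
                states = make_adam_states(model)
                restarts += 1
                phase_records = []
                phase_start = r
                log.add(r, tr, log.best_valid, te, eta, "linesearch")
            else:
                break

    model = best_model.copy()
    solve_genome_all_loci(model, tensor, train_keys, cfg.lam_G2)
    all_loci = np.arange(I)
    final_train = build_entries(tensor, train_keys, all_loci)
    final_valid = build_entries(tensor, valid_keys, all_loci)
    final_test = build_entries(tensor, test_keys, all_loci) if test_keys else None
    log.add(
        log.records[-1][0] if log.records else 0,
        split_mse(model, tensor, final_train),
        split_mse(model, tensor, final_valid),
        split_mse(model, tensor, final_test) if final_test is not None else np.nan,
        eta, "final-solve",
    )
    return model, log


def impute_consensus(
    models: Sequence[FactorModel],
    keys: Sequence[ExperimentKey],
    loci=None,
    clamp: bool = True,
) -> dict[ExperimentKey, np.ndarray]:
    """Average predictions across fold models, clamping negatives to zero.

    Negative values are invalid on the -log10 p scale, so any negative
    consensus value is set to 0 in the final output; ``clamp=False``
    returns the raw averaged predictions (for signed synthetic data).
    """
    if not models:
        raise ValueError("impute_consensus requires at least one model")
    shape = models[0].shape
    if any(m.shape != shape for m in models):
        raise ValueError("all models must share tensor dimensions")
    out: dict[ExperimentKey, np.ndarray] = {}
    for j, k in keys:
        pred = np.mean([m.predict_fiber(j, k, loci) for m in models], axis=0)
        out[(j, k)] = np.maximum(pred, 0.0) if clamp else pred
    return out


class ParafacImputer(BaseEstimator):
    """Estimator wrapper: consensus PARAFAC imputation over validation folds.

    Parameters mirror :class:`TrainingConfig`; ``fit`` trains one model
    per requested validation fold of one test set and stores them, and
    ``predict`` returns the clamped consensus imputation.
    """

    def __init__(self, eta=0.0045, phi_eta=1 - 1e-6, beta1=0.9, phi_beta1=1 - 1e-6,
                 beta2=0.999, adam_eps=1e-8, latent_factors=100,
                 lam_C=4.792, lam_A=8.757e-27, lam_G=8.757e-27, lam_G2=0.4122,
                 init_range=0.33, partition_size=1000, local_iters=5000,
                 burnin_loci=8000, training_locus_fraction=0.01,
                 mse_record_every=3, min_rounds=50, window_records=6,
                 convergence_shift=1e-5, convergence_alpha=0.05,
                 line_search_len=3, max_rounds=2000, n_folds=8, seed=0):
        self.eta = eta
        self.phi_eta = phi_eta
        self.beta1 = beta1
        self.phi_beta1 = phi_beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.latent_factors = latent_factors
        self.lam_C = lam_C
        self.lam_A = lam_A
        self.lam_G = lam_G
        self.lam_G2 = lam_G2
        self.init_range = init_range
        self.partition_size = partition_size
        self.local_iters = local_iters
        self.burnin_loci = burnin_loci
        self.training_locus_fraction = training_locus_fraction
        self.mse_record_every = mse_record_every
        self.min_rounds = min_rounds
        self.window_records = window_records
        self.convergence_shift = convergence_shift
        self.convergence_alpha = convergence_alpha
        self.line_search_len = line_search_len
        self.max_rounds = max_rounds
        self.n_folds = n_folds
        self.seed = seed

    def _config(self) -> TrainingConfig:
        return TrainingConfig(**self.get_params())

    def fit(self, tensor: ObservedTensor, y=None, *, split: SplitAssignment | None = None,
            test_id: int = 0, folds: Sequence[int] | None = None):
        cfg = self._config()
        if split is None:
            from .tensor import make_splits

            split = make_splits(tensor.observed_keys, n_folds=cfg.n_folds, seed=cfg.seed)
        folds = list(range(cfg.n_folds)) if folds is None else list(folds)
        self.models_ = []
        self.logs_ = []
        for fold in folds:
            model, log = train(tensor, split, test_id, fold, cfg)
            self.models_.append(model)
            self.logs_.append(log)
        self.split_ = split
        self.test_id_ = test_id
        return self

    def predict(self, keys: Sequence[ExperimentKey], loci=None):
        return impute_consensus(self.models_, keys, loci)
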