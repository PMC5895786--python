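"""Optimizer, convergence detection, burn-in, parallel rounds, genome solve."""

import numpy as np
import pytest

from epitensor.parafac import FactorModel, ParticipationCounts, RegularizationWeights
from epitensor.synthetic import generate_tensor
from epitensor.tensor import make_splits
from epitensor.training import (
    AdamState,
    TrainingConfig,
    adam_nag_step,
    build_entries,
    burn_in,
    check_convergence,
    impute_consensus,
    init_model,
    line_search_restart,
    make_adam_states,
    parallel_round,
    schedule,
    second_order_genome_solve,
    split_mse,
    train,
)
from conftest import tiny_config


class TestSchedule:
    def test_first_step_undecayed(self):
        assert schedule(1, 0.0045, 1 - 1e-6, 0.9, 1 - 1e-6) == (0.0045, 0.9)

    def test_unit_decay_constant(self):
        assert schedule(500, 0.01, 1.0, 0.8, 1.0) == (0.01, 0.8)

    def test_million_step_decay(self):
        eta_t, b1_t = schedule(10**6 + 1, 0.0045, 1 - 1e-6, 0.9, 1 - 1e-6)
        assert eta_t == pytest.approx(0.0045 * 0.3678796, rel=1e-5)
        assert b1_t == pytest.approx(0.9 * 0.3678796, rel=1e-5)

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            schedule(0, 0.0045, 1.0, 0.9, 1.0)


class TestAdamNagStep:
    def test_zero_gradient_no_move(self):
        p = np.array([1.0, -2.0])
        st = AdamState.zeros_like(p)
        new, _ = adam_nag_step(p, np.zeros(2), st, 0.01, 0.9, 0.999, 1e-8)
        assert np.allclose(new, p)

    def test_sign_normalized_limit(self):
        # beta1 -> 0, beta2 -> 0, eps -> 0: a step of magnitude eta_t in the
        # gradient's sign direction
        p = np.array([1.0, 2.0, 3.0])
        st = AdamState.zeros_like(p)
        new, _ = adam_nag_step(p, np.array([5.0, -2.0, 0.1]), st, 0.01, 0.0, 1e-14, 1e-16)
        assert np.allclose(p - new, [0.01, -0.01, 0.01], atol=1e-8)

    def test_constant_gradient_step_approaches_eta(self):
        p = np.zeros(1)
        st = AdamState.zeros_like(p)
        eta_t = 0.01
        prev = p
        for _ in range(300):
            prev = p
            p, st = adam_nag_step(p, np.array([3.0]), st, eta_t, 0.9, 0.999, 1e-8)
        assert abs(float(prev[0] - p[0])) == pytest.approx(eta_t, rel=0.05)

    def test_rejects_non_finite_gradient(self):
        p = np.zeros(2)
        with pytest.raises(ValueError):
            adam_nag_step(p, np.array([1.0, np.nan]), AdamState.zeros_like(p), 0.01, 0.9, 0.999, 1e-8)

    def test_kernel_matches_block_step(self, small_tensor):
        """One compiled single-entry update equals the block-level op."""
        from epitensor.parafac import entry_gradients
        from epitensor.training import _SGDKernel

        tensor, _ = small_tensor
        keys = tensor.observed_keys[:4]
        loci = np.arange(tensor.I)
        model = init_model(tensor.restrict(keys), 3, seed=5)
        ref = model.copy()
        states = make_adam_states(model)
        cfg = tiny_config(latent_factors=3)
        entries = build_entries(tensor, keys, loci)
        counts = ParticipationCounts.from_entries(zip(*entries[:3]), model.shape)
        kernel = _SGDKernel(model, states, counts, cfg, cfg.eta, cfg.beta1)
        kernel.run(entries, np.array([17]))
        j, k, i = (int(entries[0][17]), int(entries[1][17]), int(entries[2][17]))
        lam = cfg.regularization
        grads = entry_gradients(ref, float(entries[3][17]), j, k, i, lam, counts)
        eta_t, b1_t = schedule(1, cfg.eta, cfg.phi_eta, cfg.beta1, cfg.phi_beta1)
        b1_next = cfg.beta1 * cfg.phi_beta1
        for name, row, grad in [("C", j, grads[0]), ("A", k, grads[1]), ("G", i, grads[2])]:
            block = getattr(ref, name)
            st = AdamState.zeros_like(np.atleast_2d(block[row]))
            new, _ = adam_nag_step(
                block[row][None, :], np.atleast_2d(grad), st,
                eta_t, b1_t, cfg.beta2, cfg.adam_eps, beta1_next=b1_next,
            )
            assert np.allclose(getattr(model, name)[row], new[0], atol=1e-12)


class TestInitModel:
    def test_deterministic_and_in_range(self, small_tensor):
        tensor, _ = small_tensor
        a = init_model(tensor, 5, seed=3)
        b = init_model(tensor, 5, seed=3)
        for name in "CAGcag":
            assert np.array_equal(getattr(a, name), getattr(b, name))
        for name in "CAG":
            arr = getattr(a, name)
            assert np.all(np.abs(arr) < 0.33)

    def test_constant_tensor_bias_init(self):
        tensor, _ = generate_tensor(J=3, K=3, I=10, L_true=1, sigma=0.0,
                                    observed_fraction=1.0, min_support=1, seed=0)
        for key in tensor.values:
            tensor.values[key] = np.full(10, 7.0)
        m = init_model(tensor, 2, seed=0)
        assert np.allclose(m.c, 0.0)
        assert np.allclose(m.a, 0.0)
        assert np.allclose(m.g, 7.0)
        # bias-only prediction is the plane-mean estimate
        m.C[:] = 0
        m.A[:] = 0
        assert m.predict_fiber(0, 0)[0] == pytest.approx(7.0)


class TestBurnIn:
    def _setup(self, seed):
        tensor, _ = generate_tensor(J=6, K=4, I=80, L_true=2, sigma=0.05,
                                    observed_fraction=0.8, min_support=2, seed=seed)
        keys = tensor.observed_keys
        cfg = tiny_config(seed=seed)
        model = init_model(tensor.restrict(keys), cfg.latent_factors, seed=seed)
        return tensor, keys, model, cfg

    def test_descent_on_average(self):
        improved = 0
        for seed in range(10):
            tensor, keys, model, cfg = self._setup(seed)
            loci = np.arange(tensor.I)
            entries = build_entries(tensor, keys, loci)
            before = split_mse(model, tensor, entries)
            burn_in(tensor, keys, loci, model, make_adam_states(model), cfg)
            after = split_mse(model, tensor, entries)
            improved += after <= before
        assert improved >= 8

    def test_zero_local_iters_noop(self):
        tensor, keys, model, cfg = self._setup(0)
        cfg = tiny_config(local_iters=0)
        ref = model.copy()
        burn_in(tensor, keys, np.arange(tensor.I), model, make_adam_states(model), cfg)
        for name in "CAGcag":
            assert np.array_equal(getattr(model, name), getattr(ref, name))

    def test_deterministic(self):
        outs = []
        for _ in range(2):
            tensor, keys, model, cfg = self._setup(3)
            burn_in(tensor, keys, np.arange(tensor.I), model, make_adam_states(model), cfg)
            outs.append(model)
        assert np.array_equal(outs[0].C, outs[1].C)
        assert np.array_equal(outs[0].g, outs[1].g)


class TestParallelRound:
    def test_average_equals_mean_of_local_updates(self, small_tensor):
        """The shared blocks after a round equal the hand-computed mean of the
        independently run per-partition local updates."""
        tensor, _ = small_tensor
        keys = tensor.observed_keys
        cfg = tiny_config(local_iters=100)
        loci = np.arange(tensor.I)
        model = init_model(tensor.restrict(keys), cfg.latent_factors, seed=1)
        states = make_adam_states(model)
        counts = ParticipationCounts.from_entries(
            zip(*build_entries(tensor, keys, loci)[:3]), model.shape
        )
        parts = [
            build_entries(tensor, keys, loci[:60]),
            build_entries(tensor, keys, loci[60:]),
        ]
        # reference: run each partition independently from the same start
        expected = []
        from epitensor.training import _SGDKernel

        for p, entries in enumerate(parts):
            local = model.copy()
            local_states = {n: states[n].copy() for n in "CAGcag"}
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12, 1, p]))
            order = rng.integers(0, entries[0].size, size=cfg.local_iters)
            _SGDKernel(local, local_states, counts, cfg, cfg.eta, cfg.beta1).run(entries, order)
            expected.append(local)
        parallel_round(model, states, parts, counts, cfg, cfg.eta, cfg.beta1, 1)
        for name in ("C", "A", "c", "a"):
            mean = np.mean([getattr(e, name) for e in expected], axis=0)
            assert np.allclose(getattr(model, name), mean, atol=1e-12)

    def test_single_partition_identity(self, small_tensor):
        tensor, _ = small_tensor
        keys = tensor.observed_keys
        cfg = tiny_config(local_iters=50)
        loci = np.arange(tensor.I)
        entries = build_entries(tensor, keys, loci)
        counts = ParticipationCounts.from_entries(
            zip(*entries[:3]), (tensor.J, tensor.K, tensor.I)
        )
        model = init_model(tensor.restrict(keys), cfg.latent_factors, seed=2)
        states = make_adam_states(model)
        ref = model.copy()
        ref_states = {n: states[n].copy() for n in "CAGcag"}
        from epitensor.training import _SGDKernel

        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12, 1, 0]))
        order = rng.integers(0, entries[0].size, size=cfg.local_iters)
        _SGDKernel(ref, ref_states, counts, cfg, cfg.eta, cfg.beta1).run(entries, order)
        parallel_round(model, states, [entries], counts, cfg, cfg.eta, cfg.beta1, 1)
        assert np.allclose(model.C, ref.C)
        assert np.allclose(model.a, ref.a)


class TestSplitMse:
    def test_known_residuals(self):
        m = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((3, 1)),
                        np.zeros(1), np.zeros(1), np.zeros(3))
        from epitensor.tensor import GenomicBinIndex, ObservedTensor

        tensor = ObservedTensor(
            ["c"], ["a"], GenomicBinIndex.tile("chrS", 75, 25),
            {(0, 0): np.array([-1.0, 1.0, -2.0])}, "raw",
        )
        entries = build_entries(tensor, [(0, 0)], np.arange(3))
        assert split_mse(m, tensor, entries) == pytest.approx(2.0)

    def test_empty_rejected(self):
        m = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                        np.zeros(1), np.zeros(1), np.zeros(1))
        from epitensor.tensor import GenomicBinIndex, ObservedTensor

        tensor = ObservedTensor(["c"], ["a"], GenomicBinIndex.tile("chrS", 25, 25),
                                {(0, 0): np.array([1.0])}, "raw")
        with pytest.raises(ValueError):
            split_mse(m, tensor, build_entries(tensor, [], np.arange(1)))


class TestConvergence:
    def test_decreasing_series_not_converged(self):
        series = [1.00 - 0.02 * i for i in range(12)]
        cfg = TrainingConfig(window_records=6)
        assert check_convergence(series, cfg) is False

    def test_increasing_series_converged(self):
        series = [0.76 + 0.02 * i for i in range(12)]
        cfg = TrainingConfig(window_records=6)
        assert check_convergence(series, cfg) is True

    def test_short_series_not_converged(self):
        cfg = TrainingConfig(window_records=6)
        assert check_convergence([1.0] * 11, cfg) is False

    def test_min_rounds_gate(self):
        series = [0.76 + 0.02 * i for i in range(12)]
        cfg = TrainingConfig(window_records=6, min_rounds=50)
        assert check_convergence(series, cfg, rounds_elapsed=36) is False
        assert check_convergence(series, cfg, rounds_elapsed=60) is True


class TestLineSearch:
    def test_published_defaults(self):
        model = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                            np.zeros(1), np.zeros(1), np.zeros(1))
        _, eta, b1 = line_search_restart(model, 0.0045, 0.9)
        assert eta == pytest.approx(0.00225)
        assert b1 == pytest.approx(0.8)

    def test_beta1_iteration_and_fixed_point(self):
        model = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                            np.zeros(1), np.zeros(1), np.zeros(1))
        b1 = 0.9
        seen = []
        eta = 1.0
        for _ in range(3):
            _, eta, b1 = line_search_restart(model, eta, b1)
            seen.append(round(b1, 10))
        assert seen == [0.8, 0.6, 0.2]
        _, _, b1 = line_search_restart(model, 1.0, 1.0)
        assert b1 == 1.0

    def test_missing_checkpoint(self):
        with pytest.raises(ValueError):
            line_search_restart(None, 0.0045, 0.9)


class TestSecondOrderSolve:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        J, K, L = 6, 5, 3
        C = rng.normal(size=(J, L))
        A = rng.normal(size=(K, L))
        c = rng.normal(size=J)
        a = rng.normal(size=K)
        G_true = rng.normal(size=L)
        g_true = rng.normal()
        obs = [
            (j, k, float((C[j] * A[k]) @ G_true + c[j] + a[k] + g_true))
            for j in range(J) for k in range(K)
        ]
        G_i, g_i = second_order_genome_solve(C, A, c, a, obs, 0.0)
        resid = [
            d - (C[j] * A[k]) @ G_i - c[j] - a[k] - g_i for j, k, d in obs
        ]
        assert np.max(np.abs(resid)) < 1e-8

    def test_large_penalty_limit(self):
        rng = np.random.default_rng(1)
        J, K, L = 5, 4, 2
        C, A = rng.normal(size=(J, L)), rng.normal(size=(K, L))
        c, a = rng.normal(size=J), rng.normal(size=K)
        obs = [(j, k, rng.normal()) for j in range(J) for k in range(K)]
        G_i, g_i = second_order_genome_solve(C, A, c, a, obs, 1e12)
        assert np.linalg.norm(G_i) < 1e-6
        target = np.mean([d - c[j] - a[k] for j, k, d in obs])
        assert g_i == pytest.approx(target, rel=1e-6)

    @pytest.mark.parametrize("lam", [0.0, 0.4122, 3.0])
    def test_matches_dense_oracle(self, lam):
        rng = np.random.default_rng(int(lam * 100))
        for _ in range(20):
            J, K, L = 5, 4, 3
            C, A = rng.normal(size=(J, L)), rng.normal(size=(K, L))
            c, a = rng.normal(size=J), rng.normal(size=K)
            obs = [
                (j, k, rng.normal())
                for j in range(J) for k in range(K) if rng.random() < 0.7
            ] or [(0, 0, 1.0)]
            G_i, g_i = second_order_genome_solve(C, A, c, a, obs, lam)
            jj = np.array([o[0] for o in obs])
            kk = np.array([o[1] for o in obs])
            y = np.array([o[2] for o in obs])
            Z = np.column_stack([C[jj] * A[kk], np.ones(len(obs))])
            M = Z.T @ Z + lam * np.diag(np.r_[np.ones(L), 0.0])
            oracle = np.linalg.pinv(M) @ Z.T @ (y - c[jj] - a[kk])
            assert np.max(np.abs(np.r_[G_i, g_i] - oracle)) < 1e-8

    def test_no_observations_warns_and_zeros(self, caplog):
        with caplog.at_level("WARNING"):
            G_i, g_i = second_order_genome_solve(np.zeros((2, 3)), np.zeros((2, 3)),
                                                 np.zeros(2), np.zeros(2), [], 0.1)
        assert np.allclose(G_i, 0) and g_i == 0.0


@pytest.fixture(scope="module")
def trained():
    tensor, truth = generate_tensor(J=8, K=5, I=100, L_true=2, sigma=0.05,
                                    observed_fraction=0.8, min_support=2, seed=5)
    split = make_splits(tensor.observed_keys, n_test=4, n_folds=4, seed=5)
    cfg = tiny_config(seed=5, n_folds=4)
    model, log = train(tensor, split, 0, 0, cfg)
    return tensor, split, cfg, model, log


class TestTrainAndConsensus:
    def test_deterministic(self, trained):
        tensor, split, cfg, model, _ = trained
        model2, _ = train(tensor, split, 0, 0, cfg)
        for name in "CAGcag":
            assert np.array_equal(getattr(model, name), getattr(model2, name))

    def test_best_so_far_non_increasing(self, trained):
        _, _, _, _, log = trained
        best = log.best_so_far()
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(best, best[1:]))

    def test_genome_stationarity_after_final_solve(self, trained):
        """The convex genome sub-problem is solved exactly: its gradient at
        every locus is (numerically) zero."""
        tensor, split, cfg, model, _ = trained
        train_keys, _, _ = split.keys_for(0, 0)
        jj = np.array([j for j, _ in train_keys])
        kk = np.array([k for _, k in train_keys])
        X = model.C[jj] * model.A[kk]
        Z = np.column_stack([X, np.ones(len(train_keys))])
        D = tensor.stacked(train_keys)
        R = Z @ np.vstack([model.G.T, model.g]) - (D - (model.c[jj] + model.a[kk])[:, None])
        grad = 2 * Z.T @ R
        grad[: model.L] += 2 * cfg.lam_G2 * model.G.T
        assert np.max(np.abs(grad)) < 1e-6

    def test_consensus_clamps_negatives(self):
        m = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((2, 1)),
                        np.array([-0.5]), np.zeros(1), np.array([0.0, 0.9]))
        out = impute_consensus([m], [(0, 0)])
        assert np.allclose(out[(0, 0)], [0.0, 0.4])

    def test_consensus_mean_of_two_models(self):
        def bias_model(v):
            return FactorModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                               np.array([v]), np.zeros(1), np.zeros(1))

        out = impute_consensus([bias_model(-0.2), bias_model(0.4)], [(0, 0)])
        assert out[(0, 0)][0] == pytest.approx(0.1)

    def test_consensus_of_identical_models(self, trained):
        _, _, _, model, _ = trained
        one = impute_consensus([model], [(0, 0)])
        three = impute_consensus([model] * 3, [(0, 0)])
        assert np.allclose(one[(0, 0)], three[(0, 0)])
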