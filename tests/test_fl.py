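"""Training strategies: exactness of the weighted aggregation, degeneracy
reductions, and determinism, mostly on the convex linear toy model."""

import numpy as np
import pytest

from fedpet.fl import (
    LinearModel,
    LocalDataset,
    LocalUpdate,
    StrategyConfig,
    aggregate,
    local_update,
    pool_datasets,
    run_center_based,
    run_centralized,
    run_fl_parallel,
    run_fl_sequential,
)
from fedpet.model import U2Net, micro_config


def make_centers(rng, sizes, d=4, noise=0.1):
    """Linear-regression silos sharing a ground-truth weight vector."""
    w_true = rng.standard_normal((d, 1))
    centers = []
    for i, n in enumerate(sizes):
        X = rng.standard_normal((n, d))
        Y = X @ w_true + noise * rng.standard_normal((n, 1))
        centers.append(LocalDataset(f"c{i}", X, Y))
    return centers, w_true


SGD_FB = dict(optimizer="sgd", weight_decay=0.0)  # full-batch SGD recipe


class TestLocalUpdate:
    def test_zero_learning_rate_returns_theta_unchanged(self, rng):
        centers, _ = make_centers(rng, [12])
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="CB", learning_rate=0.0, batch_size=4,
                             local_epochs=3, **SGD_FB)
        theta = model.init_params(0).to_flat()
        up, _ = local_update(model, theta, centers[0], cfg, seed=1)
        np.testing.assert_array_equal(up.payload, theta)

    def test_gradient_mode_matches_normal_equations(self, rng):
        """Full-batch gradient of mean squared loss: (2/N) X^T (X w - y)."""
        centers, _ = make_centers(rng, [20])
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="FL_PL", aggregation_mode="gradient",
                             batch_size=64, weight_decay=0.0)
        theta = model.init_params(0).to_flat()
        up, _ = local_update(model, theta, centers[0], cfg, seed=1)
        X, Y = centers[0].X, centers[0].Y
        expected = (2.0 / len(X)) * X.T @ (X @ theta.reshape(4, 1) - Y)
        np.testing.assert_allclose(up.payload, expected.ravel(), rtol=1e-12)

    def test_gradient_mode_with_multiple_epochs_rejected(self, rng):
        centers, _ = make_centers(rng, [10])
        cfg = StrategyConfig(strategy="FL_PL", aggregation_mode="gradient",
                             local_epochs=2)
        with pytest.raises(ValueError, match="local_epochs=1"):
            local_update(LinearModel(4), np.zeros(4), centers[0], cfg, seed=0)

    def test_deterministic_given_seed(self, rng):
        centers, _ = make_centers(rng, [16])
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="CB", batch_size=4, local_epochs=2)
        theta = model.init_params(0).to_flat()
        a, _ = local_update(model, theta, centers[0], cfg, seed=9)
        b, _ = local_update(model, theta, centers[0], cfg, seed=9)
        np.testing.assert_array_equal(a.payload, b.payload)


class TestAggregate:
    def test_hand_evaluated_weighted_gradient_step(self):
        """K=2 with N=(25, 75), gradients (1,0) and (0,1), eta=0.1."""
        ups = [
            LocalUpdate("a", 25, "gradient", np.array([1.0, 0.0])),
            LocalUpdate("b", 75, "gradient", np.array([0.0, 1.0])),
        ]
        out = aggregate(ups, np.zeros(2), eta=0.1, mode="gradient")
        np.testing.assert_allclose(out, [-0.025, -0.075])

    def test_parameter_average_of_identical_thetas(self):
        theta = np.array([3.0, -1.0, 2.0])
        ups = [LocalUpdate(c, n, "parameters", theta.copy())
               for c, n in (("a", 10), ("b", 30), ("c", 5))]
        np.testing.assert_allclose(
            aggregate(ups, np.zeros(3), eta=0.1, mode="parameter_average"), theta
        )

    def test_parameter_average_equals_gradient_mode_for_single_sgd_step(self, rng):
        """FedAvg over one full-batch SGD step per center reduces to the
        pooled-gradient update, to floating tolerance."""
        centers, _ = make_centers(rng, [25, 75, 100])
        model = LinearModel(4)
        eta = 0.05
        theta = model.init_params(1).to_flat()
        g_cfg = StrategyConfig(strategy="FL_PL", aggregation_mode="gradient",
                               batch_size=128, weight_decay=0.0)
        p_cfg = StrategyConfig(strategy="FL_PL", aggregation_mode="parameter_average",
                               batch_size=128, learning_rate=eta, **SGD_FB)
        g_ups = [local_update(model, theta, c, g_cfg, seed=0)[0] for c in centers]
        p_ups = [local_update(model, theta, c, p_cfg, seed=0)[0] for c in centers]
        out_g = aggregate(g_ups, theta, eta=eta, mode="gradient")
        out_p = aggregate(p_ups, theta, eta=eta, mode="parameter_average")
        np.testing.assert_allclose(out_p, out_g, atol=1e-12)

    def test_mismatched_shapes_rejected(self):
        ups = [LocalUpdate("a", 5, "gradient", np.zeros(3)),
               LocalUpdate("b", 5, "gradient", np.zeros(4))]
        with pytest.raises(ValueError, match="conformable"):
            aggregate(ups, np.zeros(3), eta=0.1)


class TestStrategyEquivalences:
    def test_parallel_gradient_round_equals_pooled_sgd_step(self, rng):
        """One gradient-mode round is exactly one centralized full-batch SGD
        step on the pooled data, for arbitrary center sizes."""
        centers, _ = make_centers(rng, [7, 19, 34])
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="FL_PL", rounds=1, aggregation_mode="gradient",
                             batch_size=256, learning_rate=0.01, weight_decay=0.0)
        state = run_fl_parallel(centers, model, cfg, seed=5)
        pooled = pool_datasets(centers)
        theta0 = model.init_params(5).to_flat()
        _, g = model.loss_and_grad(theta0, pooled.X, pooled.Y)
        np.testing.assert_allclose(state.theta, theta0 - 0.01 * g, rtol=1e-9)

    def test_identical_data_makes_parallel_equal_centralized(self, rng):
        """With every silo holding the same data (full batch), the FL-PL
        trajectory coincides with centralized training round for round."""
        base, _ = make_centers(rng, [12])
        X, Y = base[0].X, base[0].Y
        centers = [LocalDataset(f"c{i}", X.copy(), Y.copy()) for i in range(3)]
        model = LinearModel(4)
        R, E = 6, 2
        fl_cfg = StrategyConfig(strategy="FL_PL", rounds=R, local_epochs=E,
                                batch_size=64, optimizer="adam")
        cz_cfg = StrategyConfig(strategy="CZ", local_epochs=R * E, batch_size=64,
                                optimizer="adam")
        fl = run_fl_parallel(centers, model, fl_cfg, seed=3)
        cz = run_centralized([centers[0]], model, cz_cfg, seed=3)
        np.testing.assert_allclose(fl.theta, cz.theta, atol=1e-9)

    def test_identical_data_parallel_equals_centralized_on_image_net(self, rng):
        """The same degeneracy holds on the tiny float64 image network."""
        net = U2Net(micro_config())
        X = rng.random((4, 1, 8, 8))
        Y = rng.random((4, 1, 8, 8))
        centers = [LocalDataset(f"c{i}", X.copy(), Y.copy()) for i in range(2)]
        fl_cfg = StrategyConfig(strategy="FL_PL", rounds=3, local_epochs=1,
                                batch_size=8)
        cz_cfg = StrategyConfig(strategy="CZ", local_epochs=3, batch_size=8)
        fl = run_fl_parallel(centers, net, fl_cfg, seed=2)
        cz = run_centralized([centers[0]], net, cz_cfg, seed=2)
        np.testing.assert_allclose(fl.theta, cz.theta, atol=1e-9)

    def test_single_center_sequential_equals_center_based(self, rng):
        """K=1 FL-SQ over R rounds is bit-identical to CB for R*E epochs."""
        centers, _ = make_centers(rng, [15])
        model = LinearModel(4)
        R, E = 4, 2
        sq = run_fl_sequential(
            centers, model,
            StrategyConfig(strategy="FL_SQ", rounds=R, local_epochs=E, batch_size=4),
            seed=11,
        )
        cb = run_center_based(
            centers[0], model,
            StrategyConfig(strategy="CB", local_epochs=R * E, batch_size=4),
            seed=11,
        )
        np.testing.assert_array_equal(sq.theta, cb.theta)

    def test_two_identical_centers_sequential_equals_double_epochs(self, rng):
        """FL-SQ across two clones of a dataset (E=1, stateless SGD) matches
        centralized training on one copy for twice the epochs."""
        base, _ = make_centers(rng, [10])
        X, Y = base[0].X, base[0].Y
        centers = [LocalDataset("a", X.copy(), Y.copy()),
                   LocalDataset("b", X.copy(), Y.copy())]
        model = LinearModel(4)
        sq = run_fl_sequential(
            centers, model,
            StrategyConfig(strategy="FL_SQ", rounds=1, local_epochs=1,
                           batch_size=5, **SGD_FB),
            seed=4,
        )
        cz = run_centralized(
            [centers[0]], model,
            StrategyConfig(strategy="CZ", local_epochs=2, batch_size=5, **SGD_FB),
            seed=4,
        )
        np.testing.assert_array_equal(sq.theta, cz.theta)

    def test_centralized_over_one_center_equals_center_based(self, rng):
        centers, _ = make_centers(rng, [9])
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="CZ", local_epochs=3, batch_size=4)
        cz = run_centralized(centers, model, cfg, seed=8)
        cb = run_center_based(centers[0], model, cfg, seed=8)
        np.testing.assert_array_equal(cz.theta, cb.theta)

    def test_pooled_sample_count(self, rng):
        centers, _ = make_centers(rng, [5, 7, 11])
        assert pool_datasets(centers).N_k == 23


class TestConvergenceAndAudit:
    def test_loss_monotone_on_convex_problem_with_decaying_sgd(self, rng):
        """Full-batch gradient descent on least squares with a small step
        decreases the objective every epoch."""
        centers, _ = make_centers(rng, [40], noise=0.2)
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="CB", local_epochs=25, batch_size=64,
                             learning_rate=0.02, **SGD_FB)
        state = run_center_based(centers[0], model, cfg, seed=0)
        losses = state.global_loss_history
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_empty_center_rejected(self):
        with pytest.raises(ValueError):
            LocalDataset("empty", np.zeros((0, 2)), np.zeros((0, 1)))

    def test_full_run_deterministic(self, rng):
        centers, _ = make_centers(rng, [8, 12])
        model = LinearModel(4)
        cfg = StrategyConfig(strategy="FL_PL", rounds=3, local_epochs=2, batch_size=4)
        a = run_fl_parallel(centers, model, cfg, seed=6)
        b = run_fl_parallel(centers, model, cfg, seed=6)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.global_loss_history == b.global_loss_history
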