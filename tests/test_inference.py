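"""Inference-phase tests: amortized sweep, gradient-descent dynamics,
stopping behaviour, closed-form fixed points and readouts."""

import numpy as np
import pytest

from hybridpc import (
    AmortizedWeights,
    GenerativeWeights,
    NetworkConfig,
    NetworkState,
    amortized_sweep,
    bottom_up_predict,
    classify,
    compute_errors,
    free_energy,
    generate,
    init_weights,
    iterative_step,
    label_entropy,
    run_inference,
)
from hybridpc.inference import InferenceResult

from conftest import numerical_free_energy_grad, random_state


def scalar_linear_net(theta_val=1.0, top_prior="none", **kw):
    cfg = NetworkConfig(layer_sizes=[1, 1], gen_activation=["identity"],
                        amo_activation=["identity"], top_prior=top_prior, **kw)
    theta = GenerativeWeights([np.array([[theta_val]])])
    phi = AmortizedWeights([np.array([[0.0]])])
    return cfg, theta, phi


class TestAmortizedSweep:
    def test_zero_weights_give_zero_beliefs(self, small_net):
        cfg, _, phi = small_net
        phi0 = AmortizedWeights([np.zeros_like(m) for m in phi.matrices])
        state = amortized_sweep(phi0, np.ones(cfg.layer_sizes[0]), cfg)
        for mu in state.mu[1:]:
            np.testing.assert_array_equal(mu, np.zeros_like(mu))

    def test_identity_chain_propagates_input(self):
        cfg = NetworkConfig(layer_sizes=[1, 1], amo_activation=["identity"])
        phi = AmortizedWeights([np.array([[1.0]])])
        state = amortized_sweep(phi, np.array([0.7]), cfg)
        np.testing.assert_allclose(state.mu[1], [[0.7]])

    def test_matches_composed_bottom_up_passes(self):
        cfg = NetworkConfig(layer_sizes=[2, 2, 2], seed=0)
        _, phi = init_weights(cfg, seed=3)
        x = np.array([0.2, -0.4])
        state = amortized_sweep(phi, x, cfg)
        h1 = bottom_up_predict(phi.matrices[0], x, cfg.amo_activation[0])
        h2 = bottom_up_predict(phi.matrices[1], h1, cfg.amo_activation[1])
        np.testing.assert_allclose(state.mu[1][0], h1, atol=1e-12)
        np.testing.assert_allclose(state.mu[2][0], h2, atol=1e-12)

    def test_only_data_layer_clamped(self, small_net):
        cfg, _, phi = small_net
        state = amortized_sweep(phi, np.zeros(cfg.layer_sizes[0]), cfg)
        assert state.clamped == [True, False, False, False]

    def test_wrong_input_length_raises(self, small_net):
        cfg, _, phi = small_net
        with pytest.raises(ValueError):
            amortized_sweep(phi, np.zeros(cfg.layer_sizes[0] + 1), cfg)


class TestIterativeStep:
    def test_scalar_linear_update(self):
        cfg, theta, _ = scalar_linear_net(kappa=0.1)
        state = NetworkState(mu=[[[1.0]], [[0.0]]], clamped=[True, False])
        new = iterative_step(state, theta, cfg)
        # error below is 1, no error above: mu_1 <- 0 + 0.1 * 1
        np.testing.assert_allclose(new.mu[1], [[0.1]])

    def test_zero_error_fixed_point(self):
        cfg, theta, _ = scalar_linear_net(kappa=0.1)
        state = NetworkState(mu=[[[1.0]], [[1.0]]], clamped=[True, False])
        new = iterative_step(state, theta, cfg)
        np.testing.assert_allclose(new.mu[1], [[1.0]])

    @pytest.mark.parametrize("top_prior", ["none", "gaussian"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_finite_difference_gradient_descent(self, seed, top_prior):
        cfg = NetworkConfig(layer_sizes=[12, 8, 5], kappa=0.01,
                            top_prior=top_prior, top_prior_mean=0.1)
        theta, _ = init_weights(cfg, seed=seed)
        state = random_state(cfg, np.random.default_rng(seed))
        new = iterative_step(state, theta, cfg)
        for i in range(1, cfg.n_links + 1):
            num = numerical_free_energy_grad(state, theta, cfg, wrt_layer=i)
            update = new.mu[i] - state.mu[i]
            np.testing.assert_allclose(update, -cfg.kappa * num,
                                       rtol=1e-4, atol=1e-9)

    def test_clamped_layers_bitwise_unchanged(self, small_net):
        cfg, theta, _ = small_net
        state = random_state(cfg, np.random.default_rng(9), clamp_top=True)
        before0, beforeL = state.mu[0].copy(), state.mu[-1].copy()
        for _ in range(5):
            state = iterative_step(state, theta, cfg)
        np.testing.assert_array_equal(state.mu[0], before0)
        np.testing.assert_array_equal(state.mu[-1], beforeL)

    def test_sequential_schedule_also_descends_energy(self, small_net):
        cfg, theta, _ = small_net
        cfg = cfg.with_(update_schedule="sequential")
        state = random_state(cfg, np.random.default_rng(10))
        f0 = free_energy(compute_errors(state, theta, cfg), cfg)
        state = iterative_step(state, theta, cfg)
        f1 = free_energy(compute_errors(state, theta, cfg), cfg)
        assert f1 < f0

    def test_energy_descends_on_nearly_all_steps(self):
        """Free energy is non-increasing across >= 95% of iterative steps
        over 20 seeded random networks (rare overshoot allowed)."""
        good = total = 0
        for seed in range(20):
            cfg = NetworkConfig(layer_sizes=[10, 7, 4], kappa=0.01, seed=seed)
            theta, _ = init_weights(cfg, seed=seed)
            state = random_state(cfg, np.random.default_rng(seed))
            f_prev = free_energy(compute_errors(state, theta, cfg), cfg)
            for _ in range(100):
                state = iterative_step(state, theta, cfg)
                f = free_energy(compute_errors(state, theta, cfg), cfg)
                good += f <= f_prev + 1e-12
                total += 1
                f_prev = f
        assert good / total >= 0.95


class TestRunInference:
    def test_iteration_cap_respected(self, small_net):
        cfg, theta, phi = small_net
        cfg = cfg.with_(adaptive_stop=False, n_iters_max=10)
        res = run_inference(np.zeros(cfg.layer_sizes[0]), theta, phi, cfg)
        assert res.n_iters_used == 10
        assert res.stopped_by == "iteration_cap"
        assert len(res.energy_trace) == res.n_iters_used + 1

    def test_zero_iterations_returns_initialization(self, small_net):
        cfg, theta, phi = small_net
        cfg = cfg.with_(n_iters_max=0, adaptive_stop=False)
        res = run_inference(np.ones(cfg.layer_sizes[0]), theta, phi, cfg)
        assert res.n_iters_used == 0
        for a, b in zip(res.state_star.mu, res.sweep_state.mu):
            np.testing.assert_array_equal(a, b)

    def test_sweep_below_threshold_stops_immediately(self):
        # identical zero weights: sweep beliefs are all zero and so are all
        # prediction errors on a zero input -> statistic 0 < 0.005
        cfg = NetworkConfig(layer_sizes=[3, 2], adaptive_stop=True)
        theta = GenerativeWeights([np.zeros((3, 2))])
        phi = AmortizedWeights([np.zeros((2, 3))])
        res = run_inference(np.zeros(3), theta, phi, cfg)
        assert res.n_iters_used == 0
        assert res.stopped_by == "threshold"

    def test_standard_pc_mode_initializes_beliefs_at_zero(self, small_net):
        cfg, theta, phi = small_net
        cfg = cfg.with_(mode="standard_pc", n_iters_max=0)
        res = run_inference(np.ones(cfg.layer_sizes[0]), theta, phi, cfg)
        for mu in res.state_star.mu[1:]:
            np.testing.assert_array_equal(mu, np.zeros_like(mu))

    def test_scalar_fixed_point_with_gaussian_prior(self):
        """argmin of 0.5(1-mu)^2 + 0.5 mu^2 is mu = 0.5."""
        cfg, theta, phi = scalar_linear_net(
            top_prior="gaussian", kappa=0.05, n_iters_max=500,
            amortized_enabled=False)
        res = run_inference(np.array([1.0]), theta, phi, cfg)
        assert res.state_star.mu[1][0, 0] == pytest.approx(0.5, abs=1e-4)

    def test_multivariate_linear_fixed_point(self):
        """Converged beliefs match the ridge solution (th'th + I)^-1 th'x."""
        rng = np.random.default_rng(12)
        d0, d1 = 6, 4
        cfg = NetworkConfig(layer_sizes=[d0, d1], gen_activation=["identity"],
                            amo_activation=["identity"], top_prior="gaussian",
                            top_prior_mean=0.0, kappa=0.05, n_iters_max=4000,
                            amortized_enabled=False)
        th = rng.standard_normal((d0, d1)) * 0.5
        theta = GenerativeWeights([th])
        phi = AmortizedWeights([np.zeros((d1, d0))])
        x = rng.standard_normal(d0)
        res = run_inference(x, theta, phi, cfg)
        expect = np.linalg.solve(th.T @ th + np.eye(d1), th.T @ x)
        np.testing.assert_allclose(res.state_star.mu[1][0], expect, atol=1e-5)

    def test_clamp_top_fixes_label_layer(self, small_net):
        cfg, theta, phi = small_net
        cfg = cfg.with_(n_iters_max=5)
        target = np.zeros(cfg.layer_sizes[-1])
        target[1] = 1.0
        res = run_inference(np.zeros(cfg.layer_sizes[0]), theta, phi, cfg,
                            clamp_top_to=target)
        np.testing.assert_array_equal(res.state_star.mu[-1][0], target)


class TestReadouts:
    def test_classify_argmax(self):
        state = NetworkState(mu=[np.zeros((1, 2)), [[0.1, 0.9, 0.0]]],
                             clamped=[True, False])
        res = InferenceResult(state, state, 0, [0.0], "iteration_cap")
        assert classify(res)[0] == 1

    def test_classify_reads_back_clamped_one_hot(self):
        top = np.zeros((1, 10))
        top[0, 7] = 1.0
        state = NetworkState(mu=[np.zeros((1, 2)), top], clamped=[True, True])
        res = InferenceResult(state, state, 0, [0.0], "iteration_cap")
        assert classify(res)[0] == 7

    def test_classify_tie_breaks_to_lowest_index(self):
        state = NetworkState(mu=[np.zeros((1, 2)), [[0.0, 0.5, 0.1, 0.0, 0.5, 0.5]]],
                             clamped=[True, False])
        res = InferenceResult(state, state, 0, [0.0], "iteration_cap")
        assert classify(res)[0] == 1

    def test_generate_linear_net_matches_composed_top_down_pass(self):
        rng = np.random.default_rng(13)
        cfg = NetworkConfig(layer_sizes=[5, 4, 3],
                            gen_activation=["identity", "identity"],
                            kappa=0.05, n_iters_max=3000)
        th1 = rng.standard_normal((5, 4)) * 0.3
        th2 = rng.standard_normal((4, 3)) * 0.3
        theta = GenerativeWeights([th1, th2])
        onehot = np.zeros(3)
        onehot[1] = 1.0
        img = generate(theta, 1, cfg)
        np.testing.assert_allclose(img, th1 @ th2 @ onehot, atol=1e-6)

    def test_generate_zero_weights_give_zero_image(self):
        cfg = NetworkConfig(layer_sizes=[4, 3], n_iters_max=20)
        theta = GenerativeWeights([np.zeros((4, 3))])
        np.testing.assert_array_equal(generate(theta, 0, cfg), np.zeros(4))

    def test_generate_output_length_and_label_range(self):
        cfg = NetworkConfig(layer_sizes=[6, 5, 3], n_iters_max=5)
        theta, _ = init_weights(cfg, seed=0)
        assert generate(theta, 2, cfg).shape == (6,)
        with pytest.raises(ValueError):
            generate(theta, 3, cfg)

    def test_entropy_uniform_and_peaked(self):
        def res_with_top(top):
            state = NetworkState(mu=[np.zeros((1, 2)), np.atleast_2d(top)],
                                 clamped=[True, False])
            return InferenceResult(state, state, 0, [0.0], "iteration_cap")

        uniform = label_entropy(res_with_top(np.zeros(10)))
        assert uniform[0] == pytest.approx(np.log(10), abs=1e-12)
        peaked = label_entropy(res_with_top(np.r_[50.0, np.zeros(9)]))
        assert peaked[0] < 1e-10

    def test_entropy_bounds_on_random_vectors(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            d = rng.integers(2, 12)
            state = NetworkState(
                mu=[np.zeros((1, 2)), rng.standard_normal((1, d)) * 10],
                clamped=[True, False])
            res = InferenceResult(state, state, 0, [0.0], "iteration_cap")
            e = label_entropy(res)[0]
            assert 0.0 <= e <= np.log(d) + 1e-12
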