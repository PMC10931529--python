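"""Physics-informed network solver: pipeline, losses, adaptive weights,
training behaviour.  Networks are kept tiny; accuracy at published scale is
exercised by the acceptance suite."""

import numpy as np
import pytest

from grayode import autodiff as ad
from grayode import pk, make_graybox_spec, simulate_forward, subsample
from grayode.autodiff import Var
from grayode.pinn import (AdaptiveWeights, PINNConfig, _feature_matrix,
                          _Problem, adaptive_update, forward_nets, total_loss,
                          train)

TINY = PINNConfig(main_net=(8, 2), aux_net=(6, 2), N_collocation=20,
                  iters_stage1=5, iters_stage2=5, iters_lbfgs=0, T=10.0, seed=0)


@pytest.fixture(scope="module")
def pk_obs(pk_model):
    traj = simulate_forward(pk_model, t_grid=np.linspace(0, 50, 12))
    return subsample(traj, 12)


class TestAutodiff:
    def test_gradients_match_finite_differences(self, pk_model, pk_obs):
        prob = _Problem(pk_model, pk_obs, TINY, "params")
        lam = AdaptiveWeights(lambda_ode=np.ones(3))
        arrays = prob.parameter_arrays()
        pv = [Var(a) for a in arrays]
        total, _, _ = prob.loss(pv, lam, 2)
        ad.backward(total)
        rng = np.random.default_rng(7)
        for idx in [0, 2, len(arrays) - 1]:
            a = arrays[idx]
            i = tuple(rng.integers(0, s) for s in a.shape)
            eps = 1e-6
            up = [x.copy() for x in arrays]
            up[idx][i] += eps
            dn = [x.copy() for x in arrays]
            dn[idx][i] -= eps
            fp, _, _ = prob.loss([Var(x) for x in up], lam, 2)
            fm, _, _ = prob.loss([Var(x) for x in dn], lam, 2)
            fd = (float(fp.value) - float(fm.value)) / (2 * eps)
            assert pv[idx].grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestPipeline:
    def test_input_scaling(self):
        cfg = PINNConfig(T=100.0)
        x, v = _feature_matrix(np.array([1800.0]), cfg, omega=1.0)
        assert x[0, 0] == pytest.approx(18.0)
        assert v[0, 0] == pytest.approx(0.01)

    def test_empty_feature_list_passes_scaled_time(self):
        x, v = _feature_matrix(np.array([5.0, 10.0]), PINNConfig(T=10.0), omega=1.0)
        assert x.shape == (2, 1) and np.allclose(x[:, 0], [0.5, 1.0])

    def test_oscillatory_features_and_derivatives(self):
        cfg = PINNConfig(T=10.0, features=("t", "sin", "cos"))
        t = np.linspace(0, 20, 7)
        x, v = _feature_matrix(t, cfg, omega=3.0)
        assert x.shape == (7, 3)
        assert np.allclose(x[:, 1], np.sin(3.0 * t / 10.0))
        assert np.allclose(v[:, 2], -3.0 * np.sin(3.0 * t / 10.0) / 10.0)

    def test_identity_output_scaling(self, pk_model, pk_obs):
        prob = _Problem(pk_model, pk_obs, TINY, "params")
        u_scaled, _ = forward_nets(np.array([1.0, 2.0]), prob.main, None, TINY)
        assert u_scaled.shape == (2, 3)  # raw network output, k = 1

    def test_network_tangent_matches_finite_difference(self, pk_model, pk_obs):
        prob = _Problem(pk_model, pk_obs, TINY, "params")
        params = [Var(a) for a in prob.main.parameters()]
        t = np.array([3.0, 17.0])
        x, v = _feature_matrix(t, TINY, prob.omega)
        u, du = prob.main.forward_tangent(x, v, params)
        h = 1e-6
        xp, _ = _feature_matrix(t + h, TINY, prob.omega)
        xm, _ = _feature_matrix(t - h, TINY, prob.omega)
        up, _ = prob.main.forward_tangent(xp, v, params)
        um, _ = prob.main.forward_tangent(xm, v, params)
        fd = (up.value - um.value) / (2 * h)
        assert np.allclose(du.value, fd, atol=1e-6)


class TestTotalLoss:
    def test_total_is_weighted_component_sum(self, pk_model, pk_obs):
        gray = make_graybox_spec(pk_model, ["h"])
        prob = _Problem(gray, pk_obs, TINY, "graybox")
        lam = AdaptiveWeights(lambda_ode=np.array([2.0, 3.0, 4.0]))
        pv = [Var(a) for a in prob.parameter_arrays()]
        total, comp, ode_comps = prob.loss(pv, lam, 2)
        expected = comp["L_ic"] + comp["L_data"] + sum(
            w * float(c.value) for w, c in zip(lam.lambda_ode, ode_comps))
        assert float(total.value) == pytest.approx(expected, rel=1e-12)

    def test_data_loss_vanishes_when_data_equals_prediction(self, pk_model):
        cfg = PINNConfig(main_net=(8, 2), N_collocation=10, iters_stage1=0,
                         iters_stage2=0, iters_lbfgs=0, T=10.0, seed=0,
                         output_scales={"B": 1.0, "G": 1.0, "U": 1.0})
        traj = simulate_forward(pk_model, t_grid=np.linspace(0, 50, 8))
        obs0 = subsample(traj, 8)
        prob = _Problem(pk_model, obs0, cfg, "params")
        u, _ = forward_nets(obs0.times, prob.main, None, cfg)
        from grayode.synthetic_data import ObservationSet
        obs_match = ObservationSet(obs0.times, u, pk_model.state_names)
        prob2 = _Problem(pk_model, obs_match, cfg, "params")
        _, comp, _ = prob2.loss([Var(a) for a in prob2.parameter_arrays()],
                                AdaptiveWeights(np.ones(3)), 1)
        assert comp["L_data"] < 1e-28

    def test_supervised_stage_has_no_ode_component(self, pk_model, pk_obs):
        prob = _Problem(pk_model, pk_obs, TINY, "params")
        _, comp = total_loss(prob, AdaptiveWeights(np.ones(3)), stage=1)
        assert "L_ode" not in comp


class TestAdaptiveWeights:
    def test_zero_residual_leaves_weights_unchanged(self):
        lam = AdaptiveWeights(lambda_ode=np.ones(3))
        out = adaptive_update(lam, [0.0, 0.0, 0.0], lr=0.1)
        assert np.array_equal(out.lambda_ode, lam.lambda_ode)

    def test_positive_residual_raises_its_weight(self):
        lam = AdaptiveWeights(lambda_ode=np.ones(3))
        out = adaptive_update(lam, [0.0, 5.0, 0.0], lr=0.1)
        assert out.lambda_ode[1] > 1.0
        assert out.lambda_ode[0] == 1.0 and out.lambda_ode[2] == 1.0

    def test_clamped_at_positive_floor(self):
        lam = AdaptiveWeights(lambda_ode=np.array([1e-7]))
        out = adaptive_update(lam, [-100.0], lr=1.0)
        assert out.lambda_ode[0] >= 1e-6

    def test_data_and_ic_weights_fixed(self):
        lam = AdaptiveWeights(lambda_ode=np.ones(2))
        out = adaptive_update(lam, [1.0, 1.0], lr=0.1)
        assert out.lambda_data == 1.0 and out.lambda_ic == 1.0


class TestTraining:
    def test_zero_iterations_returns_initial_networks(self, pk_model, pk_obs):
        cfg = PINNConfig(main_net=(8, 2), N_collocation=10, iters_stage1=0,
                         iters_stage2=0, iters_lbfgs=0, T=10.0, seed=3)
        res = train(pk_model, pk_obs, cfg, mode="params")
        fresh = _Problem(pk_model, pk_obs, cfg, "params")
        for a, b in zip(res.main.parameters(), fresh.main.parameters()):
            assert np.array_equal(a, b)

    def test_short_training_reduces_loss(self, pk_model, pk_obs):
        cfg = PINNConfig(main_net=(16, 3), N_collocation=50, iters_stage1=50,
                         iters_stage2=150, iters_lbfgs=0, T=10.0, seed=0,
                         adaptive_weights=False)
        res = train(pk_model, pk_obs, cfg, mode="params")
        hist = [h["total"] for h in res.loss_history if h["stage"] == 2]
        assert hist[-1] < hist[0]

    def test_deterministic_given_seed(self, pk_model, pk_obs):
        cfg = PINNConfig(main_net=(8, 2), N_collocation=10, iters_stage1=10,
                         iters_stage2=10, iters_lbfgs=0, T=10.0, seed=9)
        a = train(pk_model, pk_obs, cfg, mode="params")
        b = train(pk_model, pk_obs, cfg, mode="params")
        for x, y in zip(a.main.parameters(), b.main.parameters()):
            assert np.array_equal(x, y)
        assert a.params == b.params

    def test_zeroed_head_gives_constant_term(self, pk_model, pk_obs):
        gray = make_graybox_spec(pk_model, ["h"])
        cfg = PINNConfig(main_net=(8, 2), aux_net=(6, 2), N_collocation=10,
                         iters_stage1=0, iters_stage2=0, iters_lbfgs=0,
                         T=10.0, seed=1)
        res = train(gray, pk_obs, cfg, mode="graybox")
        res.aux.weights[-1][:] = 0.0  # zero the output head
        terms = res.predict_terms(np.linspace(0, 50, 20))
        assert np.allclose(terms["h"], terms["h"][0])

    def test_graybox_mode_requires_slots(self, pk_model, pk_obs):
        with pytest.raises(ValueError):
            train(pk_model, pk_obs, TINY, mode="graybox")
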