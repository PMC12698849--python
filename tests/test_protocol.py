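import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splitfedlab as sfl
from splitfedlab.model import ParameterVector
from splitfedlab.protocol import (StaleGradientError, client_step, init_state,
                                  server_step, train_centralized)
from splitfedlab.nn import make_optimizer
from tests.conftest import tiny_spec


def _mini_setup(lr=1e-3, optimizer="sgd"):
    data = sfl.preprocess(sfl.generate_synthetic_images(6, 3, 8, seed=1))
    plan = sfl.partition(data, 1, seed=1)
    cfg = sfl.TrainConfig(n_clients=1, epochs=1, batch_size=4, lr=lr,
                          optimizer=optimizer, seed=1, n_classes=3,
                          image_size=8, spec=tiny_spec())
    state = init_state(cfg, plan)
    return data, plan, cfg, state


class TestServerStep:
    def test_zero_lr_leaves_server_unchanged_but_packet_populated(self):
        data, plan, cfg, state = _mini_setup(lr=0.0)
        before = [a.copy() for a in state.server_part.param_arrays()]
        smashed = sfl.client_forward(state.client_models[0], data.images[:4])
        packet, loss = server_step(state.server_part, state.server_opt,
                                   smashed, data.labels[:4], cfg)
        for a, b in zip(state.server_part.param_arrays(), before):
            assert np.array_equal(a, b)
        assert packet.smashed_grad.shape == smashed.activations.shape
        assert np.isfinite(loss)

    def test_batch_size_mismatch_rejected(self):
        data, plan, cfg, state = _mini_setup()
        smashed = sfl.client_forward(state.client_models[0], data.images[:4])
        with pytest.raises(ValueError):
            server_step(state.server_part, state.server_opt, smashed,
                        data.labels[:3], cfg)

    def test_saturated_prediction_gives_vanishing_gradient(self):
        data, plan, cfg, state = _mini_setup()
        smashed = sfl.client_forward(state.client_models[0], data.images[:1])
        # drive the head to a confident correct answer
        head = state.server_part.layers[-1]
        head.params["weight"][...] = 0.0
        head.params["bias"][...] = -50.0
        head.params["bias"][data.labels[0]] = 50.0
        packet, loss = server_step(state.server_part, state.server_opt,
                                   smashed, data.labels[:1], cfg)
        assert loss < 1e-10
        assert np.abs(packet.smashed_grad).max() < 1e-10


class TestClientStep:
    def test_zero_lr_leaves_client_unchanged(self):
        data, plan, cfg, state = _mini_setup(lr=0.0)
        cmodel = state.client_models[0]
        before = [a.copy() for a in cmodel.client.param_arrays()]
        smashed = sfl.client_forward(cmodel, data.images[:4])
        packet, _ = server_step(state.server_part, state.server_opt, smashed,
                                data.labels[:4], cfg)
        client_step(cmodel.client, state.client_opts[0], packet, cfg)
        for a, b in zip(cmodel.client.param_arrays(), before):
            assert np.array_equal(a, b)
        assert packet.client_param_grads is not None
        assert packet.client_param_grads.size == cmodel.client.n_params()

    def test_stale_packet_rejected(self):
        data, plan, cfg, state = _mini_setup()
        cmodel = state.client_models[0]
        smashed = sfl.client_forward(cmodel, data.images[:4])
        packet, _ = server_step(state.server_part, state.server_opt, smashed,
                                data.labels[:4], cfg, round_idx=3)
        with pytest.raises(StaleGradientError):
            client_step(cmodel.client, state.client_opts[0], packet, cfg,
                        round_idx=4)

    def test_sgd_steps_are_deterministic_and_repeat(self):
        data, plan, cfg, state = _mini_setup(lr=0.1, optimizer="sgd")
        cmodel = state.client_models[0]
        deltas = []
        for _ in range(2):
            before = [a.copy() for a in cmodel.client.param_arrays()]
            smashed = sfl.client_forward(cmodel, data.images[:4])
            opt = make_optimizer("sgd", cmodel.client.param_arrays(), 0.1)
            packet, _ = server_step(state.server_part,
                                    make_optimizer("sgd",
                                                   state.server_part.param_arrays(),
                                                   0.0),
                                    smashed, data.labels[:4], cfg)
            client_step(cmodel.client, opt, packet, cfg)
            deltas.append([a - b for a, b in
                           zip(cmodel.client.param_arrays(), before)])
        # same loss surface, server frozen: successive plain-SGD steps point
        # the same way
        cos = sum(float((d1 * d2).sum()) for d1, d2 in zip(*deltas))
        assert cos > 0


class TestFedAvg:
    def test_mean_of_identical_inputs_is_identity(self, tiny_model):
        pv = ParameterVector.from_model(tiny_model.client)
        avg = sfl.fedavg([pv, pv.copy(), pv.copy()], [3, 2, 1])
        assert np.allclose(avg.flatten(), pv.flatten(), atol=1e-12)

    def test_equal_weight_arithmetic(self):
        a = ParameterVector(["w"], [np.array([2.0])])
        b = ParameterVector(["w"], [np.array([4.0])])
        assert sfl.fedavg([a, b], [1, 1]).arrays[0][0] == 3.0

    def test_degenerate_weight_selects_single_client(self):
        a = ParameterVector(["w"], [np.array([2.0, 5.0])])
        b = ParameterVector(["w"], [np.array([4.0, 1.0])])
        out = sfl.fedavg([a, b], [1, 0])
        assert np.array_equal(out.arrays[0], a.arrays[0])

    def test_matches_bruteforce_weighted_mean_on_random_sets(self):
        rng = np.random.default_rng(0)
        pvs = [ParameterVector(["w", "b"], [rng.normal(size=(3, 2)),
                                            rng.normal(size=4)])
               for _ in range(4)]
        w = [5, 1, 2, 2]
        avg = sfl.fedavg(pvs, w)
        expect = sum(wi * pv.flatten() for wi, pv in zip(w, pvs)) / sum(w)
        assert np.allclose(avg.flatten(), expect, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(perm_seed=st.integers(0, 500))
    def test_permutation_invariance(self, perm_seed):
        rng = np.random.default_rng(7)
        pvs = [ParameterVector(["w"], [rng.normal(size=5)]) for _ in range(4)]
        w = [1.0, 2.0, 3.0, 4.0]
        order = np.random.default_rng(perm_seed).permutation(4)
        a = sfl.fedavg(pvs, w).flatten()
        b = sfl.fedavg([pvs[i] for i in order], [w[i] for i in order]).flatten()
        assert np.allclose(a, b, atol=1e-12)

    def test_invalid_weights_rejected(self):
        pv = ParameterVector(["w"], [np.zeros(2)])
        with pytest.raises(ValueError):
            sfl.fedavg([pv, pv], [0, 0])
        with pytest.raises(ValueError):
            sfl.fedavg([pv, pv], [1, -1])


class TestTrain:
    def test_single_client_equals_centralized(self, synth_small):
        tr, te = sfl.train_test_split_set(synth_small, 0.2, seed=3)
        plan = sfl.partition(tr, 1, seed=3)
        cfg = sfl.TrainConfig(n_clients=1, epochs=1, batch_size=16, seed=3,
                              image_size=16)
        state, h1 = sfl.train(tr, plan, cfg)
        mono, h2 = train_centralized(tr, plan, cfg)
        gm = state.model()
        pairs = zip(gm.client.param_arrays() + gm.server.param_arrays(),
                    mono.client.param_arrays() + mono.server.param_arrays())
        assert max(np.abs(a - b).max() for a, b in pairs) <= 1e-5
        assert h1[0]["loss"] == pytest.approx(h2[0]["loss"], abs=1e-12)

    def test_clients_identical_after_aggregation(self, synth_small):
        plan = sfl.partition(synth_small, 3, seed=0)
        cfg = sfl.TrainConfig(n_clients=3, epochs=2, batch_size=16, seed=0,
                              image_size=16)
        state, _ = sfl.train(synth_small, plan, cfg)
        ref = ParameterVector.from_model(state.client_models[0].client).flatten()
        for m in state.client_models[1:]:
            assert np.array_equal(
                ParameterVector.from_model(m.client).flatten(), ref)

    def test_samples_per_epoch_and_finite_losses(self, synth_small):
        plan = sfl.partition(synth_small, 2, seed=1)
        cfg = sfl.TrainConfig(n_clients=2, epochs=2, batch_size=16, seed=1,
                              image_size=16)
        state, history = sfl.train(synth_small, plan, cfg)
        for row in history:
            assert row["n_samples"] == sum(plan.shard_sizes)
            assert np.isfinite(row["loss"])

    def test_two_client_run_reaches_target_accuracy(self, trained_splitfed):
        assert trained_splitfed["history"][-1]["accuracy"] >= 0.90

    def test_zero_lr_train_rejected(self, synth_small):
        plan = sfl.partition(synth_small, 1, seed=0)
        cfg = sfl.TrainConfig(n_clients=1, epochs=1, lr=0.0, image_size=16)
        with pytest.raises(ValueError):
            sfl.train(synth_small, plan, cfg)


class TestEvaluate:
    def test_perfect_predictions_and_report_shape(self, trained_splitfed):
        report = sfl.evaluate(trained_splitfed["state"], trained_splitfed["test"])
        assert report.n_classes == 4
        assert report.confusion.sum() == len(trained_splitfed["test"])
        assert report.accuracy >= 0.90
        assert report.weighted_f1 >= 0.90

    def test_empty_test_set_rejected(self, trained_splitfed):
        empty = trained_splitfed["test"].subset([])
        with pytest.raises(ValueError):
            sfl.evaluate(trained_splitfed["state"], empty)
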