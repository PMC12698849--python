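import numpy as np
import pytest
import scipy.stats as st

import splitfedlab as sfl
from splitfedlab.dp import (add_noise_to_params, add_noise_to_transmission,
                            cauchy_pdf, noise_center, noisy_update,
                            restore_parameters, sample_noise)
from splitfedlab.model import ParameterVector
from splitfedlab.protocol import init_state


class TestNoiseSpec:
    def test_invalid_family_scale_targets(self):
        with pytest.raises(ValueError):
            sfl.NoiseSpec(family="uniform")
        with pytest.raises(ValueError):
            sfl.NoiseSpec(sigma=0.0)
        with pytest.raises(ValueError):
            sfl.NoiseSpec(targets=("weights",))
        with pytest.raises(ValueError):
            sfl.NoiseSpec(targets=())


class TestSampler:
    def test_cauchy_pdf_peak_value(self):
        # density at the location is 1 / (pi sigma)
        assert cauchy_pdf(0.0, 0.0, 1.0) == pytest.approx(1 / np.pi)
        assert cauchy_pdf(2.0, 2.0, 0.5) == pytest.approx(1 / (np.pi * 0.5))
        assert cauchy_pdf(0.0, 0.0, 1.0) == pytest.approx(0.31831, abs=1e-5)

    def test_cauchy_empirical_median_concentrates_at_location(self):
        spec = sfl.NoiseSpec(family="cauchy", gamma=2.0, sigma=1.0)
        draws = sample_noise(spec, 100_000, np.random.default_rng(0))
        assert 1.98 <= np.median(draws) <= 2.02

    def test_exponential_support_is_one_sided(self):
        spec = sfl.NoiseSpec(family="exponential", gamma=0.0, sigma=2.0)
        draws = sample_noise(spec, 10_000, np.random.default_rng(1))
        assert draws.min() >= 0.0
        # sigma is the mean of the shifted draw
        assert np.mean(draws) == pytest.approx(2.0, rel=0.05)

    def test_reproducible_given_rng_state(self):
        spec = sfl.NoiseSpec(family="laplace", gamma=1.0, sigma=0.3)
        a = sample_noise(spec, (5, 5), np.random.default_rng(9))
        b = sample_noise(spec, (5, 5), np.random.default_rng(9))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("family,dist", [
        ("gaussian", lambda g, s: st.norm(loc=g, scale=s)),
        ("laplace", lambda g, s: st.laplace(loc=g, scale=s)),
        ("cauchy", lambda g, s: st.cauchy(loc=g, scale=s)),
        ("exponential", lambda g, s: st.expon(loc=g, scale=s)),
    ])
    @pytest.mark.parametrize("gamma,sigma", [(0.0, 1.0), (2.0, 0.5)])
    def test_goodness_of_fit_against_analytic_cdf(self, family, dist, gamma, sigma):
        from splitfedlab.dp import FAMILIES

        spec = sfl.NoiseSpec(family=family, gamma=gamma, sigma=sigma)
        draws = sample_noise(spec, 10_000,
                             np.random.default_rng([FAMILIES.index(family), 4]))
        pvalue = st.kstest(draws, dist(gamma, sigma).cdf).pvalue
        assert pvalue > 0.01

    def test_heavy_tail_ordering_cauchy_vs_gaussian(self):
        rng = np.random.default_rng(3)
        c = sample_noise(sfl.NoiseSpec(family="cauchy", sigma=1.0), 10_000, rng)
        g = sample_noise(sfl.NoiseSpec(family="gaussian", sigma=1.0), 10_000, rng)
        assert np.quantile(np.abs(c), 0.999) > np.quantile(np.abs(g), 0.999)

    def test_noise_center_by_family(self):
        assert noise_center(sfl.NoiseSpec(family="gaussian", gamma=1.5)) == 1.5
        assert noise_center(sfl.NoiseSpec(family="cauchy", gamma=0.0)) == 0.0
        assert noise_center(
            sfl.NoiseSpec(family="exponential", gamma=1.0, sigma=2.0)) == 3.0


class TestInjectionPoints:
    def _pv(self):
        rng = np.random.default_rng(0)
        return ParameterVector(["w", "b"], [rng.normal(size=(3, 2)),
                                            rng.normal(size=4)])

    def test_param_noise_additive_contract(self):
        pv = self._pv()
        spec = sfl.NoiseSpec(family="gaussian", sigma=0.1,
                             targets=("parameters",))
        before = pv.flatten().copy()
        rng = np.random.default_rng(2)
        noisy = add_noise_to_params(pv, spec, np.random.default_rng(2))
        noise = sample_noise(spec, before.shape, rng)
        assert np.array_equal(pv.flatten(), before)  # original untouched
        assert np.array_equal(noisy.flatten(), before + noise)

    def test_zero_noise_hook_is_identity(self):
        pv = self._pv()
        spec = sfl.NoiseSpec(family="cauchy", sigma=1.0, targets=("parameters",))
        noisy = add_noise_to_params(pv, spec, np.random.default_rng(0),
                                    noise=np.zeros(pv.n_params))
        assert np.array_equal(noisy.flatten(), pv.flatten())

    def test_param_noise_mean_concentration(self):
        # 1e4 zero-valued scalars, gaussian(gamma=5, sigma=0.01):
        # CLT bound on the mean, 5 +/- 0.001
        pv = ParameterVector(["w"], [np.zeros(10_000)])
        spec = sfl.NoiseSpec(family="gaussian", gamma=5.0, sigma=0.01,
                             targets=("parameters",))
        noisy = add_noise_to_params(pv, spec, np.random.default_rng(6))
        assert abs(noisy.flatten().mean() - 5.0) < 0.001

    def test_transmission_noise_record_and_metadata(self, tiny_model):
        x = np.random.default_rng(0).uniform(-1, 1, (3, 8, 8))
        smashed = sfl.client_forward(tiny_model, x, labels=np.array([0, 1, 2]))
        spec = sfl.NoiseSpec(family="laplace", sigma=0.5,
                             targets=("activations",))
        rec = add_noise_to_transmission(smashed, spec, np.random.default_rng(1))
        assert np.array_equal(rec.noisy, rec.original + rec.noise)
        assert np.array_equal(smashed.labels, [0, 1, 2])  # labels untouched
        rec0 = add_noise_to_transmission(smashed, spec, np.random.default_rng(1),
                                         noise=np.zeros_like(rec.original))
        assert np.array_equal(rec0.noisy, rec0.original)

    def test_server_output_perturbation_vanishes_with_scale(self, tiny_model):
        x = np.random.default_rng(0).uniform(-1, 1, (4, 8, 8))
        smashed = sfl.client_forward(tiny_model, x)
        clean = sfl.server_forward(tiny_model, smashed)
        diffs = []
        for sigma in (1.0, 1e-3, 1e-6):
            spec = sfl.NoiseSpec(family="gaussian", sigma=sigma,
                                 targets=("activations",))
            rec = add_noise_to_transmission(smashed, spec,
                                            np.random.default_rng(5))
            noisy_scores = tiny_model.server.forward(rec.noisy)
            diffs.append(np.abs(noisy_scores - clean).max())
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-4


class TestNoisyUpdate:
    def test_zero_noise_is_plain_gradient_step(self):
        pv = ParameterVector(["w"], [np.array([1.0, 2.0])])
        grad = np.array([0.5, -0.5])
        spec = sfl.NoiseSpec(family="cauchy", sigma=1.0)
        out = noisy_update(pv, grad, lr=0.1, spec=spec,
                           rng=np.random.default_rng(0), noise=np.zeros(2))
        assert np.allclose(out.flatten(), [0.95, 2.05])

    def test_zero_lr_zero_noise_is_identity(self):
        pv = ParameterVector(["w"], [np.array([1.0, 2.0])])
        out = noisy_update(pv, np.array([3.0, 4.0]), lr=0.0,
                           spec=sfl.NoiseSpec(family="cauchy"),
                           rng=np.random.default_rng(0), noise=np.zeros(2))
        assert np.array_equal(out.flatten(), pv.flatten())

    def test_seeded_update_bitwise_reproducible(self):
        pv = ParameterVector(["w"], [np.array([1.0, 2.0])])
        spec = sfl.NoiseSpec(family="cauchy", sigma=0.5)
        a = noisy_update(pv, np.zeros(2), 0.1, spec, np.random.default_rng(8))
        b = noisy_update(pv, np.zeros(2), 0.1, spec, np.random.default_rng(8))
        assert np.array_equal(a.flatten(), b.flatten())


class TestRestoration:
    def test_restore_after_param_noise_round_trip(self, synth_small):
        plan = sfl.partition(synth_small, 2, seed=0)
        cfg = sfl.TrainConfig(n_clients=2, epochs=1, image_size=16, seed=0)
        state = init_state(cfg, plan)
        before = [ParameterVector.from_model(m.client).flatten()
                  for m in state.client_models]
        state.pristine_client_params = [
            ParameterVector.from_model(m.client) for m in state.client_models]
        # corrupt the working copies, then restore
        for m in state.client_models:
            for arr in m.client.param_arrays():
                arr += 1.0
        restore_parameters(state)
        after = [ParameterVector.from_model(m.client).flatten()
                 for m in state.client_models]
        for a, b in zip(before, after):
            assert np.array_equal(a, b)

    def test_restore_without_pristine_copy_errors(self, synth_small):
        plan = sfl.partition(synth_small, 1, seed=0)
        cfg = sfl.TrainConfig(n_clients=1, epochs=1, image_size=16)
        state = init_state(cfg, plan)
        with pytest.raises(RuntimeError):
            restore_parameters(state)

    def test_parameter_only_noise_leaves_trajectory_unchanged(self, synth_small):
        plan = sfl.partition(synth_small, 2, seed=4)
        clean_cfg = sfl.TrainConfig(n_clients=2, epochs=2, image_size=16, seed=4)
        noisy_cfg = sfl.TrainConfig(
            n_clients=2, epochs=2, image_size=16, seed=4,
            noise=sfl.NoiseSpec(family="cauchy", sigma=10.0,
                                targets=("parameters",)))
        s1, h1 = sfl.train(synth_small, plan, clean_cfg)
        s2, h2 = sfl.train(synth_small, plan, noisy_cfg)
        a = s1.global_client.flatten()
        b = s2.global_client.flatten()
        assert np.array_equal(a, b)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]
        # but the adversary-visible outbound copies were noisy
        assert s2.last_outbound_params is not None
        assert not np.array_equal(s2.last_outbound_params[0].flatten(),
                                  s2.global_client.flatten())
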