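import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import transaug.generative_models as gm
from transaug import engine as eg
from transaug.attention_masks import AttentionMask
from transaug.datasets_io import ExpressionDataset
from transaug.quality_metrics import adversarial_accuracy, precision_recall

from conftest import two_mode_mixture


class TestGanLosses:
    def test_maximal_confusion_point(self):
        losses = gm.gan_losses([0.5, 0.5], [0.5, 0.5])
        assert losses.value == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_perfect_discriminator(self):
        losses = gm.gan_losses([1.0, 1.0], [0.0, 0.0])
        assert losses.value == pytest.approx(0.0, abs=1e-5)

    def test_direct_evaluation(self):
        losses = gm.gan_losses([0.8], [0.3])
        assert losses.value == pytest.approx(np.log(0.8) + np.log(0.7), abs=1e-9)
        assert losses.generator_loss == pytest.approx(-np.log(0.3), abs=1e-9)
        assert losses.saturating_generator_loss == pytest.approx(np.log(0.7), abs=1e-9)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError, match="d_true"):
            gm.gan_losses([1.2], [0.5])


class TestWganGpLosses:
    def test_separated_scores(self):
        losses = gm.wgan_gp_losses([1.0], [0.0], penalty=0.0)
        assert losses.wasserstein_estimate == 1.0
        assert losses.critic_loss == -1.0

    def test_indistinguishable(self):
        losses = gm.wgan_gp_losses([0.3, 0.7], [0.3, 0.7])
        assert losses.wasserstein_estimate == 0.0

    def test_direct_evaluation(self):
        losses = gm.wgan_gp_losses([2.0, 4.0], [1.0, 1.0], penalty=0.5)
        assert losses.critic_loss == pytest.approx(-1.5)
        assert losses.generator_loss == pytest.approx(-1.0)


class TestGradientPenalty:
    def linear_critic(self, w):
        wt = eg.Tensor(np.asarray(w, dtype=float)[:, None])
        return lambda x: x @ wt

    def test_unit_lipschitz_critic_zero(self, rng):
        critic = self.linear_critic([0.6, 0.8])  # ||w|| = 1
        gp = gm.gradient_penalty(critic, rng.random((8, 2)), rng.random((8, 2)), 10.0, 0)
        assert gp == pytest.approx(0.0, abs=1e-4)

    def test_constant_critic_gives_lambda(self, rng):
        critic = lambda x: x @ eg.Tensor(np.zeros((3, 1)))
        gp = gm.gradient_penalty(critic, rng.random((8, 3)), rng.random((8, 3)), 7.5, 0)
        assert gp == pytest.approx(7.5, abs=1e-4)

    def test_two_lipschitz_critic(self, rng):
        critic = self.linear_critic([1.2, 1.6])  # ||w|| = 2
        gp = gm.gradient_penalty(critic, rng.random((8, 2)), rng.random((8, 2)), 10.0, 0)
        assert gp == pytest.approx(10.0, abs=1e-4)

    def test_nonnegative_for_random_mlp_critic(self, rng):
        critic = eg.MLP(4, (8,), 1, np.random.default_rng(3))
        gp = gm.gradient_penalty(critic, rng.random((6, 4)), rng.random((6, 4)), 10.0, 1)
        assert gp >= 0.0

    def test_shape_mismatch(self, rng):
        critic = self.linear_critic([1.0, 0.0])
        with pytest.raises(ValueError, match="shape"):
            gm.gradient_penalty(critic, rng.random((4, 2)), rng.random((5, 2)))


def full_mask(d):
    return AttentionMask(
        {(i, j) for i in range(d) for j in range(d) if i != j}, d, "coexp"
    )


class TestSparseAttention:
    def test_gamma_zero_is_identity(self, rng):
        params = gm.AttentionLayerParams(
            rng.normal(size=3), rng.normal(size=3), rng.normal(size=3), 0.0, full_mask(3)
        )
        x = rng.random(3)
        assert np.array_equal(gm.sparse_attention(x, params), x)

    def test_equal_scores_split_weight(self):
        # gene 0 with two neighbors at identical values -> equal alphas;
        # self score is also 0, so the three-way softmin is uniform
        mask = AttentionMask({(0, 1), (1, 0), (0, 2), (2, 0)}, 3, "coexp")
        params = gm.AttentionLayerParams(np.ones(3), np.ones(3), np.ones(3), 1.0, mask)
        x = np.array([0.4, 0.4, 0.4])
        out = gm.sparse_attention(x, params)
        assert out[0] == pytest.approx(0.4 + 0.4)  # alpha sums to 1, values all 0.4

    def test_hand_evaluated_two_gene_example(self):
        params = gm.AttentionLayerParams(
            np.ones(2), np.ones(2), np.ones(2), 1.0, full_mask(2)
        )
        out = gm.sparse_attention(np.array([1.0, 2.0]), params)
        a = np.exp(0) / (np.exp(0) + np.exp(-1))
        assert out[0] == pytest.approx(1.0 + (a * 1.0 + (1 - a) * 2.0), abs=1e-4)
        assert out[0] == pytest.approx(2.269, abs=1e-3)

    def test_mask_index_out_of_range(self, rng):
        mask = full_mask(3)
        params = gm.AttentionLayerParams(
            np.ones(3), np.ones(3), np.ones(3), 1.0, mask
        )
        with pytest.raises(ValueError, match="length"):
            gm.sparse_attention(rng.random(5), params)
        with pytest.raises(ValueError):
            gm.AttentionLayerParams(np.ones(2), np.ones(2), np.ones(2), 1.0, mask)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_softmin_weights_sum_to_one(self, seed):
        # with the as-printed convention the output collapses to
        # x + gamma * w_v * x exactly iff the alphas sum to 1
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 8))
        mask = full_mask(d)
        w_v = rng.normal(size=d)
        params = gm.AttentionLayerParams(
            rng.normal(size=d), rng.normal(size=d), w_v, 1.0, mask, as_printed=True
        )
        x = rng.random(d)
        assert np.allclose(gm.sparse_attention(x, params), x + w_v * x, atol=1e-6)

    def test_neighbor_convention_with_constant_input(self, rng):
        d = 4
        params = gm.AttentionLayerParams(
            rng.normal(size=d), rng.normal(size=d), np.ones(d), 0.5, full_mask(d)
        )
        x = np.full(d, 0.3)
        # all values equal 0.3, so any convex combination returns 0.3
        assert np.allclose(gm.sparse_attention(x, params), 0.3 + 0.5 * 0.3, atol=1e-9)

    def test_layer_matches_functional(self, rng):
        mask = AttentionMask({(0, 1), (1, 0), (2, 3), (3, 2)}, 5, "coexp")
        layer = gm.AttentionLayer(mask, np.random.default_rng(1))
        x = rng.random((6, 5))
        assert np.allclose(
            layer(eg.Tensor(x)).data, gm.sparse_attention(x, layer.to_params())
        )


class TestBuildGenerator:
    def test_output_shape_and_bounds(self, rng):
        config = gm.toy_config("wgan_gp")
        gen = gm.build_generator(config, n_genes=7, rng=0)
        out = gen(eg.Tensor(rng.normal(size=(5, config.d_z))))
        assert out.data.shape == (5, 7)
        assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_seeding_contract(self):
        config = gm.toy_config("wgan_gp")
        g1 = gm.build_generator(config, 5, rng=3)
        g2 = gm.build_generator(config, 5, rng=3)
        for p1, p2 in zip(g1.parameters, g2.parameters):
            assert np.array_equal(p1.data, p2.data)

    def test_attention_requires_mask(self):
        with pytest.raises(ValueError, match="mask"):
            gm.build_generator(gm.toy_config("attgan"), 5, rng=0)


@pytest.fixture(scope="module")
def mixture_data():
    return two_mode_mixture(200, 0)


class TestTrain:
    def test_history_bookkeeping_one_epoch(self, mixture_data):
        config = gm.toy_config("gan", epochs=1, batch_size=200, conditional=False)
        model = gm.train(mixture_data, config)
        assert len(model.history["g_loss"]) == 1
        assert len(model.history["d_loss"]) == 1

    def test_short_wgan_recovers_both_modes(self):
        x = two_mode_mixture(500, 0)
        held = two_mode_mixture(500, 1000)
        config = gm.toy_config(
            "wgan_gp", epochs=10_000, max_steps=300, conditional=False, seed=0
        )
        model = gm.train(x, config)
        gen = gm.generate(model, 500, seed=0).values
        _, recall, _ = precision_recall(held, gen, k=5)
        assert recall >= 0.7

    def test_conditional_training_smoke(self, toy_dataset):
        config = gm.toy_config("wgan_gp", epochs=2, seed=1)
        model = gm.train(toy_dataset, config)
        assert model.encoder is not None
        gen = gm.generate(model, 50, seed=2)
        assert gen.covariates is not None

    def test_gamma_zero_attgan_matches_attention_free(self, toy_dataset):
        small = toy_dataset.subset(range(64))
        mask = full_mask(5)
        base_kwargs = dict(epochs=3, batch_size=32, seed=5, conditional=False)
        data = small.values[:, :5]
        plain = gm.train(data, gm.toy_config("wgan_gp", **base_kwargs))
        att = gm.train(
            data,
            gm.toy_config("attgan", gamma_mode="fixed", gamma_init=0.0, **base_kwargs),
            mask=mask,
        )
        for p1, p2 in zip(plain.generator.mlp.parameters, att.generator.mlp.parameters):
            assert np.allclose(p1.data, p2.data, atol=1e-12)
        assert np.allclose(
            plain.history["d_loss"], att.history["d_loss"], atol=1e-12
        )

    def test_attgan_learns_gamma(self, mixture_data):
        mask = full_mask(2)
        config = gm.toy_config(
            "attgan", epochs=3, conditional=False, gamma_mode="learned", seed=2
        )
        model = gm.train(mixture_data, config, mask=mask)
        assert "gamma" in model.history

    def test_rand_attgan_permutes_mask(self, mixture_data):
        mask = AttentionMask({(0, 1), (1, 0)}, 2, "ppi")
        config = gm.toy_config("rand_attgan", epochs=1, conditional=False, seed=0)
        model = gm.train(mixture_data, config, mask=mask)
        assert model.mask.provenance == "random"
        assert len(model.mask) == len(mask)

    def test_pretrain_disables_attention_then_enables(self, mixture_data):
        mask = full_mask(2)
        config = gm.toy_config(
            "attgan", epochs=2, pretrain_epochs=1, conditional=False, seed=0
        )
        model = gm.train(mixture_data, config, mask=mask)
        assert model.generator.attention.enabled


@pytest.fixture(scope="module")
def trained(toy_dataset):
    config = gm.toy_config("wgan_gp", epochs=2, seed=0)
    return gm.train(toy_dataset, config)


class TestGenerate:
    def test_counts_and_observed_patterns(self, trained, toy_dataset):
        gen = gm.generate(trained, 1000, toy_dataset, seed=0)
        assert gen.n_samples == 1000
        observed = set(
            map(tuple, toy_dataset.covariates[["gender", "tissue", "cancer"]].itertuples(index=False))
        )
        produced = set(
            map(tuple, gen.covariates[["gender", "tissue", "cancer"]].itertuples(index=False))
        )
        assert produced <= observed

    def test_reproducible_per_seed(self, trained, toy_dataset):
        a = gm.generate(trained, 20, toy_dataset, seed=9)
        b = gm.generate(trained, 20, toy_dataset, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_output_in_unit_interval(self, trained, toy_dataset):
        gen = gm.generate(trained, 200, toy_dataset, seed=1)
        assert gen.values.min() >= 0 and gen.values.max() <= 1

    def test_untrained_model_has_high_adversarial_accuracy(self):
        x = two_mode_mixture(300, 3)
        config = gm.toy_config("wgan_gp", conditional=False, seed=4)
        model = gm.GenerativeModel(
            generator=gm.build_generator(config, 2, rng=4),
            discriminator=gm.build_discriminator(config, 2, rng=5),
            config=config,
            gene_ids=["gene_0", "gene_1"],
        )
        gen = gm.generate(model, 300, seed=4)
        assert adversarial_accuracy(x, gen.values) > 0.9

    def test_bad_m(self, trained):
        with pytest.raises(ValueError, match="positive"):
            gm.generate(trained, 0)


def test_checkpoint_round_trip(tmp_path, mixture_data=None):
    x = two_mode_mixture(100, 1)
    config = gm.toy_config("wgan_gp", epochs=1, conditional=False, seed=0)
    model = gm.train(x, config)
    path = tmp_path / "model.ckpt"
    gm.save_model(model, path)
    back = gm.load_model(path)
    a = gm.generate(model, 10, seed=0).values
    b = gm.generate(back, 10, seed=0).values
    assert np.array_equal(a, b)
    assert (tmp_path / "model.ckpt.json").exists()
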