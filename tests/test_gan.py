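"""Cross-modal GAN: network contracts, adversarial updates, gradient flow
through the sonification, and conditional generation."""

import numpy as np
import pytest

from soundsight import nn
from soundsight.gan import CrossModalGAN, Discriminator, Generator


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


class TestGenerator:
    def test_output_shape_and_range_28(self, rng):
        gen = Generator(image_size=28, embed_dim=128, noise_dim=100,
                        base_channels=16, rng=np.random.default_rng(1))
        emb = rng.normal(size=(3, 128))
        noise = rng.normal(size=(3, 100))
        img = gen.forward(emb, noise)
        assert img.shape == (3, 28, 28)
        assert img.data.min() >= 0.0 and img.data.max() <= 1.0

    def test_upsampling_quadruples_feature_map_area(self):
        # 28 -> base 7 -> 14 -> 28: each step doubles the side
        gen = Generator(28, 128, 100, 16, np.random.default_rng(0))
        assert gen.base == 7

    def test_deterministic_given_inputs(self, rng):
        emb = rng.normal(size=(2, 128))
        noise = rng.normal(size=(2, 100))
        gen = Generator(8, 128, 100, 8, np.random.default_rng(2))
        a = gen.forward(emb, noise).data
        b = gen.forward(emb, noise).data
        np.testing.assert_array_equal(a, b)

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            Generator(30, 128, 100, 8, np.random.default_rng(0))


class TestDiscriminator:
    def test_two_heads(self, rng):
        disc = Discriminator((16, 16), n_classes=4, channels=(8, 16),
                             fc_width=32, rng=np.random.default_rng(3))
        feats = nn.Tensor(rng.normal(size=(5, 16, 16)))
        src, cls = disc.forward(feats)
        assert src.shape == (5, 1)
        assert cls.shape == (5, 4)
        probs = nn.softmax(cls.data)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_untrained_source_scores_near_half(self, rng):
        disc = Discriminator((16, 16), 2, (8, 16), 32,
                             np.random.default_rng(4))
        feats = nn.Tensor(rng.normal(size=(64, 16, 16)))
        src, _ = disc.forward(feats)
        mean_score = float(src.sigmoid().data.mean())
        assert 0.3 <= mean_score <= 0.7


class TestTrainStep:
    @pytest.fixture()
    def prepared(self, toy_profile, toy_corpus, toy_codec, toy_frontend,
                 toy_encoder):
        from soundsight.frontend import sonify_and_featurize
        images, labels, split = toy_corpus
        gan = CrossModalGAN(encoder=toy_encoder, codec_config=toy_codec,
                            frontend_config=toy_frontend, seed=0,
                            **toy_profile["gan"])
        gan._init_models(2)
        feats = sonify_and_featurize(images[split.train], toy_codec,
                                     toy_frontend)
        embeds = toy_encoder.embed(feats)
        return gan, feats * gan.feature_scale, embeds, labels[split.train]

    def test_discriminator_loss_decreases_over_50_steps(self, prepared):
        gan, feats, embeds, labels = prepared
        batch = slice(0, 20)
        losses = [gan.train_step(feats[batch], embeds[batch],
                                 labels[batch])["d_loss"]
                  for _ in range(50)]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_frozen_generator_untouched_by_discriminator_step(self,
                                                              prepared):
        gan, feats, embeds, labels = prepared
        before = [p.data.copy() for p in gan.generator_.params]
        gan.train_step(feats[:20], embeds[:20], labels[:20],
                       update_generator=False)
        for p, b in zip(gan.generator_.params, before):
            np.testing.assert_array_equal(p.data, b)

    def test_generator_gradient_matches_finite_differences(self, prepared):
        """Backprop through discriminator, log-mel and sonification agrees
        with a finite-difference probe of a generator parameter."""
        gan, feats, embeds, labels = prepared
        noise = np.random.default_rng(9).standard_normal((4, gan.noise_dim))
        loss = gan._generator_loss(embeds[:4], labels[:4], noise)
        for p in gan.generator_.params:
            p.zero_grad()
        loss.backward()
        w = gan.generator_.fc.w
        flat_idx = int(np.argmax(np.abs(w.grad)))
        idx = np.unravel_index(flat_idx, w.shape)
        g_bp = w.grad[idx]
        eps = 1e-5
        orig = w.data[idx]
        w.data[idx] = orig + eps
        up = float(gan._generator_loss(embeds[:4], labels[:4], noise).data)
        w.data[idx] = orig - eps
        dn = float(gan._generator_loss(embeds[:4], labels[:4], noise).data)
        w.data[idx] = orig
        fd = (up - dn) / (2 * eps)
        assert abs(g_bp - fd) / (abs(fd) + 1e-12) <= 1e-2

    def test_nonfinite_loss_aborts(self, prepared):
        gan, feats, embeds, labels = prepared
        gan.generator_.fc.w.data[:] = np.inf
        with pytest.raises(RuntimeError, match="non-finite"):
            gan.train_step(feats[:4], embeds[:4], labels[:4])


class TestGeneration:
    def test_counts_range_and_determinism(self, toy_gan, toy_encoder,
                                          toy_features, toy_corpus):
        _, labels, split = toy_corpus
        emb = toy_encoder.embed(toy_features[split.test][:4])
        lab = labels[split.test][:4]
        imgs, out_labels = toy_gan.generate(emb, lab, n_per_embedding=3,
                                            seed=7)
        assert imgs.shape == (12, 8, 8)
        assert imgs.min() >= 0.0 and imgs.max() <= 1.0
        np.testing.assert_array_equal(out_labels, np.repeat(lab, 3))
        imgs2, _ = toy_gan.generate(emb, lab, n_per_embedding=3, seed=7)
        np.testing.assert_array_equal(imgs, imgs2)

    def test_noise_drives_diversity(self, toy_gan, toy_encoder,
                                    toy_features):
        emb = toy_encoder.embed(toy_features[:1])
        imgs, _ = toy_gan.generate(emb, np.array([0]), n_per_embedding=2,
                                   seed=3)
        frac_diff = np.mean(np.abs(imgs[0] - imgs[1]) > 1e-3)
        assert frac_diff >= 0.01

    def test_class_conditional_means_differ(self, toy_gan, toy_encoder,
                                            toy_features, toy_corpus):
        _, labels, split = toy_corpus
        emb = toy_encoder.embed(toy_features[split.test])
        lab = labels[split.test]
        imgs, out_labels = toy_gan.generate(emb, lab, n_per_embedding=4,
                                            seed=1)
        mean0 = imgs[out_labels == 0].mean(axis=0)
        mean1 = imgs[out_labels == 1].mean(axis=0)
        assert np.linalg.norm(mean0 - mean1) > 0.0

    def test_discriminator_never_sees_raw_images(self, toy_gan):
        """The discriminator input width equals the log-mel feature shape,
        not the image shape."""
        fcfg = toy_gan.frontend_config
        assert toy_gan.discriminator_.feat_hw == (fcfg.n_mels,
                                                  fcfg.n_frames)
        assert (fcfg.n_mels, fcfg.n_frames) != (toy_gan.image_size,
                                                toy_gan.image_size)
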