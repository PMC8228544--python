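"""Cross-modal auxiliary-classifier GAN.

The generator maps a 128-d audio embedding plus 100-d noise to a grayscale
image; the discriminator never sees raw images.  Instead, both real and
generated images are passed through the differentiable sonify + log-mel
graph, and the discriminator judges the resulting time-frequency features
with two heads: a sigmoid source head (real vs generated) and a softmax
class head.  Gradients reach the generator *through* the sonification,
which is what couples image synthesis to the audio domain and makes the
whole pipeline sensitive to the soundscape compression ratio.

Losses follow the standard auxiliary-classifier objective: both players
optimize the class log-likelihood, while the source term is adversarial.
Setting ``class_loss_weight = 0`` reduces to a vanilla conditional GAN.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .codec import CodecConfig
from .frontend import FrontendConfig, logmel_differentiable, \
    sonify_and_featurize

__all__ = ["Generator", "Discriminator", "CrossModalGAN"]


class Generator:
    """Embedding + noise -> image.

    A dense layer seeds a ``(base x base)`` feature map (``base = size/4``);
    two upsampling steps each quadruple the feature-map area (side x2),
    giving ``base -> 2*base -> size``; a final sigmoid keeps pixels in
    [0, 1].
    """

    def __init__(self, image_size: int, embed_dim: int, noise_dim: int,
                 base_channels: int, rng: np.random.Generator):
        if image_size % 4:
            raise ValueError("image_size must be divisible by 4")
        self.image_size = image_size
        self.base = image_size // 4
        self.ch = base_channels
        self.fc = nn.Linear(embed_dim + noise_dim,
                            self.ch * self.base * self.base, rng)
        self.conv1 = nn.Conv2d(self.ch, self.ch // 2, rng)
        self.conv2 = nn.Conv2d(self.ch // 2, 1, rng)

    def forward(self, embed: np.ndarray, noise: np.ndarray) -> nn.Tensor:
        z = nn.concat([nn.as_tensor(embed), nn.as_tensor(noise)], axis=1)
        n = z.shape[0]
        h = self.fc(z).relu().reshape(n, self.ch, self.base, self.base)
        h = self.conv1(nn.upsample2x(h)).relu()
        img = self.conv2(nn.upsample2x(h)).sigmoid()
        return img.reshape(n, self.image_size, self.image_size)

    @property
    def params(self):
        return [*self.fc.params, *self.conv1.params, *self.conv2.params]


class Discriminator:
    """Log-mel feature -> (source logit, class logits)."""

    def __init__(self, feat_hw: tuple[int, int], n_classes: int,
                 channels: tuple[int, int], fc_width: int,
                 rng: np.random.Generator):
        self.feat_hw = feat_hw
        self.conv1 = nn.Conv2d(1, channels[0], rng)
        self.conv2 = nn.Conv2d(channels[0], channels[1], rng)
        h, w = feat_hw[0] // 4, feat_hw[1] // 4
        self.fc = nn.Linear(channels[1] * h * w, fc_width, rng)
        # small-scale head init keeps untrained outputs near neutral
        self.head_src = nn.Linear(fc_width, 1, rng, scale=1e-2)
        self.head_cls = nn.Linear(fc_width, n_classes, rng, scale=1e-2)

    def forward(self, feats: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        n = feats.shape[0]
        h = feats.reshape(n, 1, *self.feat_hw)
        h = nn.maxpool2d(self.conv1(h).relu())
        h = nn.maxpool2d(self.conv2(h).relu())
        h = self.fc(h.reshape(n, int(np.prod(h.shape[1:])))).relu()
        return self.head_src(h), self.head_cls(h)

    @property
    def params(self):
        return [*self.conv1.params, *self.conv2.params, *self.fc.params,
                *self.head_src.params, *self.head_cls.params]


class CrossModalGAN(BaseEstimator):
    """Audio-conditioned image generator trained adversarially in the
    audio-feature domain.

    Parameters
    ----------
    encoder : AudioEncoderClassifier
        Trained (and frozen) audio encoder supplying 128-d embeddings.
    codec_config, frontend_config
        Sonification and log-mel settings shared by both GAN paths.
    image_size : int
        Side of the square generated image (divisible by 4).
    embed_dim, noise_dim : int
        Conditioning sizes (128 and 100).
    lr, batch_size, epochs, seed
        Adam step size (1e-3 default), batch size (100 default), training
        epochs, and the seed controlling init, shuffling and noise.
    class_loss_weight : float
        Weight of the auxiliary class term; 0 disables it (vanilla
        conditional GAN ablation).
    feature_scale : float
        Constant rescaling applied to log-mel features before the
        discriminator (keeps inputs O(1)).
    """

    def __init__(self, encoder=None, codec_config: CodecConfig | None = None,
                 frontend_config: FrontendConfig | None = None,
                 image_size: int = 28, embed_dim: int = 128,
                 noise_dim: int = 100, lr: float = 1e-3,
                 batch_size: int = 100, epochs: int = 50, seed: int = 0,
                 gen_base_channels: int = 32,
                 disc_channels: tuple[int, int] = (16, 32),
                 disc_fc: int = 128, class_loss_weight: float = 1.0,
                 disc_lr: float | None = None, feature_scale: float = 0.1):
        self.encoder = encoder
        self.codec_config = codec_config
        self.frontend_config = frontend_config
        self.image_size = image_size
        self.embed_dim = embed_dim
        self.noise_dim = noise_dim
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.gen_base_channels = gen_base_channels
        self.disc_channels = disc_channels
        self.disc_fc = disc_fc
        self.class_loss_weight = class_loss_weight
        self.disc_lr = disc_lr
        self.feature_scale = feature_scale

    # -- construction ---------------------------------------------------
    def _init_models(self, n_classes: int):
        rng = np.random.default_rng(self.seed)
        fcfg = self.frontend_config
        self.generator_ = Generator(self.image_size, self.embed_dim,
                                    self.noise_dim, self.gen_base_channels,
                                    rng)
        self.discriminator_ = Discriminator(
            (fcfg.n_mels, fcfg.n_frames), n_classes, self.disc_channels,
            self.disc_fc, rng)
        self.opt_g_ = nn.Adam(self.generator_.params, lr=self.lr)
        self.opt_d_ = nn.Adam(self.discriminator_.params,
                              lr=self.disc_lr
                              if self.disc_lr is not None else self.lr)
        self.rng_ = rng
        self.n_classes_ = n_classes
        self.history_ = []

    def _fake_features(self, embeds: np.ndarray, noise: np.ndarray
                       ) -> tuple[nn.Tensor, nn.Tensor]:
        imgs = self.generator_.forward(embeds, noise)
        feats = logmel_differentiable(imgs, self.codec_config,
                                      self.frontend_config)
        return imgs, feats * self.feature_scale

    # -- training -------------------------------------------------------
    def train_step(self, real_feats: np.ndarray, embeds: np.ndarray,
                   labels: np.ndarray, update_generator: bool = True,
                   update_discriminator: bool = True) -> dict:
        """One adversarial update on a batch; returns the losses.

        ``real_feats`` are log-mel features of sonified real images
        (already scaled by ``feature_scale``); ``embeds`` are their audio
        embeddings; gradients reach the generator through the
        differentiable sonification graph.
        """
        w = self.class_loss_weight
        noise = self.rng_.standard_normal((len(embeds), self.noise_dim))

        # discriminator update (generated batch detached)
        _, fake_feats = self._fake_features(embeds, noise)
        fake_const = nn.Tensor(fake_feats.data)
        src_r, cls_r = self.discriminator_.forward(nn.Tensor(real_feats))
        src_f, cls_f = self.discriminator_.forward(fake_const)
        d_loss = (nn.bce_with_logits(src_r, np.ones(src_r.shape))
                  + nn.bce_with_logits(src_f, np.zeros(src_f.shape)))
        if w:
            d_loss = d_loss + w * (nn.softmax_cross_entropy(cls_r, labels)
                                   + nn.softmax_cross_entropy(cls_f, labels))
        if update_discriminator:
            self.opt_d_.zero_grad()
            d_loss.backward()
            self.opt_d_.step()

        # generator update (fresh pass, gradient flows through sonification)
        g_loss = self._generator_loss(embeds, labels, noise)
        if update_generator:
            self.opt_g_.zero_grad()
            self.opt_d_.zero_grad()  # discard, discriminator is not stepped
            g_loss.backward()
            self.opt_g_.step()
            self.opt_d_.zero_grad()

        out = {"d_loss": float(d_loss.data), "g_loss": float(g_loss.data)}
        if not all(np.isfinite(v) for v in out.values()):
            raise RuntimeError(f"non-finite GAN loss: {out}")
        return out

    def _generator_loss(self, embeds: np.ndarray, labels: np.ndarray,
                        noise: np.ndarray) -> nn.Tensor:
        """Generator objective for a fixed noise draw (used for training
        and for finite-difference gradient verification)."""
        _, fake_feats = self._fake_features(embeds, noise)
        src_f, cls_f = self.discriminator_.forward(fake_feats)
        g_loss = nn.bce_with_logits(src_f, np.ones(src_f.shape))
        if self.class_loss_weight:
            g_loss = g_loss + self.class_loss_weight * \
                nn.softmax_cross_entropy(cls_f, labels)
        return g_loss

    def fit(self, images: np.ndarray, labels: np.ndarray):
        """Train on real images; the encoder stays frozen throughout."""
        if self.encoder is None or self.codec_config is None \
                or self.frontend_config is None:
            raise ValueError("encoder, codec_config and frontend_config "
                             "are required")
        images = np.asarray(images, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        n_classes = int(labels.max()) + 1
        self._init_models(n_classes)
        raw_feats = sonify_and_featurize(images, self.codec_config,
                                         self.frontend_config)
        real_feats = raw_feats * self.feature_scale
        embeds = self.encoder.embed(raw_feats)
        self.embeddings_ = embeds
        n = len(images)
        for epoch in range(self.epochs):
            order = self.rng_.permutation(n)
            d_losses, g_losses = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                rec = self.train_step(real_feats[idx], embeds[idx],
                                      labels[idx])
                d_losses.append(rec["d_loss"])
                g_losses.append(rec["g_loss"])
            self.history_.append({"epoch": epoch,
                                  "d_loss": float(np.mean(d_losses)),
                                  "g_loss": float(np.mean(g_losses))})
        self.labels_ = labels
        return self

    # -- sampling -------------------------------------------------------
    def generate(self, embeddings: np.ndarray, labels: np.ndarray,
                 n_per_embedding: int = 1, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Sample images conditioned on audio embeddings.

        Returns ``(images, intended_labels)`` with ``len = n_embeddings *
        n_per_embedding``; deterministic given ``seed``.
        """
        embeddings = np.asarray(embeddings, dtype=np.float64)
        labels = np.asarray(labels)
        rng = np.random.default_rng(seed)
        emb_rep = np.repeat(embeddings, n_per_embedding, axis=0)
        lab_rep = np.repeat(labels, n_per_embedding)
        noise = rng.standard_normal((len(emb_rep), self.noise_dim))
        imgs = self.generator_.forward(emb_rep, noise)
        return imgs.data, lab_rep
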