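"""Evaluation stack for the cross-modal pipeline.

Contains the image-domain baseline classifier, the two generative-model
metrics (inception score computed with the baseline classifier in place of
Inception v3, and the Fréchet distance on the classifier's 128-d embedding
layer), and the accuracy-versus-compression sensitivity sweep that locates
the temporal limit of auditory sensitivity: the compression ratio beyond
which the accuracy of the baseline classifier on generated images stops
being stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .codec import CodecConfig
from .encoder import AudioEncoderClassifier
from .frontend import FrontendConfig, sonify_and_featurize
from .gan import CrossModalGAN
from .stimuli import DatasetSplit, generate_digit_glyphs, split_dataset

__all__ = [
    "BaselineImageClassifier",
    "train_baseline",
    "inception_score",
    "frechet_distance",
    "accuracy_on_generated",
    "SweepResult",
    "run_sensitivity_sweep",
    "detect_degradation_knee",
    "TOY_PROFILE",
    "FULL_PROFILE",
]


class _BaselineNet:
    """3 x (conv3x3 -> ReLU -> maxpool) + 1 conv -> dense embedding -> softmax."""

    def __init__(self, in_hw, channels, embedding_width, n_classes,
                 rng: np.random.Generator):
        chans = (1, *channels)
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], rng)
                      for i in range(4)]
        h, w = in_hw
        for _ in range(3):
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError(f"input {in_hw} too small for three pools")
        self.fc_embed = nn.Linear(channels[3] * h * w, embedding_width, rng)
        self.fc_out = nn.Linear(embedding_width, n_classes, rng)

    def forward(self, x: nn.Tensor):
        n = x.shape[0]
        h = x.reshape(n, 1, x.shape[1], x.shape[2])
        for conv in self.convs[:3]:
            h = nn.maxpool2d(conv(h).relu())
        h = self.convs[3](h).relu()          # extra conv, no pooling
        h = h.reshape(n, int(np.prod(h.shape[1:])))
        emb = self.fc_embed(h).relu()
        return self.fc_out(emb), emb

    @property
    def params(self):
        ps = []
        for layer in (*self.convs, self.fc_embed, self.fc_out):
            ps.extend(layer.params)
        return ps


class BaselineImageClassifier(BaseEstimator, ClassifierMixin):
    """Image-domain CNN used as the reference judge of generated images.

    Three alternating convolution/pooling pairs followed by one extra
    convolution, a 128-wide dense embedding layer (used by the Fréchet
    distance) and a softmax output (used by the inception score).
    """

    def __init__(self, channels=(16, 32, 64, 64), embedding_width=128,
                 n_classes=10, lr=1e-3, batch_size=64, epochs=10, seed=0):
        self.channels = channels
        self.embedding_width = embedding_width
        self.n_classes = n_classes
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, height, width)")
        rng = np.random.default_rng(self.seed)
        self.net_ = _BaselineNet(X.shape[1:], self.channels,
                                 self.embedding_width, self.n_classes, rng)
        opt = nn.Adam(self.net_.params, lr=self.lr)
        self.history_ = []
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits, _ = self.net_.forward(nn.Tensor(X[idx]))
                loss = nn.softmax_cross_entropy(logits, y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.history_.append({"epoch": epoch,
                                  "train_loss": float(np.mean(losses))})
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, X):
        logits, _ = self.net_.forward(nn.Tensor(np.asarray(X, float)))
        return nn.softmax(logits.data)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def embed(self, X) -> np.ndarray:
        """Embedding-layer activations, shape (N, embedding_width)."""
        _, emb = self.net_.forward(nn.Tensor(np.asarray(X, float)))
        return emb.data


def train_baseline(images, labels, split: DatasetSplit, seed: int = 0,
                   **params) -> tuple[BaselineImageClassifier, float]:
    """Train the baseline classifier on the image domain; returns the
    fitted model and its held-out test accuracy."""
    labels = np.asarray(labels)
    if len(split.train) == 0 or len(split.test) == 0:
        raise ValueError("degenerate split")
    counts = np.bincount(labels[split.train])
    if counts[counts > 0].min() < 2:
        raise ValueError("a training class has fewer than 2 samples")
    clf = BaselineImageClassifier(
        n_classes=int(labels.max()) + 1, seed=seed, **params)
    clf.fit(np.asarray(images)[split.train], labels[split.train])
    acc = clf.score(np.asarray(images)[split.test], labels[split.test])
    return clf, acc


# -- metrics ------------------------------------------------------------

def inception_score(class_probabilities: np.ndarray,
                    splits: int = 1) -> float:
    """exp of the mean KL divergence between conditional and marginal
    class distributions.

    Computed with the task's baseline classifier rather than Inception
    v3.  Always lies in [1, C].  ``splits > 1`` averages the score over
    contiguous chunks, the convention of the original metric; the default
    uses all samples at once.
    """
    p = np.asarray(class_probabilities, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("expected an N x C matrix")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must sum to 1")
    scores = []
    for chunk in np.array_split(p, splits):
        marginal = chunk.mean(axis=0, keepdims=True)
        kl = np.where(chunk > 0,
                      chunk * (np.log(chunk + 1e-300) - np.log(marginal + 1e-300)),
                      0.0).sum(axis=1)
        scores.append(np.exp(kl.mean()))
    return float(np.mean(scores))


def frechet_distance(real_embeddings: np.ndarray,
                     gen_embeddings: np.ndarray,
                     eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussians fitted to two embedding clouds.

    ``|mu_r - mu_g|^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2})`` with a
    symmetric-PSD-stabilized matrix square root; tiny negative results of
    numerical origin are clamped to 0.
    """
    X = np.asarray(real_embeddings, dtype=np.float64)
    Y = np.asarray(gen_embeddings, dtype=np.float64)
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    cov_x = np.atleast_2d(np.cov(X, rowvar=False))
    cov_y = np.atleast_2d(np.cov(Y, rowvar=False))
    diff = mu_x - mu_y
    d = cov_x.shape[0]
    rank_deficient = (np.linalg.matrix_rank(cov_x) < d
                      or np.linalg.matrix_rank(cov_y) < d)
    if rank_deficient:
        warnings.warn("rank-deficient covariance; regularizing with eps*I",
                      RuntimeWarning, stacklevel=2)
        cov_x = cov_x + eps * np.eye(d)
        cov_y = cov_y + eps * np.eye(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        covmean, _ = linalg.sqrtm(cov_x @ cov_y, disp=False)
    if not np.isfinite(covmean).all():
        covmean, _ = linalg.sqrtm(
            (cov_x + eps * np.eye(d)) @ (cov_y + eps * np.eye(d)),
            disp=False)
    covmean = np.real(covmean)
    fid = float(diff @ diff + np.trace(cov_x + cov_y - 2.0 * covmean))
    return max(fid, 0.0) if fid > -1e-6 else fid


def accuracy_on_generated(classifier, images: np.ndarray,
                          intended_labels: np.ndarray) -> float:
    """Fraction of generated images classified as their conditioning class."""
    preds = classifier.predict(np.asarray(images))
    return float(np.mean(preds == np.asarray(intended_labels)))


# -- sensitivity sweep --------------------------------------------------

# Full-scale experiment settings (not exercised by the test suite; the
# full run needs hours of CPU).
FULL_PROFILE = {
    "classes": tuple(range(10)),
    "n_per_class": 500,
    "image_size": 28,
    "codec": dict(sample_rate=22000, base_duration=1.0, f_min=500.0,
                  f_max=5000.0, click_ms=0.0),
    "frontend": dict(n_fft=512, hop=128, n_mels=64, n_frames=64),
    "encoder": dict(conv_channels=(16, 32, 64, 128), fc_hidden=(512, 128),
                    lr=1e-4, batch_size=64, epochs=10),
    "baseline": dict(channels=(16, 32, 64, 64), lr=1e-3, batch_size=64,
                     epochs=10),
    "gan": dict(image_size=28, lr=1e-3, batch_size=100, epochs=2000,
                gen_base_channels=64, disc_channels=(16, 32), disc_fc=256),
    "n_samples": 5000,
}

# Reduced-scale settings sized for a single CPU: two well-separated glyph
# classes at 8x8, an 8 kHz / 0.4 s codec and 16x16 log-mel features.
TOY_PROFILE = {
    "classes": (0, 1),
    "n_per_class": 40,
    "image_size": 8,
    "codec": dict(sample_rate=8000, base_duration=0.4, f_min=500.0,
                  f_max=3500.0, click_ms=0.0),
    "frontend": dict(n_fft=128, hop=32, n_mels=16, n_frames=16),
    "encoder": dict(conv_channels=(8, 16, 32, 64), fc_hidden=(128, 128),
                    lr=1e-3, batch_size=16, epochs=25),
    "baseline": dict(channels=(8, 16, 32, 32), lr=1e-3, batch_size=16,
                     epochs=30),
    "gan": dict(image_size=8, lr=2e-3, disc_lr=5e-4, batch_size=20,
                epochs=250, gen_base_channels=32, disc_channels=(8, 16),
                disc_fc=64, class_loss_weight=3.0),
    "n_samples": 64,
}


@dataclass
class SweepResult:
    """Per-compression-ratio accuracy (mean, sd over repeats), IS and FID."""

    table: pd.DataFrame
    n_repeats: int
    n_samples: int
    failures: list = field(default_factory=list)

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _child_seed(seed: int, *idx: int) -> int:
    ss = np.random.SeedSequence([seed, *idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _prepare_corpus(profile: dict, seed: int):
    classes = profile["classes"]
    full = generate_digit_glyphs(profile["n_per_class"],
                                 seed=_child_seed(seed, 0),
                                 size=profile["image_size"])
    keep = np.isin(full.labels, classes)
    images = full.images[keep]
    remap = {c: i for i, c in enumerate(classes)}
    labels = np.array([remap[l] for l in full.labels[keep]])
    split = split_dataset(len(images), seed=_child_seed(seed, 1))
    return images, labels, split


def run_sensitivity_sweep(ratios=None, n_repeats: int = 2,
                          profile: dict | str = "toy", seed: int = 0
                          ) -> SweepResult:
    """Accuracy / IS / FID of the full pipeline across compression ratios.

    For each ratio an audio encoder is trained on that ratio's features,
    then ``n_repeats`` GANs are trained (randomness derived from
    ``(seed, ratio, repeat)``); each repeat generates ``n_samples`` images
    from held-out-audio embeddings and scores them with the image-domain
    baseline classifier.  A repeat that raises is logged in ``failures``
    and excluded from the aggregates.
    """
    if isinstance(profile, str):
        profile = TOY_PROFILE if profile == "toy" else FULL_PROFILE
    ratios = np.asarray([0.0, 0.45, 0.9] if ratios is None else ratios,
                        dtype=float)
    if ratios.min() < 0 or ratios.max() > 0.9:
        raise ValueError("ratios must lie in [0, 0.9]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    ratios = np.sort(ratios)
    n_classes = len(profile["classes"])

    images, labels, split = _prepare_corpus(profile, seed)
    baseline, base_acc = train_baseline(
        images, labels, split, seed=_child_seed(seed, 2),
        **profile["baseline"])
    real_emb = baseline.embed(images[split.test])

    rows, failures = [], []
    for ri, ratio in enumerate(ratios):
        codec = CodecConfig(compression_ratio=float(ratio),
                            **profile["codec"])
        fcfg = FrontendConfig(**profile["frontend"])
        feats = sonify_and_featurize(images, codec, fcfg)
        enc = AudioEncoderClassifier(n_classes=n_classes,
                                     seed=_child_seed(seed, 3, ri),
                                     **profile["encoder"])
        enc.fit(feats[split.train], labels[split.train])
        test_emb_audio = enc.embed(feats[split.test])

        accs, iss, fids = [], [], []
        for rep in range(n_repeats):
            try:
                gan = CrossModalGAN(
                    encoder=enc, codec_config=codec, frontend_config=fcfg,
                    seed=_child_seed(seed, 4, ri, rep), **profile["gan"])
                gan.fit(images[split.train], labels[split.train])
                n_emb = len(test_emb_audio)
                reps = int(np.ceil(profile["n_samples"] / n_emb))
                gen_imgs, gen_labels = gan.generate(
                    test_emb_audio, labels[split.test], n_per_embedding=reps,
                    seed=_child_seed(seed, 5, ri, rep))
                gen_imgs = gen_imgs[: profile["n_samples"]]
                gen_labels = gen_labels[: profile["n_samples"]]
                accs.append(accuracy_on_generated(baseline, gen_imgs,
                                                  gen_labels))
                iss.append(inception_score(baseline.predict_proba(gen_imgs)))
                fids.append(frechet_distance(real_emb,
                                             baseline.embed(gen_imgs)))
            except Exception as exc:  # keep partial results
                failures.append({"ratio": float(ratio), "repeat": rep,
                                 "error": repr(exc)})
        if accs:
            rows.append({
                "ratio": float(ratio),
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_sd": float(np.std(accs, ddof=0)),
                "inception_score": float(np.mean(iss)),
                "fid": float(np.mean(fids)),
                "encoder_test_accuracy": enc.score(feats[split.test],
                                                   labels[split.test]),
                "baseline_test_accuracy": base_acc,
                "n_ok_repeats": len(accs),
            })
    return SweepResult(table=pd.DataFrame(rows), n_repeats=n_repeats,
                       n_samples=profile["n_samples"], failures=failures)


def plot_sweep(sweep: SweepResult, path: str | Path) -> Path:
    """Three-panel PNG: accuracy (mean ± sd), inception score and FID
    against the compression ratio."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep.table
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].errorbar(df["ratio"], df["accuracy_mean"],
                     yerr=df["accuracy_sd"], marker="o", capsize=3)
    axes[0].set_ylabel("classifier accuracy on generated")
    axes[1].plot(df["ratio"], df["inception_score"], marker="o")
    axes[1].set_ylabel("inception score")
    axes[2].plot(df["ratio"], df["fid"], marker="o")
    axes[2].set_ylabel("Fréchet distance")
    for ax in axes:
        ax.set_xlabel("compression ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def detect_degradation_knee(sweep: SweepResult, sd_factor: float = 3.0
                            ) -> float | None:
    """Smallest ratio whose accuracy sd exceeds ``sd_factor`` times the
    median sd of all smaller ratios (the point where accuracy stops being
    stable); ``None`` if no such ratio exists."""
    df = sweep.table
    if len(df) < 3:
        raise ValueError("need at least 3 ratios")
    if sweep.n_repeats < 2:
        raise ValueError("sd undefined with fewer than 2 repeats")
    sds = df["accuracy_sd"].to_numpy()
    ratios = df["ratio"].to_numpy()
    for i in range(1, len(ratios)):
        ref = float(np.median(sds[:i]))
        if sds[i] > sd_factor * ref:
            return float(ratios[i])
    return None
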