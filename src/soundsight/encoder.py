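"""Audio-embedding CNN: classifier on log-mel features.

The network mirrors the audio-encoder design used throughout the package:
four convolutional blocks (3x3 conv, ReLU, 2x2 max-pool) followed by three
fully connected layers, trained with Adam.  After training, the 128-wide
penultimate activation is the *audio embedding* that conditions the image
generator, so the classifier doubles as a representation learner.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .stimuli import DatasetSplit

__all__ = ["AudioEncoderClassifier", "train_encoder"]


class _ConvStack:
    """4 x (conv3x3 -> ReLU -> maxpool2x2) + 3 fully connected layers."""

    def __init__(self, in_hw: tuple[int, int], conv_channels, fc_hidden,
                 n_classes: int, rng: np.random.Generator):
        h, w = in_hw
        if h % 16 or w % 16:
            raise ValueError(f"input {h}x{w} must be divisible by 16 "
                             "(four 2x2 pooling stages)")
        chans = (1, *conv_channels)
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], rng)
                      for i in range(4)]
        flat = conv_channels[-1] * (h // 16) * (w // 16)
        self.fc1 = nn.Linear(flat, fc_hidden[0], rng)
        self.fc2 = nn.Linear(fc_hidden[0], fc_hidden[1], rng)
        self.fc_out = nn.Linear(fc_hidden[1], n_classes, rng)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Returns (logits, embedding); embedding is the penultimate ReLU."""
        n = x.shape[0]
        h = x.reshape(n, 1, x.shape[1], x.shape[2])
        for conv in self.convs:
            h = nn.maxpool2d(conv(h).relu())
        h = h.reshape(n, int(np.prod(h.shape[1:])))
        h = self.fc1(h).relu()
        emb = self.fc2(h).relu()
        return self.fc_out(emb), emb

    @property
    def params(self):
        ps = []
        for layer in (*self.convs, self.fc1, self.fc2, self.fc_out):
            ps.extend(layer.params)
        return ps


class AudioEncoderClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier on log-mel features with a 128-d embedding layer.

    Parameters
    ----------
    conv_channels : tuple of 4 ints
        Output channels of the four convolutional blocks.
    fc_hidden : tuple of 2 ints
        Widths of the first two fully connected layers; the second is the
        embedding and must be 128 to honour the conditioning contract.
    n_classes : int
        Number of output classes.
    lr, batch_size, epochs
        Adam step size (1e-4), mini-batch size (64) and epoch count (10).
    seed : int
        Controls initialization and batch shuffling; training is
        reproducible bit-stably under a fixed seed.
    """

    def __init__(self, conv_channels=(16, 32, 64, 128),
                 fc_hidden=(512, 128), n_classes=10, lr=1e-4,
                 batch_size=64, epochs=10, seed=0):
        self.conv_channels = conv_channels
        self.fc_hidden = fc_hidden
        self.n_classes = n_classes
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _validate(self):
        if len(self.conv_channels) != 4:
            raise ValueError("exactly four convolutional blocks required")
        if len(self.fc_hidden) != 2:
            raise ValueError("exactly three fully connected layers required")

    def fit(self, X, y, validation_data=None):
        """Train on features X of shape (N, n_mels, n_frames)."""
        self._validate()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, n_mels, n_frames)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.seed)
        # standardize features once from the training set
        self.feat_mean_ = float(X.mean())
        self.feat_std_ = float(X.std()) or 1.0
        self.input_shape_ = X.shape[1:]
        X = (X - self.feat_mean_) / self.feat_std_
        self.net_ = _ConvStack(X.shape[1:], self.conv_channels,
                               self.fc_hidden, self.n_classes, rng)
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
            rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if validation_data is not None:
                Xv, yv = validation_data
                pv = self.predict_proba(Xv)
                rec["val_loss"] = float(-np.mean(np.log(
                    pv[np.arange(len(yv)), yv] + 1e-12)))
                rec["val_accuracy"] = float(
                    np.mean(pv.argmax(axis=1) == yv))
            self.history_.append(rec)
        self.classes_ = np.arange(self.n_classes)
        return self

    def _forward_np(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.float64)
        mean = getattr(self, "feat_mean_", 0.0)
        std = getattr(self, "feat_std_", 1.0)
        logits, emb = self.net_.forward(nn.Tensor((X - mean) / std))
        return logits.data, emb.data

    def predict_proba(self, X) -> np.ndarray:
        logits, _ = self._forward_np(X)
        return nn.softmax(logits)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def embed(self, X) -> np.ndarray:
        """128-d audio embeddings (penultimate-layer activations)."""
        if not hasattr(self, "net_"):
            warnings.warn("embedding from an untrained encoder",
                          RuntimeWarning, stacklevel=2)
            self._validate()
            rng = np.random.default_rng(self.seed)
            X = np.asarray(X, float)
            self.net_ = _ConvStack(X.shape[1:], self.conv_channels,
                                   self.fc_hidden, self.n_classes, rng)
        _, emb = self._forward_np(X)
        return emb


def train_encoder(features: np.ndarray, labels: np.ndarray,
                  split: DatasetSplit, config: dict | None = None
                  ) -> tuple[AudioEncoderClassifier, dict]:
    """Train the audio encoder on a train/validation/test split.

    Returns the fitted estimator and a report with per-epoch losses and
    held-out test accuracy.
    """
    labels = np.asarray(labels)
    clf = AudioEncoderClassifier(**(config or {}))
    train_classes = set(np.unique(labels[split.train]).tolist())
    all_classes = set(np.unique(labels).tolist())
    if train_classes != all_classes:
        missing = sorted(all_classes - train_classes)
        raise ValueError(f"classes {missing} absent from the training split")
    clf.fit(features[split.train], labels[split.train],
            validation_data=(features[split.validation],
                             labels[split.validation]))
    report = {
        "history": clf.history_,
        "test_accuracy": clf.score(features[split.test],
                                   labels[split.test]),
    }
    return clf, report
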