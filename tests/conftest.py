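"""Shared fixtures: a small two-class glyph corpus and trained toy models.

Everything is generated in-process at test time; session scope keeps the
expensive fits (encoder, baseline classifier, GAN) to one each.
"""

import numpy as np
import pytest

import soundsight as ss
from soundsight.evaluation import TOY_PROFILE, BaselineImageClassifier
from soundsight.encoder import AudioEncoderClassifier
from soundsight.gan import CrossModalGAN


@pytest.fixture(scope="session")
def toy_profile():
    return TOY_PROFILE


@pytest.fixture(scope="session")
def toy_corpus(toy_profile):
    """Two-class 8x8 glyph corpus with an 80/20(/20) split."""
    full = ss.generate_digit_glyphs(toy_profile["n_per_class"], seed=3,
                                    size=toy_profile["image_size"])
    keep = np.isin(full.labels, toy_profile["classes"])
    images, labels = full.images[keep], full.labels[keep]
    split = ss.split_dataset(len(images), seed=1)
    return images, labels, split


@pytest.fixture(scope="session")
def toy_codec(toy_profile):
    return ss.CodecConfig(compression_ratio=0.0, **toy_profile["codec"])


@pytest.fixture(scope="session")
def toy_frontend(toy_profile):
    return ss.FrontendConfig(**toy_profile["frontend"])


@pytest.fixture(scope="session")
def toy_features(toy_corpus, toy_codec, toy_frontend):
    images, _, _ = toy_corpus
    return ss.sonify_and_featurize(images, toy_codec, toy_frontend)


@pytest.fixture(scope="session")
def toy_encoder(toy_profile, toy_corpus, toy_features):
    _, labels, split = toy_corpus
    enc = AudioEncoderClassifier(n_classes=2, seed=0,
                                 **toy_profile["encoder"])
    enc.fit(toy_features[split.train], labels[split.train])
    return enc


@pytest.fixture(scope="session")
def toy_baseline(toy_profile, toy_corpus):
    images, labels, split = toy_corpus
    clf = BaselineImageClassifier(n_classes=2, seed=0,
                                  **toy_profile["baseline"])
    clf.fit(images[split.train], labels[split.train])
    return clf


@pytest.fixture(scope="session")
def toy_gan(toy_profile, toy_corpus, toy_codec, toy_frontend, toy_encoder):
    """A briefly trained cross-modal GAN for contract-level checks."""
    images, labels, split = toy_corpus
    params = dict(toy_profile["gan"])
    params["epochs"] = 100
    gan = CrossModalGAN(encoder=toy_encoder, codec_config=toy_codec,
                        frontend_config=toy_frontend, seed=1, **params)
    gan.fit(images[split.train], labels[split.train])
    return gan


@pytest.fixture(scope="session")
def shape_set():
    return ss.generate_shape_set(seed=7, size=64)
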