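"""Checkpointing: network parameters as NPZ with a JSON config sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .codec import CodecConfig
from .encoder import AudioEncoderClassifier
from .frontend import FrontendConfig
from .gan import CrossModalGAN

__all__ = ["save_encoder", "load_encoder", "save_gan", "load_gan"]


def _params_of(net) -> list[np.ndarray]:
    return [p.data for p in net.params]


def _restore_params(net, arrays: list[np.ndarray]) -> None:
    params = net.params
    if len(params) != len(arrays):
        raise ValueError("checkpoint does not match the architecture")
    for p, a in zip(params, arrays):
        if p.data.shape != a.shape:
            raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
        p.data[...] = a


def save_encoder(enc: AudioEncoderClassifier, out_dir: str | Path) -> Path:
    """Write weights (NPZ) plus config/history sidecar (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": a for i, a in enumerate(_params_of(enc.net_))}
    np.savez(out / "weights.npz", **arrays)
    sidecar = {
        "kind": "audio_encoder",
        "params": enc.get_params(),
        "feat_mean": enc.feat_mean_,
        "feat_std": enc.feat_std_,
        "input_shape": list(enc.input_shape_),
        "history": enc.history_,
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_encoder(model_dir: str | Path) -> AudioEncoderClassifier:
    out = Path(model_dir)
    sidecar = json.loads((out / "model.json").read_text())
    if sidecar.get("kind") != "audio_encoder":
        raise ValueError("not an audio-encoder checkpoint")
    enc = AudioEncoderClassifier(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in sidecar["params"].items()})
    enc._validate()
    from .encoder import _ConvStack
    rng = np.random.default_rng(enc.seed)
    enc.net_ = _ConvStack(tuple(sidecar["input_shape"]), enc.conv_channels,
                          enc.fc_hidden, enc.n_classes, rng)
    enc.feat_mean_ = sidecar["feat_mean"]
    enc.feat_std_ = sidecar["feat_std"]
    enc.history_ = sidecar["history"]
    enc.classes_ = np.arange(enc.n_classes)
    with np.load(out / "weights.npz") as data:
        _restore_params(enc.net_, [data[f"p{i}"] for i in range(len(data))])
    return enc


def save_gan(gan: CrossModalGAN, out_dir: str | Path) -> Path:
    """Write generator + discriminator weights and the training history."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = {f"g{i}": a for i, a in enumerate(_params_of(gan.generator_))}
    d = {f"d{i}": a for i, a in enumerate(_params_of(gan.discriminator_))}
    np.savez(out / "weights.npz", **g, **d)
    params = {k: v for k, v in gan.get_params(deep=False).items()
              if k not in ("encoder", "codec_config", "frontend_config")}
    sidecar = {
        "kind": "xmodal_gan",
        "params": params,
        "codec_config": gan.codec_config.__dict__,
        "frontend_config": gan.frontend_config.__dict__,
        "n_classes": gan.n_classes_,
        "history": gan.history_,
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_gan(model_dir: str | Path, encoder=None) -> CrossModalGAN:
    out = Path(model_dir)
    sidecar = json.loads((out / "model.json").read_text())
    if sidecar.get("kind") != "xmodal_gan":
        raise ValueError("not a cross-modal GAN checkpoint")
    params = {k: tuple(v) if isinstance(v, list) else v
              for k, v in sidecar["params"].items()}
    gan = CrossModalGAN(encoder=encoder,
                        codec_config=CodecConfig(**sidecar["codec_config"]),
                        frontend_config=FrontendConfig(
                            **sidecar["frontend_config"]),
                        **params)
    gan._init_models(sidecar["n_classes"])
    gan.history_ = sidecar["history"]
    with np.load(out / "weights.npz") as data:
        g = [data[k] for k in sorted(
            (k for k in data.files if k.startswith("g")),
            key=lambda s: int(s[1:]))]
        d = [data[k] for k in sorted(
            (k for k in data.files if k.startswith("d")),
            key=lambda s: int(s[1:]))]
    _restore_params(gan.generator_, g)
    _restore_params(gan.discriminator_, d)
    return gan
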