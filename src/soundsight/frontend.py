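"""Log-mel spectrogram frontend for soundscapes.

Two routes produce numerically matching features:

* :func:`logmel` — the reference route on a rendered soundscape
  (numpy STFT -> mel filterbank -> log -> fixed-length time axis);
* :func:`logmel_differentiable` — the same computation expressed through
  autodiff primitives (sinusoid-basis matrix product for the sonification,
  windowed DFT and mel projections as matrix products, log), so gradients
  flow from feature values back to image pixels.  This is what lets the
  image generator learn through the sonification during GAN training.

The time axis is brought to a fixed ``n_frames`` by linear resampling of
the frame axis by default (so compressed soundscapes stay information
dense); zero-padding to ``n_frames`` is available via ``pad_mode="pad"``.
The fixed output shape is what allows one audio network to serve every
compression ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .codec import (CodecConfig, Soundscape, column_slices,
                    effective_duration, make_click, row_frequency)

__all__ = [
    "FrontendConfig",
    "LogMelFeature",
    "mel_filterbank",
    "logmel",
    "logmel_differentiable",
    "sonify_and_featurize",
]


@dataclass(frozen=True)
class FrontendConfig:
    """STFT / mel parameters (64 x 64 output by default).

    The defaults give a square feature suited to four 2x2 pooling stages;
    the toy profile used in fast pipeline runs shrinks them to 16 x 16.
    """

    n_fft: int = 512
    hop: int = 128
    n_mels: int = 64
    n_frames: int = 64
    log_floor: float = 1e-6
    pad_mode: str = "resample"  # "resample" or "pad"

    def __post_init__(self):
        if self.n_fft <= self.hop:
            raise ValueError("n_fft must exceed hop")
        if self.n_mels < 8 or self.n_frames < 8:
            raise ValueError("n_mels and n_frames must be >= 8")
        if self.pad_mode not in ("resample", "pad"):
            raise ValueError("pad_mode must be 'resample' or 'pad'")


@dataclass
class LogMelFeature:
    values: np.ndarray          # (n_mels, n_frames)
    config: FrontendConfig


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular mel filters (n_mels x (n_fft//2 + 1)), 0 Hz to Nyquist."""
    n_bins = n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2.0),
                          n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, centre, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(centre - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - centre, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_band_of(freq_hz: float, sample_rate: int, n_fft: int,
                n_mels: int) -> int:
    """Index of the mel band whose centre is nearest ``freq_hz``."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2.0),
                          n_mels + 2)
    centres = _mel_to_hz(mel_pts[1:-1])
    return int(np.argmin(np.abs(centres - freq_hz)))


def _window(n_fft: int) -> np.ndarray:
    # periodic Hann
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n_fft) / n_fft)


def _n_stft_frames(n_samples: int, cfg: FrontendConfig) -> int:
    if n_samples < cfg.n_fft:
        raise ValueError(f"signal of {n_samples} samples is shorter than "
                         f"n_fft={cfg.n_fft}")
    return 1 + (n_samples - cfg.n_fft) // cfg.hop


def _resample_matrix(n_t: int, n_frames: int) -> np.ndarray:
    """Linear-interpolation matrix R (n_t x n_frames): out = in @ R."""
    R = np.zeros((n_t, n_frames))
    if n_t == 1:
        R[0, :] = 1.0
        return R
    pos = np.linspace(0.0, n_t - 1, n_frames)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_t - 1)
    frac = pos - lo
    R[lo, np.arange(n_frames)] += 1.0 - frac
    R[hi, np.arange(n_frames)] += frac
    return R


def _fix_frames(logm: np.ndarray, cfg: FrontendConfig) -> np.ndarray:
    """Bring (n_t, n_mels) to (n_frames, n_mels) by resampling or padding."""
    n_t = logm.shape[0]
    if cfg.pad_mode == "resample":
        return _resample_matrix(n_t, cfg.n_frames).T @ logm
    if n_t >= cfg.n_frames:
        return logm[: cfg.n_frames]
    pad = np.full((cfg.n_frames - n_t, logm.shape[1]),
                  np.log(cfg.log_floor))
    return np.vstack([logm, pad])


def logmel(ss: Soundscape, cfg: FrontendConfig) -> LogMelFeature:
    """Reference log-mel feature of a soundscape, shape (n_mels, n_frames)."""
    x = np.asarray(ss.samples, dtype=np.float64)
    n_t = _n_stft_frames(len(x), cfg)
    frames = sliding_window_view(x, cfg.n_fft)[:: cfg.hop][:n_t]
    spec = np.abs(np.fft.rfft(frames * _window(cfg.n_fft), axis=1))
    melspec = spec @ mel_filterbank(ss.sample_rate, cfg.n_fft, cfg.n_mels).T
    logm = np.log(melspec + cfg.log_floor)
    return LogMelFeature(values=_fix_frames(logm, cfg).T, config=cfg)


# -- differentiable route ----------------------------------------------

_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def _sonify_basis(n_rows: int, n_cols: int, cfg: CodecConfig) -> np.ndarray:
    """Constant matrix B (n_rows*n_cols x T): waveform = pixels_flat @ B.

    Row (i, j) of B is ``sin(2 pi f_i t) / n_rows`` masked to column j's
    time slice, mirroring the reference encoder exactly.
    """
    key = (n_rows, n_cols, cfg.sample_rate, cfg.base_duration,
           cfg.compression_ratio, cfg.f_min, cfg.f_max)
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    dur = effective_duration(cfg.base_duration, cfg.compression_ratio)
    n_samples = int(round(dur * cfg.sample_rate))
    if n_samples < n_cols:
        raise ValueError("too few samples per column")
    t = np.arange(n_samples) / cfg.sample_rate
    freqs = np.array([row_frequency(n_rows - 1 - i, n_rows,
                                    cfg.f_min, cfg.f_max)
                      for i in range(n_rows)])
    sines = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]) / n_rows
    bounds = column_slices(n_samples, n_cols)
    B = np.zeros((n_rows * n_cols, n_samples))
    for j in range(n_cols):
        seg = slice(bounds[j], bounds[j + 1])
        B[j:: n_cols, seg] = sines[:, seg]
    _BASIS_CACHE[key] = B
    return B


def logmel_differentiable(images, codec_cfg: CodecConfig,
                          frontend_cfg: FrontendConfig) -> nn.Tensor:
    """Sonify + log-mel as one differentiable graph.

    Parameters
    ----------
    images
        ``(N, n_rows, n_cols)`` batch, ndarray or :class:`nn.Tensor` with
        values in [0, 1].
    Returns
    -------
    nn.Tensor of shape ``(N, n_mels, n_frames)`` matching the reference
    :func:`logmel` of :func:`soundsight.codec.encode` output to within
    1e-4 relative.
    """
    x = nn.as_tensor(images)
    n, n_rows, n_cols = x.shape
    B = _sonify_basis(n_rows, n_cols, codec_cfg)
    wav = x.reshape(n, n_rows * n_cols) @ nn.Tensor(B)       # (N, T)
    # peak normalization (skipped gracefully for silent images)
    peak = wav.abs().max(axis=1, keepdims=True)
    wav = wav * (nn.as_tensor(codec_cfg.peak_level) / (peak + 1e-12))
    click = make_click(codec_cfg)
    if click.size:
        wav = nn.concat(
            [nn.Tensor(np.broadcast_to(click, (n, click.size)).copy()), wav],
            axis=1)
    n_t = _n_stft_frames(wav.shape[1], frontend_cfg)
    idx = (np.arange(n_t)[:, None] * frontend_cfg.hop
           + np.arange(frontend_cfg.n_fft)[None, :])
    frames = wav[:, idx]                                      # (N, n_t, n_fft)
    win = _window(frontend_cfg.n_fft)
    n_bins = frontend_cfg.n_fft // 2 + 1
    k = np.arange(n_bins)
    ang = 2.0 * np.pi * np.outer(np.arange(frontend_cfg.n_fft), k) \
        / frontend_cfg.n_fft
    Wc = win[:, None] * np.cos(ang)
    Ws = win[:, None] * -np.sin(ang)
    re = frames @ nn.Tensor(Wc)
    im = frames @ nn.Tensor(Ws)
    mag = (re * re + im * im + 1e-30).sqrt()
    M = mel_filterbank(codec_cfg.sample_rate, frontend_cfg.n_fft,
                       frontend_cfg.n_mels)
    logm = (mag @ nn.Tensor(M.T) + frontend_cfg.log_floor).log()
    # (N, n_t, n_mels) -> (N, n_mels, n_frames)
    logm = logm.transpose(0, 2, 1)
    if frontend_cfg.pad_mode == "resample":
        return logm @ nn.Tensor(_resample_matrix(n_t, frontend_cfg.n_frames))
    if n_t >= frontend_cfg.n_frames:
        return logm[:, :, : frontend_cfg.n_frames]
    pad = np.full((n, frontend_cfg.n_mels, frontend_cfg.n_frames - n_t),
                  np.log(frontend_cfg.log_floor))
    return nn.concat([logm, nn.Tensor(pad)], axis=2)


def sonify_and_featurize(images: np.ndarray, codec_cfg: CodecConfig,
                         frontend_cfg: FrontendConfig,
                         labels=None) -> np.ndarray:
    """Reference-path features for a batch of images, (N, n_mels, n_frames)."""
    from .codec import encode
    feats = []
    for i, img in enumerate(images):
        label = None if labels is None else int(labels[i])
        feats.append(logmel(encode(img, codec_cfg, label=label),
                            frontend_cfg).values)
    return np.stack(feats)
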