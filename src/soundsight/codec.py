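"""Deterministic vOICe-style image-to-soundscape codec.

An image is scanned column by column from left to right over the soundscape
duration.  Each pixel row carries a sinusoid whose frequency follows a
log-linear scale (500-5000 Hz by default, higher image rows -> higher
pitch), and pixel brightness sets that sinusoid's amplitude during the
pixel's column slice.  A *compression ratio* r shortens the scan: the
effective duration is ``base_duration * (1 - r)`` with row frequencies
unchanged, so compression only accelerates the scan.

The module also provides a spectral verification decoder (projection of
each column slice onto the row frequencies) and 16-bit PCM WAV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "CodecConfig",
    "Soundscape",
    "effective_duration",
    "row_frequency",
    "make_click",
    "encode",
    "decode_peaks",
    "write_wav",
    "read_wav",
]


@dataclass(frozen=True)
class CodecConfig:
    """Parameters of the image-to-audio encoding.

    sample_rate
        Audio sampling frequency in Hz (22 kHz default).
    base_duration
        Uncompressed soundscape length in seconds (one image frame per
        second by default).
    compression_ratio
        Fraction in [0, 1) by which the scan is shortened; 0.5 turns a 1 s
        soundscape into 0.5 s.
    f_min, f_max
        Endpoints of the log-linear row-frequency scale in Hz.
    click_ms
        Length of the broadband onset click in milliseconds (0 disables;
        the behavioral stimuli use 50 ms).
    peak_level
        Peak amplitude after normalization, in (0, 1].
    """

    sample_rate: int = 22000
    base_duration: float = 1.0
    compression_ratio: float = 0.0
    f_min: float = 500.0
    f_max: float = 5000.0
    click_ms: float = 0.0
    peak_level: float = 0.9

    def __post_init__(self):
        if not (0 < self.f_min < self.f_max < self.sample_rate / 2):
            raise ValueError("need 0 < f_min < f_max < sample_rate/2")
        if not (0.0 <= self.compression_ratio < 1.0):
            raise ValueError("compression_ratio must be in [0, 1)")
        if self.base_duration <= 0:
            raise ValueError("base_duration must be positive")
        if not (0.0 < self.peak_level <= 1.0):
            raise ValueError("peak_level must be in (0, 1]")
        if self.click_ms < 0:
            raise ValueError("click_ms must be >= 0")

    def with_ratio(self, r: float) -> "CodecConfig":
        return replace(self, compression_ratio=float(r))


@dataclass
class Soundscape:
    """A mono audio rendering of one image."""

    samples: np.ndarray
    sample_rate: int
    effective_duration: float
    source_label: int | None = None
    config: CodecConfig | None = None
    click_samples: int = 0

    @property
    def scan_samples(self) -> np.ndarray:
        """Samples excluding the onset click."""
        return self.samples[self.click_samples:]

    @property
    def scan_duration(self) -> float:
        """Duration in seconds of the image scan, excluding the click."""
        return len(self.scan_samples) / self.sample_rate


def effective_duration(base_duration: float, compression_ratio: float
                       ) -> float:
    """Scan duration after compression: ``base * (1 - r)``."""
    if not (0.0 <= compression_ratio < 1.0):
        raise ValueError("compression_ratio must be in [0, 1) "
                         "(1 would give a zero-length soundscape)")
    if base_duration <= 0:
        raise ValueError("base_duration must be positive")
    return base_duration * (1.0 - compression_ratio)


def row_frequency(row_index_from_bottom: int, n_rows: int,
                  f_min: float = 500.0, f_max: float = 5000.0) -> float:
    """Frequency of a pixel row on the log-linear scale.

    ``row_index_from_bottom = 0`` is the lowest image row and maps to
    ``f_min``; the top row maps to ``f_max``.  For a single-row image the
    frequency is ``f_min``.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if not (0 <= row_index_from_bottom < n_rows):
        raise ValueError("row index out of range")
    if n_rows == 1:
        return float(f_min)
    expo = row_index_from_bottom / (n_rows - 1)
    return float(f_min * (f_max / f_min) ** expo)


def _row_frequencies_top_down(n_rows: int, cfg: CodecConfig) -> np.ndarray:
    """Frequencies for matrix rows (row 0 = top = highest pitch)."""
    return np.array([row_frequency(n_rows - 1 - i, n_rows,
                                   cfg.f_min, cfg.f_max)
                     for i in range(n_rows)])


def column_slices(n_samples: int, n_cols: int) -> np.ndarray:
    """Boundaries of the equal time slices: array of length n_cols + 1."""
    return np.round(np.linspace(0, n_samples, n_cols + 1)).astype(int)


def make_click(cfg: CodecConfig) -> np.ndarray:
    """Deterministic broadband onset click of ``click_ms`` milliseconds."""
    n = int(round(cfg.click_ms * 1e-3 * cfg.sample_rate))
    if n == 0:
        return np.zeros(0)
    rng = np.random.default_rng(1234)  # fixed: the click is a constant
    burst = rng.uniform(-1.0, 1.0, n) * np.exp(-np.linspace(0, 5, n))
    return burst / np.max(np.abs(burst)) * cfg.peak_level


def encode(image: np.ndarray, cfg: CodecConfig,
           label: int | None = None) -> Soundscape:
    """Sonify a grayscale image (rows x cols, values in [0, 1]).

    The scan duration ``D = base_duration * (1 - compression_ratio)`` is
    divided into ``n_cols`` equal slices; during slice j the signal is the
    sum over rows i of ``a_ij * sin(2 pi f_i t)`` with ``a_ij`` the pixel
    brightness scaled by ``1/n_rows`` and phases continuous across slices.
    The result is peak-normalized to ``peak_level`` (an all-black image
    stays silent) and the onset click, if any, is prepended.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    n_rows, n_cols = image.shape
    dur = effective_duration(cfg.base_duration, cfg.compression_ratio)
    n_samples = int(round(dur * cfg.sample_rate))
    if n_samples < n_cols:
        raise ValueError(
            f"{n_samples} samples cannot resolve {n_cols} columns; "
            "reduce compression or the column count")
    t = np.arange(n_samples) / cfg.sample_rate
    freqs = _row_frequencies_top_down(n_rows, cfg)
    bounds = column_slices(n_samples, n_cols)
    # per-sample amplitude envelope for every row (piecewise constant)
    col_of_sample = np.searchsorted(bounds[1:-1], np.arange(n_samples),
                                    side="right")
    amps = image[:, col_of_sample] / n_rows          # (rows, samples)
    sines = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :])
    samples = (amps * sines).sum(axis=0)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples * (cfg.peak_level / peak)
    click = make_click(cfg)
    if click.size:
        samples = np.concatenate([click, samples])
    return Soundscape(samples=samples, sample_rate=cfg.sample_rate,
                      effective_duration=dur, source_label=label,
                      config=cfg, click_samples=click.size)


def decode_peaks(ss: Soundscape, n_rows: int, n_cols: int) -> np.ndarray:
    """Verification decoder: spectral magnitude per (row frequency, slice).

    Projects each column slice of the scan onto complex exponentials at the
    row frequencies and normalizes the magnitudes to [0, 1].  For sparse
    images the per-column argmax row matches the encoded pixel row; this is
    a diagnostic, not the perceptual decoder (which is the GAN).
    """
    cfg = ss.config
    if cfg is None:
        raise ValueError("soundscape lacks its codec config")
    x = ss.scan_samples
    if len(x) < n_cols:
        raise ValueError("soundscape too short for the requested columns")
    freqs = _row_frequencies_top_down(n_rows, cfg)
    bounds = column_slices(len(x), n_cols)
    out = np.zeros((n_rows, n_cols))
    t = np.arange(len(x)) / cfg.sample_rate
    for j in range(n_cols):
        seg = slice(bounds[j], bounds[j + 1])
        basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, seg])
        out[:, j] = np.abs(basis @ x[seg]) / max(bounds[j + 1] - bounds[j], 1)
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


def write_wav(ss: Soundscape, path: str | Path) -> Path:
    """Write a 16-bit PCM mono WAV file."""
    if not str(path):
        raise ValueError("empty path")
    if np.max(np.abs(ss.samples)) > 1.0:
        raise ValueError("samples exceed [-1, 1]; refusing to clip")
    pcm = np.round(ss.samples * 32767.0).astype(np.int16)
    wavfile.write(str(path), ss.sample_rate, pcm)
    return Path(path)


def read_wav(path: str | Path, config: CodecConfig | None = None
             ) -> Soundscape:
    """Read a 16-bit PCM mono WAV file back into a soundscape."""
    rate, pcm = wavfile.read(str(path))
    if pcm.ndim != 1:
        raise ValueError("expected mono audio")
    samples = pcm.astype(np.float64) / 32767.0
    return Soundscape(samples=samples, sample_rate=rate,
                      effective_duration=len(samples) / rate, config=config)
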