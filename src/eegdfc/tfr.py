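"""Analytic-wavelet time-frequency representations and image rendering.

A complex (analytic) Morlet continuous wavelet transform computed in the
frequency domain over a log-spaced frequency grid, plus a renderer that
turns magnitude spectrograms into 224 x 224 x 3 RGB images suitable for
CNN-style feature extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .exceptions import ConfigurationError, DataError

IMAGE_SIZE = 224


@dataclass
class Spectrogram:
    """Magnitude TFR: rows are frequencies (Hz), columns are times (s)."""

    magnitude: np.ndarray  # (n_scales, n_times), >= 0
    frequencies: np.ndarray  # Hz per row, strictly monotone
    times: np.ndarray  # seconds per column
    provenance: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitude, dtype=float)
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise DataError("magnitude must be finite and non-negative")
        f = np.asarray(self.frequencies, dtype=float)
        if not (np.all(np.diff(f) > 0) or np.all(np.diff(f) < 0)):
            raise DataError("frequency axis must be strictly monotone")
        self.magnitude = m
        self.frequencies = f
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class SpectroImage:
    """An RGB uint8 image of fixed 224 x 224 x 3 shape."""

    pixels: np.ndarray
    provenance: tuple = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise DataError(f"pixels must be {IMAGE_SIZE}x{IMAGE_SIZE}x3, got {p.shape}")
        self.pixels = p.astype(np.uint8)


def analytic_wavelet_tfr(
    signal: np.ndarray,
    sampling_rate: float,
    n_scales: int = 64,
    f_min: float = 1.0,
    f_max: float = 45.0,
    omega0: float = 6.0,
    provenance: tuple = (),
) -> Spectrogram:
    """Magnitude of an analytic Morlet CWT on a log-spaced frequency grid.

    The wavelet is zero for negative frequencies, so the transform is the
    analytic signal filtered by Gaussian bandpasses centred on each grid
    frequency; a pure tone localizes at the nearest grid row.
    """
    if not (0 < f_min < f_max):
        raise ConfigurationError("require 0 < f_min < f_max")
    if f_max > sampling_rate / 2.0:
        raise ConfigurationError("f_max must be <= sampling_rate / 2")
    if n_scales < 4:
        raise ConfigurationError("n_scales must be >= 4")
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("signal must be finite")
    n = x.size
    freqs = np.geomspace(f_min, f_max, n_scales)
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / sampling_rate)
    xf = np.fft.fft(x)
    # scale for centre frequency f: s = omega0 / (2 pi f)
    scales = omega0 / (2.0 * np.pi * freqs)
    arg = scales[:, None] * omega[None, :] - omega0
    psi_hat = np.exp(-0.5 * arg * arg)
    psi_hat[:, omega <= 0] = 0.0
    coeffs = np.fft.ifft(xf[None, :] * psi_hat, axis=1)
    return Spectrogram(
        magnitude=np.abs(coeffs),
        frequencies=freqs,
        times=np.arange(n) / sampling_rate,
        provenance=provenance,
    )


def render_image(
    spec: Spectrogram, colormap: str = "viridis", size: int = IMAGE_SIZE
) -> SpectroImage:
    """Min-max normalize, colormap to RGB, bilinearly resize to ``size``.

    Deterministic and invariant to positive rescaling of the magnitude;
    a constant spectrogram renders as a single flat color.
    """
    m = spec.magnitude
    if m.size == 0:
        raise DataError("cannot render an empty spectrogram")
    lo, hi = float(m.min()), float(m.max())
    norm = np.zeros_like(m) if hi <= lo else (m - lo) / (hi - lo)
    # row 0 is the lowest frequency; flip so it sits at the image bottom
    rgba = colormaps[colormap](norm[::-1, :])
    rgb8 = (rgba[:, :, :3] * 255.0).round().astype(np.uint8)
    img = Image.fromarray(rgb8, mode="RGB").resize((size, size), Image.BILINEAR)
    pixels = np.asarray(img)
    if size != IMAGE_SIZE:
        out = SpectroImage.__new__(SpectroImage)
        out.pixels = pixels
        out.provenance = spec.provenance
        return out
    return SpectroImage(pixels=pixels, provenance=spec.provenance)


def denoised_signal(imfset, n_keep: int | None = None) -> np.ndarray:
    """Sum of the first ``n_keep`` IMFs (all, if None) — the per-channel
    signal the TFR is computed on by default."""
    imfs = imfset.imfs[:n_keep] if n_keep is not None else imfset.imfs
    if not imfs:
        return imfset.residue.copy()
    return np.sum(imfs, axis=0)
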