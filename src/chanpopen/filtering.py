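"""Gaussian low-pass filtering with the −3 dB-cutoff convention.

Single-channel work parameterizes Gaussian filters by their −3 dB frequency
fc rather than the kernel width.  For a Gaussian impulse response the two
are related by sigma_t = 0.1325/fc, and the 10–90% step rise time is
0.3396/fc — both follow from the Gaussian transfer function
H(f) = exp(-(2*pi*f*sigma_t)^2 / 2) evaluated at |H| = 1/sqrt(2).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

__all__ = ["sigma_from_fc", "gaussian_kernel", "gaussian_lowpass", "cascade_fc"]

#: sigma_t * fc for a Gaussian filter, = sqrt(ln 2) / (2 pi)
SIGMA_FC = np.sqrt(np.log(2.0)) / (2.0 * np.pi)  # 0.13249...

#: 10-90% rise time * fc for the Gaussian step response
RISE_FC = 0.3396


def sigma_from_fc(fc: float) -> float:
    """Kernel standard deviation in seconds for a −3 dB cutoff ``fc`` (Hz)."""
    if fc <= 0:
        raise ValueError("fc must be positive")
    return SIGMA_FC / fc


def gaussian_kernel(fc: float, fs: float, truncate: float = 4.0) -> np.ndarray:
    """Unit-sum symmetric Gaussian kernel sampled at ``fs``.

    Truncated at ±``truncate`` sigma and renormalized, so DC gain is exactly
    one regardless of truncation.
    """
    sigma_samples = sigma_from_fc(fc) * fs
    half = max(1, int(np.ceil(truncate * sigma_samples)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_samples) ** 2)
    return k / k.sum()


def gaussian_lowpass(samples: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Zero-phase Gaussian filtering of a sampled signal.

    Edges are handled by reflecting the signal, preserving DC level at the
    boundaries.
    """
    if fc >= fs / 2:
        raise ValueError(f"fc={fc} must be below the Nyquist frequency {fs / 2}")
    samples = np.asarray(samples)
    dtype = samples.dtype if samples.dtype == np.float32 else np.float64
    kernel = gaussian_kernel(fc, fs).astype(dtype)
    return convolve1d(samples.astype(dtype, copy=False), kernel, mode="reflect")


def cascade_fc(fc_in: float | None, fc_new: float) -> float:
    """Effective cutoff of two Gaussian filters in series.

    Gaussian transfer functions multiply, so cutoffs combine as
    1/fc_eff^2 = 1/fc_in^2 + 1/fc_new^2.
    """
    if fc_in is None:
        return fc_new
    return 1.0 / np.sqrt(1.0 / fc_in**2 + 1.0 / fc_new**2)
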