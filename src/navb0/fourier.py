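"""Centered Fourier transforms and the shift-theorem phase ramp.

Convention used throughout the package: the DC sample of every k-space
axis sits at index ``n // 2`` (fftshifted layout), and image-domain
coordinates are ``u = (arange(n) - n // 2) / n`` so that shifting
k-space by ``delta`` samples along an axis is exactly multiplication of
the image by ``exp(-2j * pi * delta * u)`` along that axis.
"""

from __future__ import annotations

import numpy as np


def fftc(x: np.ndarray, axes) -> np.ndarray:
    """Centered, orthonormal FFT along ``axes``."""
    if np.isscalar(axes):
        axes = (axes,)
    axes = tuple(axes)
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes) -> np.ndarray:
    """Centered, orthonormal inverse FFT along ``axes``."""
    if np.isscalar(axes):
        axes = (axes,)
    axes = tuple(axes)
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def fft2c(x: np.ndarray, axes=(-2, -1)) -> np.ndarray:
    return fftc(x, axes)


def ifft2c(x: np.ndarray, axes=(-2, -1)) -> np.ndarray:
    return ifftc(x, axes)


def centered_coords(n: int) -> np.ndarray:
    """Normalized image coordinates ``(arange(n) - n//2) / n`` in [-0.5, 0.5)."""
    return (np.arange(n) - n // 2) / n


def shift_ramp(n: int, delta: float) -> np.ndarray:
    """Image-domain phase ramp whose FT effect is a +delta-sample k-space shift."""
    return np.exp(-2j * np.pi * delta * centered_coords(n))


def fourier_shift(kdata: np.ndarray, delta: float, axis: int) -> np.ndarray:
    """Shift k-space data by ``delta`` samples along ``axis`` via the shift theorem.

    Exact (analytic) sub-sample shift: transform to the conjugate domain
    along ``axis``, apply the phase ramp, transform back.
    """
    n = kdata.shape[axis]
    hybrid = ifftc(kdata, (axis,))
    shape = [1] * kdata.ndim
    shape[axis] = n
    hybrid = hybrid * shift_ramp(n, delta).reshape(shape)
    return fftc(hybrid, (axis,))
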