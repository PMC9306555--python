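"""In-memory containers for multichannel k-space, navigators and image series.

Indexing convention (used everywhere in the package):

* k-space data is ``(channel j, readout kx, phase-encode ky[, slice kz])``
  with DC at index ``n // 2`` on every k axis (see :mod:`navb0.fourier`);
* ``mask`` marks acquired phase-encode lines;
* ``line_times`` holds seconds-from-excitation for each ky line, ``nan``
  on lines that were not acquired;
* times are seconds, field offsets Hz, shim gradients uT/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "MultiChannelKSpace",
    "NavigatorSet",
    "ImageSeries",
    "RawDataset",
]


@dataclass
class MultiChannelKSpace:
    """Complex k-space samples for one excitation (or one calibration scan).

    Parameters
    ----------
    data
        Complex array ``(J, Nx, Ny)`` or ``(J, Nx, Ny, Nz)``.
    mask
        Boolean acquired-line indicator with shape ``data.shape[2:]``.
        All-true for fully sampled calibration.
    line_times
        Seconds from excitation per ky line (shape ``(Ny,)``), ``nan``
        where the line was not acquired.  ``None`` for calibration data
        where per-line timing is irrelevant.
    echo_spacing
        Seconds between consecutive EPI line acquisitions.
    fov
        Field of view in meters per axis ``(x, y[, z])``.
    caipi_shift
        Integer CAIPI k-space shift index per simultaneously excited
        slice (all zeros / empty when no SMS collapsing applies).
    """

    data: np.ndarray
    mask: np.ndarray
    echo_spacing: float
    fov: tuple
    line_times: np.ndarray | None = None
    caipi_shift: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.caipi_shift = np.asarray(self.caipi_shift, dtype=int)
        self.fov = tuple(float(v) for v in np.atleast_1d(self.fov))
        if self.data.ndim not in (3, 4):
            raise ValidationError(
                f"data must be (J, Nx, Ny[, Nz]); got shape {self.data.shape}"
            )
        if self.mask.shape != self.data.shape[2:]:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match phase-encode "
                f"dimensions {self.data.shape[2:]}"
            )
        if self.line_times is not None:
            self.line_times = np.asarray(self.line_times, dtype=float)
            if self.line_times.shape[0] != self.data.shape[2]:
                raise ValidationError(
                    f"line_times length {self.line_times.shape[0]} != Ny "
                    f"{self.data.shape[2]}"
                )
        if not self.echo_spacing > 0:
            raise ValidationError("echo_spacing must be > 0")
        if any(v <= 0 for v in self.fov):
            raise ValidationError("fov components must be > 0")

    # -- convenience -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def acquired_ky(self) -> np.ndarray:
        """Acquired ky indices in ascending order (2D mask only)."""
        m = self.mask if self.mask.ndim == 1 else self.mask[:, 0]
        return np.flatnonzero(m)

    def copy(self) -> "MultiChannelKSpace":
        return replace(
            self,
            data=self.data.copy(),
            mask=self.mask.copy(),
            line_times=None if self.line_times is None else self.line_times.copy(),
            caipi_shift=self.caipi_shift.copy(),
        )


@dataclass
class NavigatorSet:
    """The three central-line (ky = 0) acquisitions of one excitation.

    The EPI reference navigator samples the central k-space line three
    times at distinct, equally spaced echo times before the imaging
    train; line ``l`` (1-based) is ``lines[l - 1]``.
    """

    lines: np.ndarray  # (3, J, M)
    line_echo_times: np.ndarray  # (3,) seconds
    frame_index: int = 0
    slice_group: int = 0

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=complex)
        self.line_echo_times = np.asarray(self.line_echo_times, dtype=float)
        if self.lines.ndim != 3 or self.lines.shape[0] != 3:
            raise ValidationError(
                f"navigator needs exactly 3 lines (3, J, M); got {self.lines.shape}"
            )
        if self.line_echo_times.shape != (3,):
            raise ValidationError("line_echo_times must have 3 entries")
        dt = np.diff(self.line_echo_times)
        if not np.all(dt > 0):
            raise ValidationError("line_echo_times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError("navigator echo times must be equally spaced")
        if self.frame_index < 0:
            raise ValidationError("frame_index must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.lines.shape[1]

    @property
    def n_readout(self) -> int:
        return self.lines.shape[2]

    @property
    def echo_spacing(self) -> float:
        return float(self.line_echo_times[1] - self.line_echo_times[0])

    def copy(self) -> "NavigatorSet":
        return replace(self, lines=self.lines.copy(),
                       line_echo_times=self.line_echo_times.copy())


@dataclass
class ImageSeries:
    """A reconstructed image time series with optional tissue/background masks."""

    frames: np.ndarray  # (T, X, Y[, Z])
    voxel_size: tuple = (1e-3, 1e-3, 1e-3)
    brain_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.voxel_size = tuple(float(v) for v in np.atleast_1d(self.voxel_size))
        spatial = self.frames.shape[1:]
        for name in ("brain_mask", "background_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != spatial:
                    raise ValidationError(
                        f"{name} shape {m.shape} != frame shape {spatial}"
                    )
                setattr(self, name, m)
        if self.brain_mask is not None and self.background_mask is not None:
            if np.any(self.brain_mask & self.background_mask):
                raise ValidationError("brain and background masks must be disjoint")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RawDataset:
    """One acquisition: per-slice calibration plus per-frame data + navigators."""

    calibration: list  # list[MultiChannelKSpace], one per slice
    frames: list  # list[MultiChannelKSpace], collapsed/undersampled per frame
    navigators: list  # list[NavigatorSet], one per frame
    slice_positions: Sequence[int] = ()
    n_slices_total: int = 0
    ground_truth: dict | None = None  # simulation-only sidecar payload

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.navigators):
            raise ValidationError("one NavigatorSet required per frame")
        if not self.n_slices_total:
            self.n_slices_total = len(self.calibration)

    @property
    def n_frames(self) -> int:
        return len(self.frames)
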