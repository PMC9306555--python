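"""GRAPPA shift operators: training, fractional powers, multi-axis composition.

A GRAPPA operator is a ``J x J`` complex matrix ``G`` calibrated so that,
at every k-space location, the vector of channel values one sample
further along a given axis is approximated by ``G`` times the vector at
the current location:

    S(k + dk) = G S(k).

Because the operator acts pointwise across channels, integer shifts are
matrix powers and arbitrary sub-sample shifts are fractional matrix
powers ``G**(delta / dk)``.  Shifts along several axes compose by
successive application of per-axis operators.  The slice-axis operator
for simultaneous-multislice data is trained on a proxy 3D calibration
volume built by stacking individually reconstructed slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import MultiChannelKSpace
from .errors import ValidationError
from .fourier import fftc, ifft2c

__all__ = [
    "GrappaOperator",
    "Proxy3DCalibration",
    "train_operator",
    "fractional_power",
    "apply_shift",
    "compose_shifts",
    "build_proxy_3d_calibration",
]

AXES = ("readout", "phase", "slice")
#: array axis (in (J, kx, ky, kz) layout) trained by each named operator axis
_AXIS_TO_DIM = {"readout": 1, "phase": 2, "slice": 3}

# eigenbasis condition number beyond which we fall back to a Schur-based
# matrix power instead of the eigendecomposition route
EIG_COND_THRESHOLD = 1e8


@dataclass
class GrappaOperator:
    """A unit k-space shift operator along one axis.

    ``weights`` maps the channel vector at k to the channel vector at
    k + one sample along ``axis``.  Fractional powers are computed from
    a cached eigendecomposition (principal branch of the complex power).
    """

    weights: np.ndarray  # (J, J)
    axis: str
    unit_shift: float = 1.0  # k-space samples per application
    training_residual: float = float("nan")
    max_shift: float = 1.0  # |delta| beyond which extrapolation is flagged
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=complex)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValidationError("operator weights must be a square JxJ matrix")
        if self.axis not in AXES:
            raise ValidationError(f"axis must be one of {AXES}")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def eigendecomposition(self):
        """Cached ``(eigenvalues, V, V^-1)`` of the weights, or None if ill-conditioned."""
        if self._eig is None:
            vals, vecs = np.linalg.eig(self.weights)
            cond = np.linalg.cond(vecs)
            if not np.isfinite(cond) or cond > EIG_COND_THRESHOLD:
                self._eig = (None, None, None)
            else:
                self._eig = (vals, vecs, np.linalg.inv(vecs))
        return self._eig

    def power(self, exponent: float) -> np.ndarray:
        return fractional_power(self, exponent)

    def powers(self, exponents: np.ndarray) -> np.ndarray:
        """Vectorized fractional powers, shape ``(len(exponents), J, J)``."""
        exponents = np.asarray(exponents, dtype=float)
        vals, vecs, vinv = self.eigendecomposition()
        if vals is None:
            return np.stack([fractional_power(self, e) for e in exponents])
        lam = np.power(vals[None, :], exponents[:, None])  # principal branch
        return np.einsum("ij,nj,jk->nik", vecs, lam, vinv)


def train_operator(
    calib,
    axis: str,
    reg: float = 1e-4,
    min_eig_modulus: float = 0.0,
    direction: int = +1,
    noise_var: float | None = None,
) -> GrappaOperator:
    """Calibrate a unit-shift operator along ``axis`` from fully sampled data.

    All (source, target) channel-vector pairs one sample apart along the
    training axis are stacked and the operator is solved in the
    Tikhonov-regularized least-squares sense

        G = T S^H (S S^H + (reg * sigma_max(S))^2 I)^{-1}.

    Parameters
    ----------
    calib
        :class:`~navb0.containers.MultiChannelKSpace` or a plain complex
        array ``(J, Nx, Ny[, Nz])``, fully sampled along ``axis``.
    axis
        ``"readout"``, ``"phase"`` or ``"slice"``.
    reg
        Tikhonov parameter relative to the largest singular value of the
        source matrix.
    min_eig_modulus
        Optional floor on eigenvalue moduli of the trained weights.  An
        ideal shift operator is unitary on the signal subspace; weakly
        determined modes come out with small moduli and blow up under
        negative fractional powers.  A floor of ~0.5 is recommended for
        the slice axis, whose proxy-3D training data spans only the few
        encoded planes.
    direction
        +1 (default) trains the operator shifting toward increasing k
        index; -1 trains the opposite direction.  Applying positive
        fractional powers of the direction-matched operator is more
        noise-robust than negative powers of the other one, because
        forward powers damp (rather than amplify) weakly encoded modes.
    noise_var
        Per-complex-sample noise variance of the data the operator will
        be *applied* to.  When given, the ridge is set to the Wiener
        level ``n_columns * noise_var`` instead of the relative ``reg``
        term, so the solve stops exploiting source structure below the
        noise floor.  The unregularized solution is exquisitely accurate
        on noiseless data but strongly non-normal, and amplifies noise
        by large factors under fractional powers; the noise-matched
        operator trades a controlled amount of shift fidelity for
        bounded noise gain.
    """
    data = calib.data if isinstance(calib, MultiChannelKSpace) else np.asarray(calib)
    dim = _AXIS_TO_DIM[axis]
    if data.ndim <= dim:
        raise ValidationError(
            f"calibration has no {axis} axis (shape {data.shape})"
        )
    J = data.shape[0]
    if J < 2:
        raise ValidationError(
            "operator requires coil sensitivity variation: need J >= 2 channels"
        )
    if data.shape[dim] < 2:
        raise ValidationError(f"need >= 2 samples along {axis} to train")

    if direction not in (+1, -1):
        raise ValidationError("direction must be +1 or -1")
    src = np.moveaxis(data, dim, -1)[..., :-1].reshape(J, -1)
    tgt = np.moveaxis(data, dim, -1)[..., 1:].reshape(J, -1)
    if direction < 0:
        src, tgt = tgt, src

    gram = src @ src.conj().T
    smax_sq = float(np.max(np.linalg.eigvalsh(gram).real))
    if smax_sq <= 0:
        raise ValidationError("calibration data has no signal")
    # rank check against the regularized solve
    eigs = np.linalg.eigvalsh(gram).real
    if np.min(eigs) < 1e-12 * smax_sq:
        warnings.warn(
            "rank-deficient source matrix; solving via regularized pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    if noise_var is not None and noise_var > 0:
        lam = src.shape[1] * float(noise_var)
    else:
        lam = (reg**2) * smax_sq
    weights = (tgt @ src.conj().T) @ np.linalg.inv(
        gram + lam * np.eye(J)
    )
    if min_eig_modulus > 0:
        vals, vecs = np.linalg.eig(weights)
        mod = np.abs(vals)
        small = mod < min_eig_modulus
        if small.any():
            vals = np.where(small, vals / np.maximum(mod, 1e-300) * min_eig_modulus,
                            vals)
            weights = (vecs * vals) @ np.linalg.inv(vecs)
    residual = float(
        np.linalg.norm(tgt - weights @ src) / np.linalg.norm(tgt)
    )
    return GrappaOperator(weights=weights, axis=axis, training_residual=residual)


def fractional_power(op: GrappaOperator, exponent: float) -> np.ndarray:
    """``op.weights ** exponent`` with the principal branch of the complex power.

    Exponent 0 returns the identity, exponent 1 the weights themselves.
    Falls back to a Schur-based matrix power (with a warning) when the
    eigenbasis is too ill-conditioned to invert reliably.
    """
    J = op.n_channels
    if exponent == 0:
        return np.eye(J, dtype=complex)
    if exponent == 1:
        return op.weights.copy()
    vals, vecs, vinv = op.eigendecomposition()
    if vals is None:
        warnings.warn(
            "ill-conditioned eigenbasis; using Schur-based matrix power",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.asarray(
            scipy.linalg.fractional_matrix_power(op.weights, exponent),
            dtype=complex,
        )
    return (vecs * np.power(vals, exponent)) @ vinv


def apply_shift(
    op: GrappaOperator,
    data: np.ndarray,
    delta: float,
    warn_extrapolation: bool = True,
) -> np.ndarray:
    """Shift multichannel k-space ``data`` by ``delta`` samples along ``op.axis``.

    ``data`` has channels on the first axis; every k-space column is
    multiplied by ``op.weights ** (delta / op.unit_shift)``.  ``delta``
    may be negative (inverse shift).
    """
    data = np.asarray(data, dtype=complex)
    if data.shape[0] != op.n_channels:
        raise ValidationError(
            f"data has {data.shape[0]} channels, operator expects {op.n_channels}"
        )
    if warn_extrapolation and abs(delta) > op.max_shift:
        warnings.warn(
            f"|delta|={abs(delta):.3g} exceeds the calibrated unit shift; "
            "operator extrapolation degrades accuracy",
            RuntimeWarning,
            stacklevel=2,
        )
    if delta == 0:
        return data.copy()
    w = fractional_power(op, delta / op.unit_shift)
    flat = data.reshape(op.n_channels, -1)
    return (w @ flat).reshape(data.shape)


def compose_shifts(
    operators: dict,
    data: np.ndarray,
    delta: tuple,
    warn_extrapolation: bool = True,
) -> np.ndarray:
    """Apply per-axis shifts ``delta = (dkx, dky, dkz)`` in fixed x -> y -> z order.

    ``operators`` maps axis names (``readout``/``phase``/``slice``) to
    trained operators; zero components are skipped, and a nonzero
    component without its operator is an error.  Operator composition is
    not exactly commutative numerically, so the order is part of the
    contract.
    """
    delta = np.asarray(delta, dtype=float)
    out = np.asarray(data, dtype=complex)
    for axis, d in zip(AXES, delta):
        if d == 0:
            continue
        if axis not in operators or operators[axis] is None:
            raise ValidationError(
                f"nonzero {axis} shift requested but no {axis} operator provided"
            )
        out = apply_shift(operators[axis], out, d, warn_extrapolation)
    return out


@dataclass
class Proxy3DCalibration:
    """Proxy 3D k-space volume for training the slice-axis operator.

    Individually reconstructed calibration slices are stacked along the
    slice axis at their encoded positions, every other plane left zero,
    and the stack transformed back to k-space along the slice axis.
    """

    volume: np.ndarray  # (J, Nx, Ny, Nz) complex k-space
    source_slice_indices: tuple

    @property
    def n_slices(self) -> int:
        return self.volume.shape[-1]


def build_proxy_3d_calibration(
    slice_calibs,
    slice_positions,
    n_slices_total: int,
) -> Proxy3DCalibration:
    """Stack per-slice calibration k-space into a 3D proxy volume.

    Parameters
    ----------
    slice_calibs
        Per-slice fully sampled calibration, each
        :class:`MultiChannelKSpace` or array ``(J, Nx, Ny)``.
    slice_positions
        Encoded plane index of each slice within the ``n_slices_total``
        stack (distinct).
    """
    positions = [int(p) for p in slice_positions]
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate slice positions in proxy 3D calibration")
    arrays = [
        c.data if isinstance(c, MultiChannelKSpace) else np.asarray(c, dtype=complex)
        for c in slice_calibs
    ]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError("all slices must share in-plane dimensions")
    J, nx, ny = arrays[0].shape
    if any(not 0 <= p < n_slices_total for p in positions):
        raise ValidationError("slice position outside the stack")
    # in-plane data is already k-space; only the slice axis needs encoding
    stack = np.zeros((J, nx, ny, n_slices_total), dtype=complex)
    for pos, arr in zip(positions, arrays):
        stack[..., pos] = arr
    volume = fftc(stack, (3,))
    return Proxy3DCalibration(volume=volume, source_slice_indices=tuple(positions))


def proxy_slice_images(proxy: Proxy3DCalibration) -> np.ndarray:
    """Image-space volume of the proxy, ``(J, x, y, z)`` (diagnostic round-trip)."""
    from .fourier import ifftc

    planes = ifftc(proxy.volume, (3,))
    return ifft2c(planes, axes=(1, 2))
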