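"""Baseline accelerated-EPI reconstruction chain.

Order of operations (fixed): Nyquist ghost correction -> dynamic
zeroth-order B0 correction -> off-resonance estimation + correction
(optional, from :mod:`navb0.estimation` / :mod:`navb0.correction`) ->
split-slice GRAPPA SMS unaliasing -> in-plane GRAPPA -> root-sum-of-
squares coil combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import MultiChannelKSpace, NavigatorSet, RawDataset
from .correction import correct_frame
from .errors import ValidationError
from .estimation import OffResonanceModel, OffResonanceResults, refine_dy
from .fourier import fftc, ifft2c, ifftc
from .grappa import build_proxy_3d_calibration, train_operator

__all__ = [
    "SliceKernels",
    "nyquist_ghost_correct",
    "zeroth_order_b0_correct",
    "train_split_slice_grappa",
    "unalias_sms",
    "grappa_inplane",
    "root_sum_of_squares",
    "ReconPipeline",
    "caipi_phases",
]


# ----------------------------------------------------------------------
# navigator-based EPI phase corrections


def _nav_hybrid(nav: NavigatorSet) -> np.ndarray:
    """Navigator lines transformed to hybrid (x, ky=0) space, (3, J, M)."""
    return ifftc(nav.lines, (2,))


def _even_echo(times: np.ndarray, echo_spacing: float) -> np.ndarray:
    return (np.rint(times / echo_spacing).astype(int) % 2) == 0


def nyquist_ghost_correct(
    frame: MultiChannelKSpace, nav: NavigatorSet
) -> tuple:
    """Remove the odd/even EPI line phase discrepancy estimated from the navigator.

    Lines 1 and 3 share readout polarity; line 2 has the opposite one.
    The 0th + 1st order phase difference between line 2 and the mean of
    lines 1 and 3 (which cancels the linear inter-echo phase evolution)
    is fit in hybrid x-space and removed from every imaging (and
    navigator) line of the discrepant parity.

    Returns the corrected ``(frame, nav)`` pair.
    """
    p = _nav_hybrid(nav)
    ref = 0.5 * (p[0] + p[2])
    xprod = np.sum(p[1] * np.conj(ref), axis=0)  # (M,)
    w = np.abs(xprod)
    if w.sum() <= 0:
        warnings.warn("degenerate navigator; ghost correction skipped",
                      RuntimeWarning, stacklevel=2)
        return frame.copy(), nav.copy()
    m = nav.n_readout
    x = np.arange(m) - m // 2
    phase = np.unwrap(np.angle(xprod))
    a = np.stack([x, np.ones_like(x, dtype=float)], axis=1) * np.sqrt(w)[:, None]
    phi1, phi0 = np.linalg.lstsq(a, phase * np.sqrt(w), rcond=None)[0]
    corr = np.exp(-1j * (phi0 + phi1 * x))

    out = frame.copy()
    if frame.line_times is not None:
        acq = frame.acquired_ky
        even = _even_echo(frame.line_times[acq], frame.echo_spacing)
        idx = acq[even]
        if idx.size:
            hyb = ifftc(out.data[:, :, idx], (1,)) * corr[None, :, None]
            out.data[:, :, idx] = fftc(hyb, (1,))

    nav_out = nav.copy()
    even_nav = _even_echo(nav.line_echo_times, nav.echo_spacing)
    hyb = ifftc(nav_out.lines[even_nav], (2,)) * corr[None, None, :]
    nav_out.lines[even_nav] = fftc(hyb, (2,))
    return out, nav_out


def _interline_phase(nav: NavigatorSet) -> float:
    """Mean phase advance per echo spacing between consecutive navigator lines."""
    z = 0.0 + 0.0j
    for l in range(2):
        z += np.sum(nav.lines[l + 1] * np.conj(nav.lines[l]))
    return float(np.angle(z))


def zeroth_order_b0_correct(
    frame: MultiChannelKSpace,
    nav: NavigatorSet,
    nav_ref: NavigatorSet,
) -> tuple:
    """Remove the global (zeroth-order) frequency offset relative to the reference.

    The offset is read off the difference in inter-line phase evolution
    between the frame's navigator and the reference navigator; each line
    at time ``t`` is then demodulated by ``exp(+2j pi df t)``.

    Returns ``(frame, nav, df_hz)``.
    """
    esp = nav.echo_spacing
    dphi = _interline_phase(nav) - _interline_phase(nav_ref)
    df = -dphi / (2 * np.pi * esp)

    out = frame.copy()
    if frame.line_times is not None and df != 0:
        acq = frame.acquired_ky
        t = frame.line_times[acq]
        out.data[:, :, acq] = out.data[:, :, acq] * np.exp(
            2j * np.pi * df * t
        )[None, None, :]
    nav_out = nav.copy()
    nav_out.lines = nav_out.lines * np.exp(
        2j * np.pi * df * nav.line_echo_times
    )[:, None, None]
    return out, nav_out, float(df)


# ----------------------------------------------------------------------
# split-slice GRAPPA


def caipi_phases(caipi_shift, n_lines: int, mb: int) -> np.ndarray:
    """CAIPI phase pattern per slice per acquired-line counter, ``(S, n_lines)``.

    Slice ``s`` receives ``exp(2j pi shift_s m / mb)`` on acquired line
    counter ``m`` — for MB=2 with shifts (0, 1) this is the alternating
    +/- pattern that displaces slice 2 by FOV/2.
    """
    shifts = np.atleast_1d(np.asarray(caipi_shift, dtype=int))
    m = np.arange(n_lines)
    return np.exp(2j * np.pi * shifts[:, None] * m[None, :] / max(mb, 1))


def _extract_patches(block: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """All valid (kh, kw) multichannel patches of ``block`` (J, H, W).

    Returns ``(J * kh * kw, P)`` with P = (H-kh+1)(W-kw+1); patch p is
    centered at ``(kh//2 + i, kw//2 + j)`` in row-major (i, j) order.
    """
    j, h, w = block.shape
    win = np.lib.stride_tricks.sliding_window_view(block, (kh, kw), axis=(1, 2))
    # win: (J, H-kh+1, W-kw+1, kh, kw)
    p = win.shape[1] * win.shape[2]
    return win.transpose(0, 3, 4, 1, 2).reshape(j * kh * kw, p)


def _apply_kernel(weights: np.ndarray, block: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Convolve kernel ``weights`` (J, J*kh*kw) over zero-padded ``block`` (J, H, W)."""
    j, h, w = block.shape
    padded = np.pad(block, ((0, 0), (kh // 2, kh - 1 - kh // 2),
                            (kw // 2, kw - 1 - kw // 2)))
    src = _extract_patches(padded, kh, kw)
    return (weights @ src).reshape(weights.shape[0], h, w)


@dataclass
class SliceKernels:
    """Split-slice GRAPPA kernels for one simultaneously excited slice group."""

    weights: list  # per slice: (J, J*kh*kw)
    kernel_size: tuple
    caipi_shift: np.ndarray
    mb: int
    regularization: float
    leakage: np.ndarray | None = None  # (S, S) energy-ratio matrix on calibration

    @property
    def n_slices(self) -> int:
        return len(self.weights)


def train_split_slice_grappa(
    slice_calibs,
    caipi_shift,
    acquired_ky: np.ndarray,
    kernel_size: tuple = (5, 5),
    reg: float = 1e-3,
) -> SliceKernels:
    """Train kernels separating CAIPI-collapsed slices on the acquired-line grid.

    The split objective trains each slice's kernel against every
    individual slice's (CAIPI-phased) calibration: reproduce the target
    slice when fed its own contribution, produce zero when fed any other
    slice's contribution.  This minimizes reconstruction error and
    inter-slice leakage jointly.
    """
    arrays = [
        c.data if isinstance(c, MultiChannelKSpace) else np.asarray(c, dtype=complex)
        for c in slice_calibs
    ]
    s_count = len(arrays)
    j = arrays[0].shape[0]
    kh, kw = kernel_size
    acquired_ky = np.asarray(acquired_ky, dtype=int)
    phases = caipi_phases(caipi_shift, len(acquired_ky), s_count)

    # per-slice calibration on the acquired-line subgrid
    sub = [a[:, :, acquired_ky] for a in arrays]
    phased = [sub[s] * phases[s][None, None, :] for s in range(s_count)]

    src_blocks = [_extract_patches(p, kh, kw) for p in phased]
    src = np.concatenate(src_blocks, axis=1)
    n_unknown = j * kh * kw
    if src.shape[1] < n_unknown:
        warnings.warn(
            "under-determined split-slice kernel fit; increasing regularization",
            RuntimeWarning, stacklevel=2,
        )
        reg = reg * 10

    gram = src @ src.conj().T
    smax_sq = float(np.max(np.linalg.eigvalsh(gram).real))
    ridge = (reg**2) * smax_sq * np.eye(n_unknown)
    gram_inv = np.linalg.inv(gram + ridge)

    def _centers(block):
        h, w = block.shape[1:]
        return block[:, kh // 2: h - (kh - 1 - kh // 2),
                     kw // 2: w - (kw - 1 - kw // 2)].reshape(j, -1)

    # targets carry the CAIPI phase too: the phase pattern is
    # multiplicative along ky, so phased-in -> phased-out is realizable
    # by a convolution kernel (phased-in -> unphased-out is not); the
    # phase is removed after synthesis in unalias_sms
    weights = []
    for s in range(s_count):
        tgt_blocks = [
            _centers(phased[s]) if sp == s else np.zeros_like(_centers(phased[s]))
            for sp in range(s_count)
        ]
        tgt = np.concatenate(tgt_blocks, axis=1)
        weights.append((tgt @ src.conj().T) @ gram_inv)

    # leakage: energy that slice sp's calibration maps into slice s's output,
    # relative to the energy slice s maps into its own output
    leakage = np.zeros((s_count, s_count))
    for s in range(s_count):
        own = np.linalg.norm(_apply_kernel(weights[s], phased[s], kh, kw))
        for sp in range(s_count):
            e = np.linalg.norm(_apply_kernel(weights[s], phased[sp], kh, kw))
            leakage[s, sp] = e / own if own > 0 else np.inf
    return SliceKernels(
        weights=weights, kernel_size=(kh, kw),
        caipi_shift=np.atleast_1d(np.asarray(caipi_shift, dtype=int)),
        mb=s_count, regularization=reg, leakage=leakage,
    )


def unalias_sms(frame: MultiChannelKSpace, kernels: SliceKernels) -> list:
    """Separate a collapsed frame into per-slice k-space on the acquired grid.

    Returns one :class:`MultiChannelKSpace` per slice with the same mask
    (unacquired lines stay zero for the in-plane GRAPPA step).
    """
    acq = frame.acquired_ky
    kh, kw = kernels.kernel_size
    block = frame.data[:, :, acq] if frame.data.ndim == 3 else frame.data[:, :, acq, 0]
    j = block.shape[0]
    if kernels.weights[0].shape != (j, j * kh * kw):
        raise ValidationError("kernel geometry does not match the frame's channels")
    phases = caipi_phases(kernels.caipi_shift, block.shape[2], kernels.mb)
    out = []
    for s in range(kernels.n_slices):
        synth = _apply_kernel(kernels.weights[s], block, kh, kw)
        synth = synth * np.conj(phases[s])[None, None, :]  # undo CAIPI shift
        full = np.zeros_like(frame.data[:, :, :] if frame.data.ndim == 3
                             else frame.data[:, :, :, 0])
        full[:, :, acq] = synth
        out.append(MultiChannelKSpace(
            data=full, mask=frame.mask if frame.mask.ndim == 1 else frame.mask[:, 0],
            echo_spacing=frame.echo_spacing, fov=frame.fov[:2],
            line_times=frame.line_times,
        ))
    return out


# ----------------------------------------------------------------------
# in-plane GRAPPA


def _train_inplane_kernel(calib: np.ndarray, r_factor: int, offset: int,
                          kx_taps: int, reg: float) -> np.ndarray:
    """Kernel synthesizing the line ``offset`` above a source line from the
    two flanking acquired lines (spacing ``r_factor``), ``kx_taps`` wide."""
    j, nx, ny = calib.shape
    half = kx_taps // 2
    srcs, tgts = [], []
    for ky in range(0, ny - r_factor):
        s1 = calib[:, :, ky]
        s2 = calib[:, :, ky + r_factor]
        t = calib[:, :, ky + offset]
        cols = []
        for line in (s1, s2):
            padded = np.pad(line, ((0, 0), (half, kx_taps - 1 - half)))
            win = np.lib.stride_tricks.sliding_window_view(padded, kx_taps, axis=1)
            cols.append(win.transpose(0, 2, 1).reshape(j * kx_taps, nx))
        srcs.append(np.concatenate(cols, axis=0))
        tgts.append(t)
    src = np.concatenate(srcs, axis=1)
    tgt = np.concatenate(tgts, axis=1)
    gram = src @ src.conj().T
    smax_sq = float(np.max(np.linalg.eigvalsh(gram).real))
    ridge = (reg**2) * smax_sq * np.eye(gram.shape[0])
    return (tgt @ src.conj().T) @ np.linalg.inv(gram + ridge)


def grappa_inplane(
    frame: MultiChannelKSpace,
    calib,
    kx_taps: int = 5,
    reg: float = 1e-3,
    kernels: dict | None = None,
) -> MultiChannelKSpace:
    """Fill missing phase-encode lines of an undersampled frame (GRAPPA).

    Sources are the two acquired lines flanking each missing line across
    all channels, ``kx_taps`` readout taps each.  Pass ``kernels`` (as
    returned by :func:`train_inplane_kernels`) to reuse a calibration fit.
    """
    mask = frame.mask if frame.mask.ndim == 1 else frame.mask[:, 0]
    if mask.all():
        return frame.copy()
    acq = np.flatnonzero(mask)
    gaps = np.unique(np.diff(acq))
    if len(gaps) != 1:
        raise ValidationError("irregular undersampling pattern")
    r_factor = int(gaps[0])
    calib_arr = calib.data if isinstance(calib, MultiChannelKSpace) else np.asarray(calib)
    if calib_arr.shape[2] < 2 * r_factor + 1:
        raise ValidationError("insufficient calibration lines for in-plane GRAPPA")
    if kernels is None:
        kernels = train_inplane_kernels(calib_arr, r_factor, kx_taps, reg)

    j, nx, ny = frame.data.shape[:3]
    half = kx_taps // 2
    out = frame.copy()
    data = out.data if out.data.ndim == 3 else out.data[..., 0]
    padded = np.pad(data, ((0, 0), (half, kx_taps - 1 - half), (r_factor, r_factor)))

    def _cols(ky_padded):
        line = padded[:, :, ky_padded]
        win = np.lib.stride_tricks.sliding_window_view(line, kx_taps, axis=1)
        return win.transpose(0, 2, 1).reshape(j * kx_taps, nx)

    for ky in np.flatnonzero(~mask):
        below = acq[acq < ky]
        if below.size:
            ky_lo = int(below[-1])
        else:
            ky_lo = int(acq[0]) - r_factor  # virtual zero line below the grid
        offset = ky - ky_lo
        src = np.concatenate(
            [_cols(ky_lo + r_factor), _cols(ky_lo + 2 * r_factor)], axis=0
        )  # +r_factor accounts for the ky padding
        data[:, :, ky] = (kernels[offset] @ src).reshape(j, nx)
    out.mask = np.ones_like(mask)
    return out


def train_inplane_kernels(calib_arr: np.ndarray, r_factor: int,
                          kx_taps: int = 5, reg: float = 1e-3) -> dict:
    """Train one in-plane GRAPPA kernel per missing-line offset 1..R-1."""
    return {
        offset: _train_inplane_kernel(calib_arr, r_factor, offset, kx_taps, reg)
        for offset in range(1, r_factor)
    }


def estimate_noise_variance(frame: MultiChannelKSpace) -> float:
    """Per-complex-sample noise variance from the diagonal k-space corners.

    Edge ringing of a compact object concentrates in a cross along the
    k-space axes; the diagonal corners (far from DC along both axes)
    are noise-dominated.  The median of |S|^2 there is robust to the
    residual signal tail (median of an exponential |S|^2 distribution
    equals ``ln 2`` times its mean, which is corrected for).
    """
    data = frame.data if frame.data.ndim == 3 else frame.data[..., 0]
    nx = data.shape[1]
    edge = max(3, int(0.15 * nx))
    acq = frame.acquired_ky
    lo, hi = acq[acq < edge], acq[acq >= data.shape[2] - edge]
    blocks = []
    for ky_idx in (lo, hi):
        if ky_idx.size:
            blocks.append(data[:, :edge, :][:, :, ky_idx].ravel())
            blocks.append(data[:, -edge:, :][:, :, ky_idx].ravel())
    if not blocks:
        return 0.0
    corners = np.concatenate(blocks)
    return float(np.median(np.abs(corners) ** 2) / np.log(2))


def root_sum_of_squares(images: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel l2 norm across the channel axis (standard coil combination)."""
    return np.sqrt(np.sum(np.abs(images) ** 2, axis=axis))


# ----------------------------------------------------------------------
# end-to-end pipeline


class ReconPipeline:
    """Calibration-derived assets + per-frame reconstruction.

    Built once from a :class:`~navb0.containers.RawDataset`; trains the
    per-axis GRAPPA shift operators (slice axis via the proxy 3D
    calibration), the split-slice GRAPPA kernels and the in-plane GRAPPA
    kernels, reconstructs the per-slice reference images, and processes
    the reference navigator.  ``recon_frame`` then runs the full chain
    on any frame.
    """

    def __init__(
        self,
        dataset: RawDataset,
        kernel_size: tuple = (5, 5),
        kx_taps: int = 5,
        reg: float = 1e-3,
        reference_frame: int = 0,
        noise_var: float | None = None,
    ) -> None:
        self.dataset = dataset
        calibs = [c.data for c in dataset.calibration]
        self.n_slices = len(calibs)
        frame0 = dataset.frames[reference_frame]
        self.acq = frame0.acquired_ky
        mask = frame0.mask if frame0.mask.ndim == 1 else frame0.mask[:, 0]
        gaps = np.unique(np.diff(self.acq))
        self.r_factor = int(gaps[0]) if len(gaps) else 1
        self.caipi_shift = frame0.caipi_shift

        # shift operators: in-plane from stacked per-slice calibration,
        # slice axis from the proxy 3D volume
        # measurement noise level of the frames drives the Wiener ridge of
        # the correction operators: the reference frame repeats the
        # calibration signal, so their difference is noise
        if noise_var is None:
            phases = caipi_phases(self.caipi_shift, len(self.acq), len(calibs))
            predicted = sum(
                calibs[s][:, :, self.acq] * phases[s][None, None, :]
                for s in range(len(calibs))
            )
            diff = frame0.data[:, :, self.acq] - predicted
            noise_var = float(np.mean(np.abs(diff) ** 2))
        self.noise_var = noise_var

        stacked = np.stack(calibs, axis=-1)  # (J, Nx, Ny, S)
        # high-fidelity set for navigator estimation (small exponents)
        self.operators = {
            "readout": train_operator(stacked, "readout"),
            "phase": train_operator(stacked, "phase"),
        }
        # noise-matched sets for per-line frame correction, one per shift
        # direction (forward powers of the direction-matched operator
        # avoid inverse-power noise blow-up)
        self.correction_ops = {
            "readout": train_operator(stacked, "readout", noise_var=noise_var),
            "phase": train_operator(stacked, "phase", noise_var=noise_var),
        }
        self.correction_ops_neg = {
            "readout": train_operator(stacked, "readout", direction=-1,
                                      noise_var=noise_var),
            "phase": train_operator(stacked, "phase", direction=-1,
                                    noise_var=noise_var),
        }
        if self.n_slices > 1:
            positions = (dataset.slice_positions
                         or tuple(s * dataset.n_slices_total // self.n_slices
                                  for s in range(self.n_slices)))
            proxy = build_proxy_3d_calibration(
                calibs, positions, dataset.n_slices_total
            )
            self.proxy = proxy
            self.operators["slice"] = train_operator(
                proxy.volume, "slice", min_eig_modulus=0.5
            )
            self.correction_ops["slice"] = train_operator(
                proxy.volume, "slice", min_eig_modulus=0.5,
                noise_var=noise_var,
            )
            self.correction_ops_neg["slice"] = train_operator(
                proxy.volume, "slice", min_eig_modulus=0.5, direction=-1,
                noise_var=noise_var,
            )

        self.slice_kernels = train_split_slice_grappa(
            calibs, self.caipi_shift, self.acq, kernel_size, reg
        )
        self.inplane_kernels = [
            train_inplane_kernels(c, self.r_factor, kx_taps, reg)
            if self.r_factor > 1 else None
            for c in calibs
        ]

        # reference images (fully sampled calibration recon, per slice)
        self.reference_images = np.stack(
            [root_sum_of_squares(ifft2c(c)) for c in calibs]
        )

        # processed reference navigator
        nav_ref = dataset.navigators[reference_frame]
        _, self.nav_ref = nyquist_ghost_correct(frame0, nav_ref)

    # -- internals ---------------------------------------------------
    def _unalias_and_fill(self, frame: MultiChannelKSpace) -> np.ndarray:
        slices = unalias_sms(frame, self.slice_kernels)
        imgs = []
        for s, sl in enumerate(slices):
            if self.inplane_kernels[s] is not None:
                sl = grappa_inplane(
                    sl, self.dataset.calibration[s].data,
                    kernels=self.inplane_kernels[s],
                )
            imgs.append(root_sum_of_squares(ifft2c(sl.data)))
        return np.stack(imgs)

    def _corrector(self, frame, est):
        return correct_frame(
            frame, est, self.correction_ops,
            operators_neg=self.correction_ops_neg,
            warn_extrapolation=False,
            readout_exact=True,
            split_constant=True,
        )

    # -- public ------------------------------------------------------
    def estimate_frame(self, frame, nav, noise_floor=None) -> OffResonanceResults:
        """Ghost/B0-process the navigator and fit the off-resonance model."""
        _, nav_c = nyquist_ghost_correct(frame, nav)
        _, nav_c, _ = zeroth_order_b0_correct(frame, nav_c, self.nav_ref)
        return OffResonanceModel(
            nav_c, self.nav_ref, self.operators, noise_floor=noise_floor
        ).fit()

    def recon_frame(
        self,
        frame: MultiChannelKSpace,
        nav: NavigatorSet,
        correct: bool = True,
        refine: bool = False,
        refine_window: float = 0.05,
        refine_points: int = 11,
    ) -> tuple:
        """Full chain on one frame; returns ``(images (S, Nx, Ny), estimate)``."""
        frame, nav = nyquist_ghost_correct(frame, nav)
        frame, nav, _ = zeroth_order_b0_correct(frame, nav, self.nav_ref)
        est = None
        if correct:
            est = OffResonanceModel(nav, self.nav_ref, self.operators).fit()
            if refine:
                est = refine_dy(
                    est, frame, self.reference_images,
                    corrector=self._corrector,
                    reconstructor=self._unalias_and_fill,
                    window=refine_window, n_points=refine_points,
                )
            frame = self._corrector(frame, est)
        return self._unalias_and_fill(frame), est
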