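"""Per-frame k-space correction from an off-resonance estimate.

Each acquired EPI line at echo index ``n`` (echo index = line time /
echo spacing, continuing the navigator's count) has accrued a k-space
shift ``b(n) = c + n * d`` per axis; the correction applies the inverse
shift ``-b(n)`` with fractional GRAPPA-operator powers, making the frame
consistent again with the calibration data used for unaliasing.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import MultiChannelKSpace, NavigatorSet
from .errors import ValidationError
from .estimation import OffResonanceResults
from .fourier import centered_coords, fftc, ifftc
from .grappa import AXES, GrappaOperator

__all__ = ["correct_frame", "correct_navigator"]


def _exact_readout_shift(lines: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Shift each k-space line by its own delta along the (fully sampled)
    readout axis via the Fourier shift theorem: exact and noise-neutral.

    ``lines`` is (J, Nx, n); ``deltas[n]`` in samples.
    """
    nx = lines.shape[1]
    u = centered_coords(nx)
    hybrid = ifftc(lines, (1,))
    ramp = np.exp(-2j * np.pi * deltas[None, :] * u[:, None])  # (Nx, n)
    return fftc(hybrid * ramp[None, :, :], (1,))


def _line_operator_matrices(operators, exponents_per_axis, J, operators_neg=None):
    """Per-line composite correction matrices W_n = Wz_n Wy_n Wx_n, shape (n, J, J).

    When a backward-trained operator set is available, each line's shift
    uses the operator matching its sign (forward powers only), which
    avoids amplifying weakly encoded coil modes through matrix inverses.
    """
    n_lines = len(next(iter(exponents_per_axis.values())))
    w = np.broadcast_to(np.eye(J, dtype=complex), (n_lines, J, J)).copy()
    for axis in AXES:  # x applied first, then y, then z (same order as compose_shifts)
        exps = exponents_per_axis.get(axis)
        if exps is None or not np.any(exps):
            continue
        exps = np.asarray(exps, dtype=float)
        op = operators.get(axis)
        if op is None:
            raise ValidationError(
                f"nonzero {axis} correction requested but no {axis} operator provided"
            )
        op_neg = (operators_neg or {}).get(axis)
        if op_neg is None:
            wa = op.powers(exps)
        else:
            wa = np.empty((n_lines, J, J), dtype=complex)
            pos = exps >= 0
            if pos.any():
                wa[pos] = op.powers(exps[pos])
            if (~pos).any():
                wa[~pos] = op_neg.powers(-exps[~pos])
        w = wa @ w
    return w


def correct_frame(
    frame: MultiChannelKSpace,
    estimate: OffResonanceResults,
    operators: dict,
    nav: NavigatorSet | None = None,
    echo_offset: float = 0.0,
    warn_extrapolation: bool = True,
    operators_neg: dict | None = None,
    readout_exact: bool = False,
    max_exponent: float | None = None,
    split_constant: bool = False,
):
    """Undo the estimated off-resonance shifts on a frame's imaging k-space.

    Parameters
    ----------
    frame
        Collapsed (or single-band) frame k-space with ``line_times`` set
        on acquired lines.
    estimate
        The frame's fitted off-resonance coefficients (samples).
    operators
        Axis name -> trained :class:`~navb0.grappa.GrappaOperator`.
    nav
        Optional navigator to correct identically (shifts ``c + l*d`` at
        its own echo indices); returned alongside the frame when given.
    echo_offset
        Extra echo offset ``n0`` added to every imaging line's echo
        index when the container's line times do not already include the
        navigator block (default 0: line times are absolute).
    operators_neg
        Optional backward-trained operators (see
        :func:`navb0.grappa.train_operator` with ``direction=-1``) used
        for lines whose correction shift is negative.
    readout_exact
        Realize the readout-axis shift with the Fourier shift theorem
        (the readout is fully sampled, so that shift has a closed form)
        instead of operator powers; exact and noise-neutral.  Phase and
        slice axes always go through the operators.
    max_exponent
        Optional cap on operator exponents (samples).  Operators are
        calibrated for shifts up to one k-space sample; lines whose
        shift would exceed the cap are corrected by the capped amount
        instead of an extrapolated power.  Applies only to the
        operator-realized axes, never to the exact readout shift.
    split_constant
        Decompose the phase-encode shift into a frame-constant part
        ``c_y + n_center * d_y`` (the shift accrued at the k-space
        center crossing), realized exactly as a phase ramp on the
        acquired-line grid, plus the echo-differential remainder
        ``(n - n_center) * d_y`` through the operators.  The constant
        part is the bulk of the shift on the high-energy central lines,
        so this cuts both operator extrapolation error and noise gain.
    """
    if frame.line_times is None:
        raise ValidationError("frame has no line_times; per-line correction needs timing")
    if np.allclose(estimate.c, 0) and np.allclose(estimate.d, 0):
        out = frame.copy()
        return (out, nav.copy()) if nav is not None else out

    acq = frame.acquired_ky
    times = frame.line_times[acq]
    if np.any(~np.isfinite(times)):
        raise ValidationError("acquired lines have non-finite line_times")
    echo_idx = times / frame.echo_spacing + echo_offset

    # echo index of the k-space center crossing (effective TE)
    if split_constant:
        center_m = int(np.argmin(np.abs(acq - frame.data.shape[2] // 2)))
        n_center = float(echo_idx[center_m])
    else:
        n_center = 0.0

    # inverse shift per line, per axis
    exps = {}
    readout_deltas = None
    phase_const = 0.0
    max_b = 0.0
    for k, axis in enumerate(AXES):
        b = estimate.c[k] + echo_idx * estimate.d[k]
        max_b = max(max_b, float(np.max(np.abs(b))))
        if estimate.c[k] == 0 and estimate.d[k] == 0:
            continue
        if axis == "readout" and readout_exact:
            readout_deltas = -b
            continue
        if axis == "phase" and split_constant:
            phase_const = -(estimate.c[k] + n_center * estimate.d[k])
            e = -(echo_idx - n_center) * estimate.d[k]
        else:
            e = -b
        if max_exponent is not None:
            e = np.clip(e, -max_exponent, max_exponent)
        exps[axis] = e
    if warn_extrapolation and max_b > 1.0:
        warnings.warn(
            f"correction shift reaches {max_b:.2f} samples (> 1); "
            "operator extrapolation regime",
            RuntimeWarning,
            stacklevel=2,
        )

    out = frame.copy()
    data = out.data
    if readout_deltas is not None:
        if data.ndim == 3:
            data[:, :, acq] = _exact_readout_shift(data[:, :, acq], readout_deltas)
        else:
            for z in range(data.shape[3]):
                data[:, :, acq, z] = _exact_readout_shift(
                    data[:, :, acq, z], readout_deltas
                )
    if phase_const != 0.0:
        # constant ky shift: exact phase-ramp resampling on the regular
        # acquired-line grid (R full-grid samples apart -> delta/R grid units)
        gaps = np.diff(acq)
        r_step = int(gaps[0]) if len(gaps) else 1
        sub = data[:, :, acq] if data.ndim == 3 else data[:, :, acq, 0]
        u = centered_coords(sub.shape[2])
        hybrid = ifftc(sub, (2,))
        hybrid *= np.exp(-2j * np.pi * (phase_const / r_step) * u)[None, None, :]
        if data.ndim == 3:
            data[:, :, acq] = fftc(hybrid, (2,))
        else:
            data[:, :, acq, 0] = fftc(hybrid, (2,))
    if exps:
        J = frame.n_channels
        w = _line_operator_matrices(operators, exps, J, operators_neg)
        if data.ndim == 3:
            # (J, Nx, Ny): correct each acquired ky line
            data[:, :, acq] = np.einsum("nij,jxn->ixn", w, data[:, :, acq])
        else:
            data[:, :, acq, :] = np.einsum("nij,jxnz->ixnz", w, data[:, :, acq, :])

    if nav is None:
        return out

    nav_out = nav.copy()
    nav_echo = nav.line_echo_times / frame.echo_spacing
    nav_exps = {}
    for k, axis in enumerate(AXES):
        if estimate.c[k] == 0 and estimate.d[k] == 0:
            continue
        bnav = -(estimate.c[k] + nav_echo * estimate.d[k])
        if axis == "readout" and readout_exact:
            shifted = _exact_readout_shift(
                np.moveaxis(nav_out.lines, 0, -1), bnav
            )
            nav_out.lines = np.moveaxis(shifted, -1, 0)
        else:
            nav_exps[axis] = bnav
    if nav_exps:
        wn = _line_operator_matrices(operators, nav_exps, nav.n_channels,
                                     operators_neg)
        nav_out.lines = np.einsum("nij,njm->nim", wn, nav_out.lines)
    return out, nav_out


def correct_navigator(
    nav: NavigatorSet,
    estimate: OffResonanceResults,
    operators: dict,
    echo_spacing: float,
) -> NavigatorSet:
    """Correct only the navigator lines (shifts ``c + l*d`` at echo indices l)."""
    out = nav.copy()
    nav_echo = nav.line_echo_times / echo_spacing
    exps = {}
    for k, axis in enumerate(AXES):
        if estimate.c[k] == 0 and estimate.d[k] == 0:
            continue
        exps[axis] = -(estimate.c[k] + nav_echo * estimate.d[k])
    if exps:
        w = _line_operator_matrices(operators, exps, nav.n_channels)
        out.lines = np.einsum("nij,njm->nim", w, out.lines)
    return out
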