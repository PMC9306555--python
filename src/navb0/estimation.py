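"""Dynamic off-resonance estimation from the 3-line EPI reference navigator.

Spatially linear off-resonance perturbations manifest as k-space shifts
that grow linearly across the equally spaced navigator echoes: line
``l`` of the frame-p navigator is the reference line shifted by

    b_l = c + l * d,    l in {1, 2, 3},

per axis, where ``c = (cx, cy, cz)`` is the offset component and
``d = (dx, dy, dz)`` the per-echo growth, both in k-space samples.  The
six coefficients are estimated by least squares on the stacked
three-line system, the shifts being realised with fractional GRAPPA
operator powers.  The model follows the statsmodels convention: build an
:class:`OffResonanceModel` from data, call :meth:`~OffResonanceModel.fit`
to obtain :class:`OffResonanceResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .containers import MultiChannelKSpace, NavigatorSet
from .errors import ValidationError
from .fourier import centered_coords, ifftc
from .grappa import AXES, GrappaOperator, compose_shifts

__all__ = [
    "GAMMA_BAR",
    "FieldModel",
    "OffResonanceModel",
    "OffResonanceResults",
    "estimate_coefficients",
    "navigator_shift_model",
    "refine_dy",
    "shift_to_gradient",
    "gradient_to_shift",
]

#: reduced gyromagnetic ratio of the proton, Hz/T
GAMMA_BAR = 42.577478518e6


@dataclass
class FieldModel:
    """A spatially linear field perturbation: ``f(r) = offset + g . r`` (Hz).

    ``gradient`` is in Hz per meter per axis; ``global_offset`` is the
    zeroth-order term, carried separately because global frequency
    correction is handled by its own reconstruction step.
    """

    gradient: tuple = (0.0, 0.0, 0.0)
    global_offset: float = 0.0

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in np.atleast_1d(self.gradient))
        if len(g) < 3:
            g = g + (0.0,) * (3 - len(g))
        self.gradient = g
        self.global_offset = float(self.global_offset)

    def evaluate(self, coords) -> np.ndarray:
        """Field in Hz at coordinates ``coords = (x[, y[, z]])`` (meters, broadcastable)."""
        out = np.asarray(self.global_offset, dtype=float)
        for g, r in zip(self.gradient, coords):
            out = out + g * np.asarray(r)
        return out

    def scaled(self, factor: float) -> "FieldModel":
        return FieldModel(
            gradient=tuple(factor * g for g in self.gradient),
            global_offset=factor * self.global_offset,
        )


# ----------------------------------------------------------------------
# unit conversions


def gradient_to_shift(gradient_uT_per_m: float, echo_spacing: float, fov_axis: float) -> float:
    """Per-echo k-space shift (samples) produced by a constant shim gradient.

    A gradient ``G`` (uT/m) adds a frequency ramp ``gamma_bar * G`` Hz/m;
    over one echo spacing this accrues a k-shift of
    ``gamma_bar * G * echo_spacing * fov`` samples.
    """
    if echo_spacing <= 0 or fov_axis <= 0:
        raise ValidationError("echo_spacing and fov must be > 0")
    return GAMMA_BAR * gradient_uT_per_m * 1e-6 * echo_spacing * fov_axis


def shift_to_gradient(d_axis: float, echo_spacing: float, fov_axis: float) -> float:
    """Inverse of :func:`gradient_to_shift`: samples per echo -> uT/m."""
    if echo_spacing <= 0 or fov_axis <= 0:
        raise ValidationError("echo_spacing and fov must be > 0")
    return d_axis / (GAMMA_BAR * echo_spacing * fov_axis) * 1e6


# ----------------------------------------------------------------------
# forward model


def navigator_shift_model(
    c,
    d,
    navs_ref: NavigatorSet,
    operators: dict,
    warn_extrapolation: bool = False,
) -> NavigatorSet:
    """Predict a frame navigator from the reference via per-line shifts c + l*d."""
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    lines = np.empty_like(navs_ref.lines)
    for l in (1, 2, 3):
        delta = c + l * d
        lines[l - 1] = compose_shifts(
            operators, navs_ref.lines[l - 1], delta, warn_extrapolation
        )
    return NavigatorSet(
        lines=lines,
        line_echo_times=navs_ref.line_echo_times.copy(),
        frame_index=navs_ref.frame_index,
        slice_group=navs_ref.slice_group,
    )


# ----------------------------------------------------------------------
# model / results


class OffResonanceModel:
    """Six-coefficient linear off-resonance model for one frame's navigator.

    Parameters
    ----------
    nav
        Frame-p navigator (3 lines).
    nav_ref
        Reference-frame navigator (frame 0 or the calibration scan's).
    operators
        Mapping axis name -> trained :class:`~navb0.grappa.GrappaOperator`.
        Axes without an operator are held at zero shift.
    bounds
        Search bound (samples) on every coefficient; navigator shifts
        beyond one calibrated unit shift are extrapolations.
    noise_floor
        Optional RMS navigator amplitude below which estimation is
        skipped and a zero, low-confidence estimate returned.
    """

    def __init__(
        self,
        nav: NavigatorSet,
        nav_ref: NavigatorSet,
        operators: dict,
        bounds: float = 1.0,
        noise_floor: float | None = None,
    ) -> None:
        if nav.lines.shape != nav_ref.lines.shape:
            raise ValidationError("frame and reference navigators must share (J, M)")
        self.nav = nav
        self.nav_ref = nav_ref
        self.operators = {a: operators.get(a) for a in AXES}
        self.bounds = float(bounds)
        self.noise_floor = noise_floor
        self.axes = tuple(a for a in AXES if self.operators[a] is not None)
        if not self.axes:
            raise ValidationError("at least one trained operator is required")
        self._ref_energy = float(np.linalg.norm(nav.lines))

    # -- objective ---------------------------------------------------
    def _expand(self, params: np.ndarray) -> tuple:
        """Map the active parameter vector to full (c, d) triples."""
        c = np.zeros(3)
        d = np.zeros(3)
        for i, axis in enumerate(self.axes):
            k = AXES.index(axis)
            c[k] = params[i]
            d[k] = params[len(self.axes) + i]
        return c, d

    def residual(self, params: np.ndarray) -> float:
        """Normalized stacked residual of the three-line shift model."""
        c, d = self._expand(np.asarray(params, dtype=float))
        if np.max(np.abs(np.concatenate([c + l * d for l in (1, 2, 3)]))) > self.bounds + 1e-9:
            return 2.0 + float(np.sum(params**2))  # soft barrier outside bounds
        pred = navigator_shift_model(c, d, self.nav_ref, self.operators)
        return float(np.linalg.norm(pred.lines - self.nav.lines) / self._ref_energy)

    # -- initialization ---------------------------------------------
    def _init_readout(self) -> tuple:
        """Per-line readout shifts from the hybrid-space phase ramp.

        Navigators are fully sampled along the readout, so the shift of
        each line relative to the reference is read off the slope of the
        phase of the x-projection cross-product; (c_x, d_x) then follow
        from a linear fit over the line index.
        """
        m = self.nav.n_readout
        u = centered_coords(m)
        shifts = np.zeros(3)
        for l in range(3):
            a = ifftc(self.nav.lines[l], (1,))
            b = ifftc(self.nav_ref.lines[l], (1,))
            xprod = np.sum(a * np.conj(b), axis=0)  # (M,) over channels
            w = np.abs(xprod)
            if w.sum() == 0:
                continue
            phase = np.unwrap(np.angle(xprod))
            # weighted LS fit of phase = -2 pi delta u + const
            A = np.stack([u, np.ones_like(u)], axis=1) * np.sqrt(w)[:, None]
            y = phase * np.sqrt(w)
            slope = np.linalg.lstsq(A, y, rcond=None)[0][0]
            shifts[l] = -slope / (2 * np.pi)
        ls = np.array([1.0, 2.0, 3.0])
        d0 = float(np.polyfit(ls, shifts, 1)[0])
        c0 = float(np.mean(shifts - ls * d0))
        return c0, d0

    # -- fitting -----------------------------------------------------
    def fit(
        self,
        x0: np.ndarray | None = None,
        xatol: float = 1e-5,
        fatol: float = 1e-10,
        maxiter: int | None = None,
    ) -> "OffResonanceResults":
        """Estimate (c, d) by derivative-free minimization of the stacked residual.

        Initialization uses sub-sample cross-correlation along the fully
        sampled readout axis; the joint refinement is Nelder-Mead (the
        objective is nonlinear in the operator exponents).  Deterministic
        given the inputs.
        """
        if self.noise_floor is not None:
            rms = np.sqrt(np.mean(np.abs(self.nav.lines) ** 2))
            if rms < self.noise_floor:
                return OffResonanceResults(
                    c=np.zeros(3), d=np.zeros(3),
                    residual=1.0, model=self,
                    frame_index=self.nav.frame_index,
                    slice_group=self.nav.slice_group,
                    converged=False, low_confidence=True,
                )
        n = len(self.axes)
        if x0 is None:
            x0 = np.zeros(2 * n)
            if "readout" in self.axes:
                c0, d0 = self._init_readout()
                i = self.axes.index("readout")
                x0[i] = np.clip(c0, -self.bounds, self.bounds)
                x0[n + i] = np.clip(d0, -self.bounds, self.bounds)
        x0 = np.asarray(x0, dtype=float)

        f0 = self.residual(x0)
        if f0 < 1e-12:  # already a perfect match (e.g. the reference frame)
            c, d = self._expand(x0)
            return OffResonanceResults(
                c=c, d=d, residual=f0, model=self,
                frame_index=self.nav.frame_index,
                slice_group=self.nav.slice_group, converged=True,
            )

        res = scipy.optimize.minimize(
            self.residual,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxiter": maxiter if maxiter is not None else 400 * n,
                "initial_simplex": _initial_simplex(x0, 0.02),
            },
        )
        if not res.success:
            warnings.warn(
                "coefficient search did not fully converge; returning best point",
                RuntimeWarning,
                stacklevel=2,
            )
        c, d = self._expand(res.x)
        return OffResonanceResults(
            c=c, d=d, residual=float(res.fun), model=self,
            frame_index=self.nav.frame_index,
            slice_group=self.nav.slice_group,
            converged=bool(res.success),
        )


def _initial_simplex(x0: np.ndarray, step: float) -> np.ndarray:
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += step
    return simplex


@dataclass
class OffResonanceResults:
    """Estimated off-resonance coefficients for one frame / slice group.

    ``c`` and ``d`` are in k-space samples; ``residual`` is the relative
    least-squares residual of the stacked navigator system (0 = perfect
    model fit, ~1 = no explanatory power).
    """

    c: np.ndarray
    d: np.ndarray
    residual: float
    frame_index: int = 0
    slice_group: int = 0
    refined: bool = False
    converged: bool = True
    low_confidence: bool = False
    model: OffResonanceModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float).reshape(3)
        self.d = np.asarray(self.d, dtype=float).reshape(3)

    # -- derived quantities -----------------------------------------
    def line_shift(self, echo_index) -> np.ndarray:
        """Shift vector ``c + n * d`` (samples) at echo index ``n`` (broadcastable)."""
        n = np.asarray(echo_index, dtype=float)
        return self.c + n[..., None] * self.d if n.ndim else self.c + float(n) * self.d

    def gradients(self, echo_spacing: float, fov: tuple) -> np.ndarray:
        """Per-axis shim-gradient equivalents of ``d`` in uT/m."""
        fov = np.atleast_1d(fov).astype(float)
        out = np.zeros(3)
        for i in range(min(3, len(fov))):
            out[i] = shift_to_gradient(self.d[i], echo_spacing, fov[i])
        return out

    def replace(self, **kwargs) -> "OffResonanceResults":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)

    # -- reporting ---------------------------------------------------
    def summary(self) -> str:
        rows = []
        header = (
            f"Off-resonance estimate  frame={self.frame_index} "
            f"slice_group={self.slice_group}\n"
            f"residual={self.residual:.4g}  refined={self.refined} "
            f"converged={self.converged}\n"
        )
        rows.append(f"{'axis':>8}{'c [samples]':>14}{'d [samples/echo]':>18}")
        for i, ax in enumerate(("x", "y", "z")):
            rows.append(f"{ax:>8}{self.c[i]:>14.5f}{self.d[i]:>18.5f}")
        return header + "\n".join(rows)

    def to_dict(self) -> dict:
        return {
            "frame": int(self.frame_index),
            "slice_group": int(self.slice_group),
            "c": [float(v) for v in self.c],
            "d": [float(v) for v in self.d],
            "residual": float(self.residual),
            "refined": bool(self.refined),
            "low_confidence": bool(self.low_confidence),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "OffResonanceResults":
        return cls(
            c=np.asarray(payload["c"], dtype=float),
            d=np.asarray(payload["d"], dtype=float),
            residual=float(payload.get("residual", float("nan"))),
            frame_index=int(payload.get("frame", 0)),
            slice_group=int(payload.get("slice_group", 0)),
            refined=bool(payload.get("refined", False)),
            low_confidence=bool(payload.get("low_confidence", False)),
        )


def estimate_coefficients(
    navs_p: NavigatorSet,
    navs_ref: NavigatorSet,
    operators: dict,
    **fit_kwargs,
) -> OffResonanceResults:
    """Convenience wrapper: build the model and fit in one call."""
    model_kwargs = {
        k: fit_kwargs.pop(k)
        for k in ("bounds", "noise_floor")
        if k in fit_kwargs
    }
    return OffResonanceModel(navs_p, navs_ref, operators, **model_kwargs).fit(
        **fit_kwargs
    )


# ----------------------------------------------------------------------
# dy refinement


def refine_dy(
    estimate: OffResonanceResults,
    frame: MultiChannelKSpace,
    reference_image: np.ndarray,
    corrector,
    reconstructor,
    window: float = 0.05,
    n_points: int = 11,
    flat_tol: float = 1e-4,
) -> OffResonanceResults:
    """Grid-refine the dy coefficient against a fully sampled reference image.

    The navigator constrains the phase-encode axis least (it is a single
    ky line), so ``dy`` is perturbed on a grid around the initial
    estimate; each candidate is used to correct the frame, an
    intermediate image is reconstructed, and the candidate maximizing
    the Pearson correlation with the reference magnitude wins.  All
    other coefficients are left untouched.  A flat correlation profile
    keeps the initial value.

    Parameters
    ----------
    corrector
        ``corrector(frame, estimate) -> corrected frame`` callback.
    reconstructor
        ``reconstructor(corrected frame) -> magnitude image`` callback.
    """
    grid = estimate.d[1] + np.linspace(-window, window, int(n_points))
    if len(grid) == 1:
        return estimate.replace(refined=True)
    ref = np.abs(np.asarray(reference_image)).ravel()
    scores = np.empty(len(grid))
    for i, dy in enumerate(grid):
        cand = estimate.replace(d=np.array([estimate.d[0], dy, estimate.d[2]]))
        img = np.abs(np.asarray(reconstructor(corrector(frame, cand)))).ravel()
        scores[i] = np.corrcoef(img, ref)[0, 1]
    if np.max(scores) - np.min(scores) < flat_tol:
        return estimate.replace(refined=False)
    best = grid[int(np.argmax(scores))]
    return estimate.replace(
        d=np.array([estimate.d[0], float(best), estimate.d[2]]), refined=True
    )


# ----------------------------------------------------------------------
# JSON sidecar


def write_estimates(estimates, path) -> None:
    """Write per-frame estimates as a JSON sidecar for downstream QC."""
    payload = [e.to_dict() for e in estimates]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_estimates(path):
    with open(path) as fh:
        payload = json.load(fh)
    return [OffResonanceResults.from_dict(p) for p in payload]
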