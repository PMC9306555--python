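"""Image-quality metrics: entropy, nRMSE, tSNR and background artifact power.

Entropy measures ghosting (energy spread over pixels), nRMSE measures
geometric distortion against a reference reconstruction, tSNR measures
temporal stability of the series, and artifact power is the l2 norm of
magnitudes in a background region that the object never occupies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .errors import ValidationError

__all__ = [
    "image_entropy",
    "nrmse",
    "tsnr",
    "artifact_power",
    "background_mask_from_reference",
    "MetricsReport",
]


def image_entropy(image: np.ndarray, normalize: bool = True) -> float:
    """Shannon entropy (bits) of the pixel-magnitude distribution.

    With ``normalize`` (default) magnitudes are scaled to sum to 1 so
    the value is a proper, scale-invariant entropy: 0 for a single
    nonzero pixel, ``log2(N)`` for a uniform image.  ``normalize=False``
    evaluates ``-sum I_k log2 I_k`` on the raw magnitudes.
    """
    mag = np.abs(np.asarray(image, dtype=float)).ravel()
    total = mag.sum()
    if total <= 0:
        raise ValidationError("entropy of an all-zero image is undefined")
    if normalize:
        mag = mag / total
    nz = mag > 0
    return float(-np.sum(mag[nz] * np.log2(mag[nz])))


def nrmse(
    image: np.ndarray,
    reference: np.ndarray,
    normalize_by: str = "reference",
) -> float:
    """RMS error normalized by an intensity range.

    ``normalize_by='reference'`` (default) divides by the reference
    image's max-min range; ``'image'`` uses the test image's range
    instead.
    """
    image = np.abs(np.asarray(image, dtype=float))
    reference = np.abs(np.asarray(reference, dtype=float))
    if image.shape != reference.shape:
        raise ValidationError(
            f"shape mismatch: {image.shape} vs {reference.shape}"
        )
    norm_img = reference if normalize_by == "reference" else image
    rng = float(norm_img.max() - norm_img.min())
    if rng <= 0:
        raise ValidationError("normalization image has zero intensity range")
    return float(np.sqrt(np.mean((image - reference) ** 2)) / rng)


def tsnr(frames: np.ndarray, mask: np.ndarray | None = None) -> tuple:
    """Temporal SNR: per-pixel mean/std over the frame axis + masked summary.

    Returns ``(map, summary)`` where ``summary`` is a dict with the
    mean, sem and pixel count over the mask (zero-variance pixels map to
    +inf and are excluded from the summary, their count logged).
    """
    frames = np.abs(np.asarray(frames, dtype=float))
    if frames.shape[0] < 2:
        raise ValidationError("tSNR needs at least 2 frames")
    mean = frames.mean(axis=0)
    std = frames.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(std > 0, mean / np.where(std > 0, std, 1.0), np.inf)
    if mask is None:
        mask = np.ones(mean.shape, dtype=bool)
    vals = tmap[mask]
    finite = np.isfinite(vals)
    v = vals[finite]
    summary = {
        "mean": float(v.mean()) if v.size else float("nan"),
        "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
        "n_pixels": int(v.size),
        "n_infinite": int(np.sum(~finite)),
    }
    return tmap, summary


def artifact_power(image: np.ndarray, background_mask: np.ndarray) -> float:
    """l2 norm of pixel magnitudes inside the background mask."""
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise ValidationError("empty background mask")
    mag = np.abs(np.asarray(image, dtype=float))
    if mag.shape != background_mask.shape:
        raise ValidationError("image and mask shapes differ")
    return float(np.linalg.norm(mag[background_mask]))


def background_mask_from_reference(
    reference: np.ndarray,
    rel_threshold: float = 0.05,
    dilate: int = 2,
) -> np.ndarray:
    """Background annulus: complement of the dilated object support.

    Support is thresholded at ``rel_threshold`` of the clean reference's
    peak magnitude and dilated by ``dilate`` pixels so edge pixels never
    count as artifact.
    """
    mag = np.abs(np.asarray(reference, dtype=float))
    support = mag > rel_threshold * mag.max()
    if dilate > 0:
        support = scipy.ndimage.binary_dilation(support, iterations=dilate)
    return ~support


@dataclass
class MetricsReport:
    """Per-frame quality metrics of one reconstructed series."""

    entropy: np.ndarray  # (T,) bits
    nrmse: np.ndarray | None = None  # (T,) fraction vs reference
    artifact_power: np.ndarray | None = None  # (T,)
    tsnr_summary: dict | None = None

    def to_dict(self) -> dict:
        def _ser(v):
            return None if v is None else [float(x) for x in np.atleast_1d(v)]

        out = {
            "entropy_bits": _ser(self.entropy),
            "nrmse": _ser(self.nrmse),
            "artifact_power": _ser(self.artifact_power),
        }
        if self.tsnr_summary is not None:
            out["tsnr"] = self.tsnr_summary
        return out


def evaluate_series(
    frames: np.ndarray,
    reference: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> MetricsReport:
    """Per-frame entropy / nRMSE / artifact power and tSNR for a series.

    ``frames`` is ``(T, ...)`` magnitude; ``reference`` a single
    reference image broadcast over frames.
    """
    frames = np.abs(np.asarray(frames, dtype=float))
    ent = np.array([image_entropy(f) for f in frames])
    err = None
    if reference is not None:
        err = np.array([nrmse(f, reference) for f in frames])
    ap = None
    if background_mask is not None:
        ap = np.array([artifact_power(f, background_mask) for f in frames])
    summary = None
    if frames.shape[0] >= 2:
        _, summary = tsnr(frames, brain_mask)
    return MetricsReport(entropy=ent, nrmse=err, artifact_power=ap,
                         tsnr_summary=summary)
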