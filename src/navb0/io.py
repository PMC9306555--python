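"""On-disk containers: HDF5 raw k-space, NIfTI image series, JSON sidecars.

The raw container is HDF5 with an ISMRMRD-compatible flavor of naming:

    /calibration/data            (S, J, Nx, Ny) complex, fully sampled
    /calibration/slice_positions (S,)
    /frames/<p>/data             (J, Nx, Ny) complex
    /frames/<p>/mask             (Ny,) bool
    /frames/<p>/line_times       (Ny,) seconds (nan = not acquired)
    /frames/<p>/navigator        (3, J, M) complex
    /frames/<p>/nav_echo_times   (3,) seconds
    root attrs: echo_spacing, fov, caipi_shift, n_slices_total, n_frames

k-space layout (DC at index n//2 on every axis), units (seconds / Hz /
uT/m) and indexing follow :mod:`navb0.containers`.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .containers import ImageSeries, MultiChannelKSpace, NavigatorSet, RawDataset
from .errors import SchemaError, ValidationError

__all__ = ["read_raw", "write_raw", "write_image_series", "read_image_series"]

_SCHEMA_VERSION = 1


def write_raw(dataset: RawDataset, path, overwrite: bool = False) -> None:
    """Write a :class:`RawDataset` to the HDF5 container.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    import os

    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    ref = dataset.calibration[0] if dataset.calibration else (
        dataset.frames[0] if dataset.frames else None
    )
    if ref is None:
        raise ValidationError("dataset has neither calibration nor frames")
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = _SCHEMA_VERSION
        fh.attrs["echo_spacing"] = ref.echo_spacing
        fh.attrs["fov"] = np.asarray(ref.fov, dtype=float)
        caipi = dataset.frames[0].caipi_shift if dataset.frames else ref.caipi_shift
        fh.attrs["caipi_shift"] = np.asarray(caipi, dtype=int)
        fh.attrs["n_slices_total"] = int(dataset.n_slices_total)
        fh.attrs["n_frames"] = len(dataset.frames)

        calib = fh.create_group("calibration")
        calib.create_dataset(
            "data", data=np.stack([c.data for c in dataset.calibration])
        )
        positions = dataset.slice_positions or tuple(range(len(dataset.calibration)))
        calib.create_dataset("slice_positions", data=np.asarray(positions, dtype=int))

        frames = fh.create_group("frames")
        for p, (frame, nav) in enumerate(zip(dataset.frames, dataset.navigators)):
            g = frames.create_group(str(p))
            g.create_dataset("data", data=frame.data)
            g.create_dataset("mask", data=frame.mask)
            if frame.line_times is not None:
                g.create_dataset("line_times", data=frame.line_times)
            g.create_dataset("navigator", data=nav.lines)
            g.create_dataset("nav_echo_times", data=nav.line_echo_times)
            g.attrs["frame_index"] = int(nav.frame_index)
            g.attrs["slice_group"] = int(nav.slice_group)

        if dataset.ground_truth is not None:
            fh.attrs["ground_truth"] = json.dumps(dataset.ground_truth)


def _require(node, key: str, kind: str):
    if kind == "attr":
        if key not in node.attrs:
            raise SchemaError(f"missing attribute '{key}' in {node.name or '/'}")
        return node.attrs[key]
    if key not in node:
        raise SchemaError(f"missing group/dataset '{key}' in {node.name or '/'}")
    return node[key]


def read_raw(path) -> RawDataset:
    """Read the HDF5 raw container back into a :class:`RawDataset`.

    Schema violations raise :class:`~navb0.errors.SchemaError` naming
    the missing key; structural violations (e.g. a navigator without
    exactly 3 lines) raise :class:`~navb0.errors.ValidationError`.
    """
    with h5py.File(path, "r") as fh:
        echo_spacing = float(_require(fh, "echo_spacing", "attr"))
        fov = tuple(np.atleast_1d(_require(fh, "fov", "attr")).astype(float))
        caipi = np.atleast_1d(_require(fh, "caipi_shift", "attr")).astype(int)
        n_slices_total = int(_require(fh, "n_slices_total", "attr"))

        calib_group = _require(fh, "calibration", "group")
        calib_data = np.asarray(_require(calib_group, "data", "dataset"))
        positions = tuple(
            int(v) for v in np.asarray(_require(calib_group, "slice_positions", "dataset"))
        )
        calibration = [
            MultiChannelKSpace(
                data=calib_data[s],
                mask=np.ones(calib_data.shape[-1], dtype=bool),
                echo_spacing=echo_spacing,
                fov=fov,
            )
            for s in range(calib_data.shape[0])
        ]

        frames_group = _require(fh, "frames", "group")
        frames, navigators = [], []
        for p in sorted(frames_group, key=int):
            g = frames_group[p]
            data = np.asarray(_require(g, "data", "dataset"))
            mask = np.asarray(_require(g, "mask", "dataset"), dtype=bool)
            line_times = (
                np.asarray(g["line_times"]) if "line_times" in g else None
            )
            nav_lines = np.asarray(_require(g, "navigator", "dataset"))
            if nav_lines.ndim != 3 or nav_lines.shape[0] != 3:
                raise ValidationError(
                    f"frame {p}: navigator must have exactly 3 lines, "
                    f"got shape {nav_lines.shape}"
                )
            if nav_lines.shape[2] != data.shape[1]:
                raise ValidationError(
                    f"frame {p}: navigator readout length {nav_lines.shape[2]} "
                    f"!= acquisition readout {data.shape[1]}"
                )
            nav_times = np.asarray(_require(g, "nav_echo_times", "dataset"))
            frames.append(
                MultiChannelKSpace(
                    data=data, mask=mask, echo_spacing=echo_spacing, fov=fov,
                    line_times=line_times, caipi_shift=caipi,
                )
            )
            navigators.append(
                NavigatorSet(
                    lines=nav_lines, line_echo_times=nav_times,
                    frame_index=int(g.attrs.get("frame_index", int(p))),
                    slice_group=int(g.attrs.get("slice_group", 0)),
                )
            )

        ground_truth = None
        if "ground_truth" in fh.attrs:
            ground_truth = json.loads(fh.attrs["ground_truth"])

    return RawDataset(
        calibration=calibration, frames=frames, navigators=navigators,
        slice_positions=positions, n_slices_total=n_slices_total,
        ground_truth=ground_truth,
    )


def write_image_series(
    series: ImageSeries, path, sanitize: bool = False
) -> None:
    """Write magnitude frames as a NIfTI-1 volume (frame axis 4th).

    Non-finite values raise unless ``sanitize`` replaces them with 0.
    """
    import nibabel as nib

    frames = np.abs(np.asarray(series.frames, dtype=float))
    if not np.all(np.isfinite(frames)):
        if not sanitize:
            raise ValidationError(
                "non-finite values in image series; pass sanitize=True to zero them"
            )
        frames = np.nan_to_num(frames, nan=0.0, posinf=0.0, neginf=0.0)
    # (T, X, Y[, Z]) -> (X, Y, Z, T)
    if frames.ndim == 3:
        frames = frames[:, :, :, None]
    vol = np.moveaxis(frames, 0, -1)
    voxel = list(series.voxel_size) + [1e-3] * (3 - len(series.voxel_size))
    affine = np.diag([v * 1e3 for v in voxel[:3]] + [1.0])  # mm in the header
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header.set_zooms(tuple(v * 1e3 for v in voxel[:3]) + (1.0,))
    nib.save(img, str(path))


def read_image_series(path) -> ImageSeries:
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    if vol.ndim == 3:
        vol = vol[..., None]
    frames = np.moveaxis(vol, -1, 0)
    zooms = img.header.get_zooms()[:3]
    return ImageSeries(frames=frames, voxel_size=tuple(z * 1e-3 for z in zooms))
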