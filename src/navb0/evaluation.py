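"""Reproducible validation studies on the standard synthetic scene.

Each function builds its inputs from the synthetic scanner, runs the
estimation/correction machinery, and returns the measured quantities.
They are exercised by the test suite and by ``scripts/acceptance.py``.

The coil array layout is a fixed design (it emulates one physical
multichannel receive coil); the ``seed`` arguments drive measurement
noise and perturbation draws.
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .estimation import (
    GAMMA_BAR,
    FieldModel,
    OffResonanceModel,
    shift_to_gradient,
)
from .fourier import fft2c, fourier_shift
from .grappa import (
    apply_shift,
    build_proxy_3d_calibration,
    fractional_power,
    train_operator,
)
from .metrics import (
    artifact_power,
    background_mask_from_reference,
    image_entropy,
    nrmse,
    tsnr,
)
from .recon import ReconPipeline
from .simulate import PerturbationSchedule, collapse_sms, default_scene, encode_epi

#: seed of the fixed coil-array design (one emulated physical coil)
COIL_DESIGN_SEED = 0


def _collapsed_nav(scene, field, rng=None):
    per = [encode_epi(scene, field, s, rng=rng) for s in range(scene.n_slices)]
    _, nav = collapse_sms(
        [f for f, _ in per], [n for _, n in per],
        tuple(range(scene.n_slices)),
    )
    return nav


def _mb2_operators(scene, ks):
    stacked = np.stack(ks, axis=-1)
    proxy = build_proxy_3d_calibration(
        ks, scene.slice_positions, scene.n_slices_total
    )
    return {
        "readout": train_operator(stacked, "readout"),
        "phase": train_operator(stacked, "phase"),
        "slice": train_operator(proxy.volume, "slice", min_eig_modulus=0.5),
    }


# ----------------------------------------------------------------------
# operator fidelity and algebra


def operator_shift_fidelity(deltas=(1.0, -1.0, 0.5, -0.5, 0.25)) -> dict:
    """Worst-case NRMSE of operator shifts vs the Fourier shift-theorem
    oracle, per axis, on noiseless 64x64 / J=12 data (slice axis via the
    proxy-3D calibration of the MB=2 scene)."""
    scene1 = default_scene(n=64, j=12, mb=1, snr_db=None, seed=COIL_DESIGN_SEED)
    k1 = fft2c(scene1.coils.slice(0) * scene1.objects[0])
    out = {}
    for axis_name, axis in (("readout", 1), ("phase", 2)):
        op = train_operator(k1, axis_name)
        errs = [
            np.linalg.norm(
                apply_shift(op, k1, d, warn_extrapolation=False)
                - fourier_shift(k1, d, axis)
            ) / np.linalg.norm(k1)
            for d in deltas
        ]
        out[axis_name] = float(max(errs))

    scene2 = default_scene(n=64, j=12, mb=2, snr_db=None, seed=COIL_DESIGN_SEED)
    ks = [fft2c(scene2.coils.slice(s) * scene2.objects[s]) for s in range(2)]
    ops = _mb2_operators(scene2, ks)
    nz = scene2.n_slices_total
    uz = [(p - nz // 2) / nz for p in scene2.slice_positions]
    collapsed = ks[0] + ks[1]
    errs = []
    for d in deltas:
        oracle = sum(
            ks[s] * np.exp(-2j * np.pi * d * uz[s]) for s in range(2)
        )
        shifted = apply_shift(ops["slice"], collapsed, d,
                              warn_extrapolation=False)
        errs.append(
            np.linalg.norm(shifted - oracle) / np.linalg.norm(collapsed)
        )
    out["slice"] = float(max(errs))
    return out


def operator_algebra_errors(n_pairs: int = 16, seed: int = 0) -> dict:
    """Exactness of the operator algebra: G^0 = I, semigroup
    G^a G^b = G^{a+b}, and shift-then-inverse data restoration."""
    scene = default_scene(n=64, j=12, mb=1, snr_db=None, seed=COIL_DESIGN_SEED)
    k = fft2c(scene.coils.slice(0) * scene.objects[0])
    gy = train_operator(k, "phase")
    rng = np.random.default_rng(seed)
    identity_err = float(
        np.linalg.norm(fractional_power(gy, 0) - np.eye(12))
    )
    semigroup = 0.0
    for _ in range(n_pairs):
        a, b = rng.uniform(-1, 1, size=2)
        lhs = fractional_power(gy, a) @ fractional_power(gy, b)
        rhs = fractional_power(gy, a + b)
        semigroup = max(
            semigroup,
            float(np.linalg.norm(lhs - rhs) / max(np.linalg.norm(rhs), 1.0)),
        )
    back = apply_shift(gy, apply_shift(gy, k, 0.6, False), -0.6, False)
    inverse_restore = float(np.linalg.norm(back - k) / np.linalg.norm(k))
    return {
        "identity_error": identity_err,
        "semigroup_error": semigroup,
        "inverse_restore_error": inverse_restore,
    }


# ----------------------------------------------------------------------
# coefficient recovery


def coefficient_recovery_study(
    n_draws: int = 50, snr_db: float = 30.0, seed: int = 0
) -> dict:
    """Seeded ensemble of known-(c,d) navigators at SNR ``snr_db``:
    recovery error statistics plus the noiseless self-consistency error."""
    scene_clean = default_scene(n=64, j=12, mb=2, snr_db=None,
                                seed=COIL_DESIGN_SEED)
    ks = [
        fft2c(scene_clean.coils.slice(s) * scene_clean.objects[s])
        for s in range(2)
    ]
    ops = _mb2_operators(scene_clean, ks)
    fov = np.array(scene_clean.fov)
    esp = scene_clean.echo_spacing

    # noiseless self-consistency
    d0 = np.array([0.03, -0.05, 0.02])
    ref0 = _collapsed_nav(scene_clean, FieldModel())
    nav0 = _collapsed_nav(scene_clean, FieldModel(gradient=tuple(d0 / (esp * fov))))
    res0 = OffResonanceModel(nav0, ref0, ops).fit()
    noiseless_err = float(np.max(np.abs(res0.d - d0)))

    scene = default_scene(n=64, j=12, mb=2, snr_db=snr_db,
                          seed=COIL_DESIGN_SEED)
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_draws):
        d_true = rng.uniform(-0.1, 0.1, size=3)
        field = FieldModel(gradient=tuple(d_true / (esp * fov)))
        ref = _collapsed_nav(scene, FieldModel(), rng)
        nav = _collapsed_nav(scene, field, rng)
        res = OffResonanceModel(nav, ref, ops).fit()
        errors.append(res.d - d_true)
    errors = np.asarray(errors)
    return {
        "median_abs_error": float(np.median(np.abs(errors))),
        "var_dx": float(np.var(errors[:, 0])),
        "var_dy": float(np.var(errors[:, 1])),
        "noiseless_error": noiseless_err,
        "n_draws": n_draws,
    }


# ----------------------------------------------------------------------
# shim sweep


def shim_sweep_study(seed: int = 0, snr_db: float = 30.0) -> dict:
    """Emulated manual shim manipulation: linear x/y/z gradients swept
    -20..+20 uT/m in 5 uT/m steps, estimated from navigators only."""
    scene = default_scene(n=64, j=12, mb=2, snr_db=snr_db,
                          seed=COIL_DESIGN_SEED)
    ks = [
        fft2c(scene.coils.slice(s) * scene.objects[s]) for s in range(2)
    ]
    ops = _mb2_operators(scene, ks)
    rng = np.random.default_rng(seed)
    ref = _collapsed_nav(scene, FieldModel(), rng)
    gradients = np.arange(-20.0, 20.1, 5.0)
    estimates = {"x": [], "y": [], "z": []}
    for axis, idx in (("x", 0), ("y", 1), ("z", 2)):
        for g in gradients:
            b = [0.0, 0.0, 0.0]
            b[idx] = GAMMA_BAR * g * 1e-6  # Hz/m
            nav = _collapsed_nav(scene, FieldModel(gradient=tuple(b)), rng)
            res = OffResonanceModel(nav, ref, ops).fit()
            estimates[axis].append(
                shift_to_gradient(res.d[idx], scene.echo_spacing,
                                  scene.fov[idx])
            )
    all_est = np.array([estimates[a] for a in "xyz"])
    truth = np.tile(gradients, (3, 1))
    return {
        "gradients_uT_per_m": gradients.tolist(),
        "estimates": {a: list(map(float, estimates[a])) for a in "xyz"},
        "mae_uT_per_m": float(np.mean(np.abs(all_est - truth))),
        "monotone": bool(np.all(np.diff(all_est, axis=1) > 0)),
    }


# ----------------------------------------------------------------------
# end-to-end corrupted series


def corrupted_series_study(
    n_frames: int = 50,
    seed: int = 0,
    field_std_hz: float = 20.0,
    snr_db: float = 30.0,
    refine: bool = True,
) -> dict:
    """The retrospective-corruption experiment: an MB=2 / R=2 series with
    random 0 +/- ``field_std_hz`` linear perturbations per frame, then
    reconstruction without correction, with correction, and (optionally)
    with the dy refinement step."""
    scene = default_scene(n=64, j=12, mb=2, r_factor=2, snr_db=snr_db,
                          seed=COIL_DESIGN_SEED)
    scene.seed = int(seed)  # measurement-noise stream
    schedule = PerturbationSchedule.draw(
        n_frames, scene, field_std_hz=field_std_hz, seed=seed + 1
    )
    dataset = simulate.make_series(scene, schedule)
    pipe = ReconPipeline(dataset)
    refs = pipe.reference_images
    brain = np.stack([
        ~background_mask_from_reference(refs[s]) for s in range(2)
    ])

    ent_u, ent_c = [], []
    nr_u, nr_c, nr_r = [], [], []
    series_u, series_c = [], []
    for p in range(1, n_frames):
        frame, nav = dataset.frames[p], dataset.navigators[p]
        img_u, _ = pipe.recon_frame(frame, nav, correct=False)
        img_c, _ = pipe.recon_frame(frame, nav, correct=True)
        ent_u.append(np.mean([image_entropy(img_u[s]) for s in range(2)]))
        ent_c.append(np.mean([image_entropy(img_c[s]) for s in range(2)]))
        nr_u.append(np.mean([nrmse(img_u[s], refs[s]) for s in range(2)]))
        nr_c.append(np.mean([nrmse(img_c[s], refs[s]) for s in range(2)]))
        series_u.append(img_u)
        series_c.append(img_c)
        if refine:
            img_r, _ = pipe.recon_frame(frame, nav, correct=True, refine=True)
            nr_r.append(np.mean([nrmse(img_r[s], refs[s]) for s in range(2)]))

    ent_u, ent_c = np.array(ent_u), np.array(ent_c)
    nr_u, nr_c = np.array(nr_u), np.array(nr_c)
    out = {
        "n_frames": n_frames,
        "entropy_reduced_fraction": float(np.mean(ent_c < ent_u)),
        "mean_entropy_uncorrected_bits": float(ent_u.mean()),
        "mean_entropy_corrected_bits": float(ent_c.mean()),
        "mean_nrmse_uncorrected_pct": float(100 * nr_u.mean()),
        "mean_nrmse_corrected_pct": float(100 * nr_c.mean()),
        "nrmse_relative_reduction_pct": float(
            100 * (1 - nr_c.mean() / nr_u.mean())
        ),
    }
    if refine:
        out["mean_nrmse_refined_pct"] = float(100 * np.mean(nr_r))
    _, s_u = tsnr(np.abs(np.stack(series_u)), brain)
    _, s_c = tsnr(np.abs(np.stack(series_c)), brain)
    out["tsnr_uncorrected"] = s_u["mean"]
    out["tsnr_corrected"] = s_c["mean"]
    return out


# ----------------------------------------------------------------------
# artifact-power ordering


def artifact_power_sweep(
    scales_hz=(0.0, 10.0, 20.0, 40.0), seed: int = 0, n_frames: int = 12
) -> dict:
    """Uncorrected split-slice recon artifact power vs field scale, plus
    clean-separation fidelity at zero perturbation (MB=2, R=1).

    Each level averages ``n_frames`` independent perturbation draws at
    that level's field std: the ordering is a population property (the
    background footprint of a single draw's ghost geometry is noisy,
    especially between the 20 and 40 Hz levels).
    """
    scene = default_scene(n=64, j=12, mb=2, r_factor=1, snr_db=None,
                          seed=COIL_DESIGN_SEED)
    zero = PerturbationSchedule.draw(
        2, scene, field_std_hz=0.0, seed=seed + 2
    )
    dataset0 = simulate.make_series(scene, zero)
    pipe = ReconPipeline(dataset0)
    refs = pipe.reference_images
    masks = [background_mask_from_reference(refs[s]) for s in range(2)]

    sep = [
        nrmse(img, refs[s])
        for s, img in enumerate(
            pipe.recon_frame(dataset0.frames[1], dataset0.navigators[1],
                             correct=False)[0]
        )
    ]

    powers = []
    for level, scale in enumerate(scales_hz):
        schedule = PerturbationSchedule.draw(
            n_frames + 1, scene, field_std_hz=max(scale, 1.0),
            seed=seed + 20 + level,
        )
        if scale == 0.0:
            schedule = schedule.scaled(0.0)
        ds = simulate.make_series(scene, schedule)
        total = 0.0
        for p in range(1, n_frames + 1):
            imgs, _ = pipe.recon_frame(ds.frames[p], ds.navigators[p],
                                       correct=False)
            total += sum(
                artifact_power(imgs[s], masks[s]) for s in range(2)
            )
        powers.append(total / n_frames)
    return {
        "scales_hz": list(scales_hz),
        "artifact_power": [float(p) for p in powers],
        "monotone_nondecreasing": bool(np.all(np.diff(powers) >= 0)),
        "separation_nrmse_pct": float(100 * max(sep)),
    }


# ----------------------------------------------------------------------
# metric closed forms


def metric_closed_forms(seed: int = 0) -> dict:
    """Analytic sanity values of the quality metrics."""
    delta_img = np.zeros((64, 64))
    delta_img[10, 20] = 3.0
    uniform = np.ones((64, 64))
    rng = np.random.default_rng(seed)
    ref = rng.random((32, 32)) + 0.5
    frames = 10.0 + rng.normal(0.0, 0.5, size=(200, 24, 24))
    _, summary = tsnr(frames)
    return {
        "entropy_delta_bits": float(image_entropy(delta_img)),
        "entropy_uniform_bits": float(image_entropy(uniform)),
        "entropy_uniform_expected_bits": float(np.log2(uniform.size)),
        "nrmse_self": float(nrmse(ref, ref)),
        "tsnr_measured": float(summary["mean"]),
        "tsnr_expected": 20.0,
    }
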