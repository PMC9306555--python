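"""Synthetic accelerated-EPI scanner for end-to-end exercise of the method.

Emulates everything the estimation/correction chain needs without any
scanner data: a Shepp-Logan-like digital phantom with deliberately
asymmetric features (so FOV/2 ghosts are detectable), smooth complex
coil sensitivities, EPI encoding with the 3-line reference navigator,
spatially linear time-varying off-resonance, multifrequency-
interpolation warping, CAIPI SMS collapsing, in-plane undersampling and
complex Gaussian noise.  All randomness is seeded; identical seeds give
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .containers import MultiChannelKSpace, NavigatorSet, RawDataset
from .errors import ValidationError
from .estimation import FieldModel
from .fourier import centered_coords, fft2c
from .recon import caipi_phases

__all__ = [
    "CoilProfileSet",
    "PhantomScene",
    "EpiTrajectory",
    "PerturbationSchedule",
    "make_coil_profiles",
    "shepp_logan_object",
    "encode_epi",
    "warp_multifrequency",
    "collapse_sms",
    "make_series",
    "default_scene",
]


# ----------------------------------------------------------------------
# phantom

# modified Shepp-Logan ellipses: (a, b, x0, y0, phi_deg, intensity)
_SHEPP_LOGAN = [
    (0.69, 0.92, 0.0, 0.0, 0.0, 1.0),
    (0.6624, 0.874, 0.0, -0.0184, 0.0, -0.8),
    (0.11, 0.31, 0.22, 0.0, -18.0, -0.2),
    (0.16, 0.41, -0.22, 0.0, 18.0, -0.2),
    (0.21, 0.25, 0.0, 0.35, 0.0, 0.1),
    (0.046, 0.046, 0.0, 0.1, 0.0, 0.1),
    (0.046, 0.046, 0.0, -0.1, 0.0, 0.1),
    (0.046, 0.023, -0.08, -0.605, 0.0, 0.1),
    (0.023, 0.023, 0.0, -0.606, 0.0, 0.1),
    (0.046, 0.023, 0.06, -0.605, 90.0, 0.1),
    # asymmetric bright feature: breaks left-right symmetry so that
    # FOV/2 ghost replicas are unambiguous in the background
    (0.12, 0.08, 0.45, 0.25, 20.0, 0.45),
]


def _render_ellipses(n: int, ellipses, scale: float, rotate_deg: float) -> np.ndarray:
    u = centered_coords(n) * 2.0  # [-1, 1) coordinates
    x, y = np.meshgrid(u, u, indexing="ij")
    rot = np.deg2rad(rotate_deg)
    xr = x * np.cos(rot) + y * np.sin(rot)
    yr = -x * np.sin(rot) + y * np.cos(rot)
    img = np.zeros((n, n))
    for a, b, x0, y0, phi, val in ellipses:
        t = np.deg2rad(phi)
        xs = (xr / scale) - x0
        ys = (yr / scale) - y0
        xe = xs * np.cos(t) + ys * np.sin(t)
        ye = -xs * np.sin(t) + ys * np.cos(t)
        img[(xe / a) ** 2 + (ye / b) ** 2 <= 1.0] += val
    return img


def shepp_logan_object(n: int, slice_index: int = 0, scale: float = 0.65) -> np.ndarray:
    """Complex Shepp-Logan-like phantom slice on an ``n x n`` grid.

    The support stays strictly inside ``scale`` of the FOV, leaving a
    background ring for artifact-power masks.  Slices are rotated copies
    (8 degrees per slice) so simultaneously excited slices are distinct,
    and a smooth low-order phase makes the object genuinely complex.
    """
    mag = np.clip(_render_ellipses(n, _SHEPP_LOGAN, scale, 8.0 * slice_index), 0, None)
    u = centered_coords(n)
    x, y = np.meshgrid(u, u, indexing="ij")
    phase = 0.4 + 2.0 * x - 1.2 * y + 1.5 * (x**2 + y * x)
    return mag * np.exp(1j * phase)


# ----------------------------------------------------------------------
# coils


@dataclass
class CoilProfileSet:
    """Smooth complex receive sensitivities, ``profiles`` = (J, nz, N, N)."""

    profiles: np.ndarray
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_slices(self) -> int:
        return self.profiles.shape[1]

    def slice(self, s: int) -> np.ndarray:
        return self.profiles[:, s]


def make_coil_profiles(
    j: int, n: int, nz: int = 1, seed: int = 0
) -> CoilProfileSet:
    """Gaussian-modulated complex coil profiles with per-channel phase ramps.

    Channels sit on a ring around the FOV with distinct linear phase
    ramps along all axes (including slice), giving the spatial encoding
    power the shift operators need; the set is sum-of-squares normalized
    to 1 everywhere.  J = 1 is allowed for pure forward simulation but
    cannot train operators.
    """
    if j < 1:
        raise ValidationError("need at least one channel")
    rng = np.random.default_rng(seed)
    u = centered_coords(n)
    x, y = np.meshgrid(u, u, indexing="ij")
    zu = centered_coords(nz)
    profiles = np.empty((j, nz, n, n), dtype=complex)
    for c in range(j):
        theta = 2 * np.pi * c / j + rng.uniform(-0.2, 0.2)
        cx, cy = 0.38 * np.cos(theta), 0.38 * np.sin(theta)
        sigma = 0.5 * (1 + rng.uniform(-0.1, 0.1))
        amp2d = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2)))
        # mild in-plane linear phase ramps: enough encoding power for the
        # shift operators without widening the coil k-space kernels
        ax, ay = rng.uniform(-2, 2, size=2)
        # slice-direction phase spread over the full circle across channels
        # plus (x,y)-dependent cross terms, so channel vectors at different
        # slice positions are genuinely distinct (slice-axis encoding)
        az = 4 * np.pi * c / j + rng.uniform(-0.3, 0.3)
        bzx, bzy = rng.uniform(-4, 4, size=2)
        phi0 = rng.uniform(-np.pi, np.pi)
        for s in range(nz):
            gain = 1.0 + 0.5 * np.cos(2 * np.pi * zu[s] + theta)
            zphase = (az + bzx * x + bzy * y) * zu[s]
            profiles[c, s] = (
                gain * amp2d * np.exp(1j * (ax * x + ay * y + zphase + phi0))
            )
    sos = np.sqrt(np.sum(np.abs(profiles) ** 2, axis=0, keepdims=True))
    profiles /= sos
    return CoilProfileSet(profiles=profiles, seed=seed)


# ----------------------------------------------------------------------
# scene / trajectory


@dataclass
class EpiTrajectory:
    """EPI line ordering and timing.

    Lines are acquired bottom-up in ky; the acquired line with counter
    ``m`` is sampled at echo index ``first_imaging_echo + m``.  The
    three navigator lines sample ky = 0 at echo indices 1, 2, 3 (echo
    spacing apart), before the imaging train.  ``ghost_phi0/1`` inject
    an odd/even readout-polarity phase discrepancy (radians, radians per
    readout sample) on even-echo lines.
    """

    n_ky: int
    echo_spacing: float
    r_factor: int = 1
    nav_echoes: tuple = (1, 2, 3)
    first_imaging_echo: int = 4
    ghost_phi0: float = 0.0
    ghost_phi1: float = 0.0

    @property
    def acquired_ky(self) -> np.ndarray:
        return np.arange(0, self.n_ky, self.r_factor)

    @property
    def line_times(self) -> np.ndarray:
        """Seconds per ky line, nan on unacquired lines."""
        t = np.full(self.n_ky, np.nan)
        acq = self.acquired_ky
        t[acq] = (self.first_imaging_echo + np.arange(len(acq))) * self.echo_spacing
        return t

    @property
    def nav_times(self) -> np.ndarray:
        return np.asarray(self.nav_echoes, dtype=float) * self.echo_spacing


@dataclass
class PhantomScene:
    """Everything needed to simulate one acquisition.

    ``objects`` is ``(nz, N, N)`` complex magnetization per slice;
    ``slice_positions`` are the encoded plane indices of the excited
    slices within the ``n_slices_total`` stack (they set each slice's z
    coordinate and the kz encoding of the CAIPI/slice axis).
    """

    objects: np.ndarray
    coils: CoilProfileSet
    fov: tuple = (0.192, 0.192, 0.02)
    echo_spacing: float = 0.5e-3
    noise_sigma: float = 0.0
    seed: int = 0
    slice_positions: tuple = (0,)
    n_slices_total: int = 1
    trajectory: EpiTrajectory = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.objects = np.asarray(self.objects, dtype=complex)
        if self.objects.ndim == 2:
            self.objects = self.objects[None]
        if self.coils.n_channels < 1:
            raise ValidationError("scene needs at least one coil")
        if self.trajectory is None:
            self.trajectory = EpiTrajectory(
                n_ky=self.objects.shape[-1], echo_spacing=self.echo_spacing
            )

    @property
    def n(self) -> int:
        return self.objects.shape[-1]

    @property
    def n_slices(self) -> int:
        return self.objects.shape[0]

    def grid_m(self):
        """(x, y) meshgrid in meters."""
        ux = centered_coords(self.n) * self.fov[0]
        uy = centered_coords(self.n) * self.fov[1]
        return np.meshgrid(ux, uy, indexing="ij")

    def slice_z_m(self, s: int) -> float:
        """z coordinate (meters) of excited slice ``s``."""
        nz = self.n_slices_total
        pos = self.slice_positions[s]
        return (pos - nz // 2) / nz * self.fov[2]

    def support_mask(self, s: int = 0, rel_threshold: float = 0.05) -> np.ndarray:
        mag = np.abs(self.objects[s])
        return mag > rel_threshold * mag.max()


def default_scene(
    n: int = 64,
    j: int = 12,
    mb: int = 2,
    n_slices_total: int | None = None,
    fov: float = 0.192,
    slice_fov: float = 0.02,
    echo_spacing: float = 0.5e-3,
    snr_db: float | None = 30.0,
    r_factor: int = 1,
    seed: int = 0,
    ghost_phi0: float = 0.0,
    ghost_phi1: float = 0.0,
) -> PhantomScene:
    """The standard synthetic scene: 64x64, J=12, MB=2, 20 ms slice FOV.

    ``snr_db`` sets the complex-noise std relative to the RMS magnitude
    of the clean fully sampled k-space of the collapsed slice group
    (None = noiseless).
    """
    if n_slices_total is None:
        n_slices_total = 2 * mb
    # excited slices centered within the stack (symmetric about the z
    # origin), keeping slice-operator eigenvalues away from the branch cut
    step = n_slices_total // mb
    positions = tuple(s * step + step // 2 for s in range(mb))
    coils = make_coil_profiles(j, n, nz=n_slices_total, seed=seed)
    objects = np.stack([shepp_logan_object(n, s) for s in range(mb)])
    coil_sub = CoilProfileSet(
        profiles=coils.profiles[:, list(positions)], seed=seed
    )
    traj = EpiTrajectory(
        n_ky=n, echo_spacing=echo_spacing, r_factor=r_factor,
        ghost_phi0=ghost_phi0, ghost_phi1=ghost_phi1,
    )
    scene = PhantomScene(
        objects=objects, coils=coil_sub,
        fov=(fov, fov, slice_fov), echo_spacing=echo_spacing,
        seed=seed, slice_positions=positions,
        n_slices_total=n_slices_total, trajectory=traj,
    )
    if snr_db is not None:
        ref = sum(
            fft2c(scene.coils.slice(s) * scene.objects[s])
            for s in range(mb)
        )
        scene.noise_sigma = float(
            np.sqrt(np.mean(np.abs(ref) ** 2)) * 10 ** (-snr_db / 20)
        )
    return scene


# ----------------------------------------------------------------------
# encoding


def _ghost_ramp(traj: EpiTrajectory, n: int) -> np.ndarray:
    x = np.arange(n) - n // 2
    return np.exp(1j * (traj.ghost_phi0 + traj.ghost_phi1 * x))


def encode_epi(
    scene: PhantomScene,
    field: FieldModel,
    slice_index: int = 0,
    trajectory: EpiTrajectory | None = None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Discrete evaluation of the EPI signal equation for one slice.

    For every line at time ``t`` the object is modulated by
    ``exp(-2j pi f(r) t)`` (``f`` the field in Hz, including the slice's
    z offset) and Fourier-encoded; the three navigator lines are ky = 0
    lines at the navigator echo times.  Complex Gaussian noise of std
    ``scene.noise_sigma`` is added to every sampled point.  Deterministic
    given the generator state.
    """
    traj = trajectory or scene.trajectory
    n = scene.n
    img = scene.coils.slice(slice_index) * scene.objects[slice_index]
    x, y = scene.grid_m()
    z = scene.slice_z_m(slice_index)
    fmap = field.evaluate((x, y, z))
    # peak-to-peak field over the FOV times the latest line time bounds the
    # k-space shift in samples; beyond half the grid it aliases
    f_span = float(fmap.max() - fmap.min())
    t_max = float(np.nanmax(traj.line_times))
    if f_span * t_max > n / 2:
        import warnings

        warnings.warn("off-resonance shift exceeds the Nyquist range",
                      RuntimeWarning, stacklevel=2)

    ghost = _ghost_ramp(traj, n)[:, None]  # along readout (x)
    acq = traj.acquired_ky
    times = traj.line_times
    data = np.zeros((scene.coils.n_channels, n, n), dtype=complex)
    for m, ky in enumerate(acq):
        t = times[ky]
        echo = traj.first_imaging_echo + m
        mod = img * np.exp(-2j * np.pi * fmap * t)
        if echo % 2 == 0:
            mod = mod * ghost
        data[:, :, ky] = fft2c(mod)[:, :, ky]

    nav_lines = np.zeros((3, scene.coils.n_channels, n), dtype=complex)
    for i, l in enumerate(traj.nav_echoes):
        t = l * scene.echo_spacing
        mod = img * np.exp(-2j * np.pi * fmap * t)
        if l % 2 == 0:
            mod = mod * ghost
        nav_lines[i] = fft2c(mod)[:, :, n // 2]

    if scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        s = scene.noise_sigma / np.sqrt(2)
        mask_cols = np.zeros(n, dtype=bool)
        mask_cols[acq] = True
        noise = rng.normal(scale=s, size=(2, *data.shape))
        data[:, :, mask_cols] += (noise[0] + 1j * noise[1])[:, :, mask_cols]
        nnav = rng.normal(scale=s, size=(2, *nav_lines.shape))
        nav_lines += nnav[0] + 1j * nnav[1]

    mask = np.zeros(n, dtype=bool)
    mask[acq] = True
    frame = MultiChannelKSpace(
        data=data, mask=mask, echo_spacing=scene.echo_spacing,
        fov=scene.fov, line_times=times,
    )
    nav = NavigatorSet(lines=nav_lines, line_echo_times=traj.nav_times)
    return frame, nav


# ----------------------------------------------------------------------
# multifrequency-interpolation warping


def warp_multifrequency(
    images: np.ndarray,
    fmap: np.ndarray,
    line_times: np.ndarray,
    n_freq_bins: int = 9,
    weights: str = "ls",
) -> np.ndarray:
    """Retrospectively warp per-channel images by a field via
    multifrequency interpolation.

    The corrupted k-space is approximated as a weighted combination of a
    few demodulated encodings at bin frequencies ``f_i``: each pixel's
    phase history ``exp(-2j pi f(r) t_n)`` over the acquired line times
    is expanded on the basis ``exp(-2j pi f_i t_n)``, the per-bin
    weighted images are Fourier-encoded, phased per line, and summed.
    Converges to the direct signal-equation evaluation as the bin count
    grows.

    Parameters
    ----------
    images
        Per-channel complex images ``(J, N, N)``.
    fmap
        Field in Hz over the grid ``(N, N)``.
    line_times
        Seconds per ky line (nan on unacquired lines -> left zero).
    weights
        ``"ls"`` (default) solves the per-pixel expansion coefficients
        by least squares over the actual line times (the standard MFI
        coefficient choice, accurate at small bin counts); ``"linear"``
        uses pixelwise linear interpolation of ``f(r)`` between
        neighboring bins (simpler, needs more bins).

    Returns
    -------
    Corrupted k-space ``(J, N, N)``.
    """
    images = np.asarray(images, dtype=complex)
    fmap = np.asarray(fmap, dtype=float)
    fmin, fmax = float(fmap.min()), float(fmap.max())
    uniform = np.isclose(fmin, fmax)
    if n_freq_bins < 2 and not uniform:
        raise ValidationError("need >= 2 frequency bins for a nonuniform field")
    times = np.asarray(line_times, dtype=float)
    acquired = np.isfinite(times)
    if uniform:
        centers = np.array([0.5 * (fmin + fmax)])
        wmaps = np.ones((1,) + fmap.shape)
    else:
        centers = np.linspace(fmin, fmax, n_freq_bins)
        if weights == "ls":
            # per-pixel LS fit of exp(-2i pi f t_n) on the bin basis
            t = times[acquired]
            basis = np.exp(-2j * np.pi * t[:, None] * centers[None, :])
            target = np.exp(-2j * np.pi * t[:, None] * fmap.ravel()[None, :])
            coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
            wmaps = coef.reshape(n_freq_bins, *fmap.shape)
        elif weights == "linear":
            width = centers[1] - centers[0]
            wmaps = np.stack([
                np.clip(1.0 - np.abs(fmap - fc) / width, 0.0, None)
                for fc in centers
            ])
        else:
            raise ValidationError("weights must be 'ls' or 'linear'")
    kbins = np.stack([fft2c(w * images) for w in wmaps])  # (B, J, N, N)
    out = np.zeros_like(images)
    for ky, t in enumerate(times):
        if not np.isfinite(t):
            continue
        phases = np.exp(-2j * np.pi * centers * t)  # (B,)
        out[:, :, ky] = np.tensordot(phases, kbins[:, :, :, ky], axes=(0, 0))
    return out


# ----------------------------------------------------------------------
# SMS collapsing


def collapse_sms(frames, navs, caipi_shift) -> tuple:
    """CAIPI-phase and sum per-slice frames (and plain-sum their navigators)."""
    shapes = {f.data.shape for f in frames}
    if len(shapes) != 1:
        raise ValidationError("slice geometries differ")
    base = frames[0]
    acq = base.acquired_ky
    phases = caipi_phases(caipi_shift, len(acq), len(frames))
    data = np.zeros_like(base.data)
    for s, f in enumerate(frames):
        contrib = f.data.copy()
        contrib[:, :, acq] *= phases[s][None, None, :]
        data += contrib
    out = MultiChannelKSpace(
        data=data, mask=base.mask.copy(), echo_spacing=base.echo_spacing,
        fov=base.fov, line_times=None if base.line_times is None
        else base.line_times.copy(),
        caipi_shift=np.atleast_1d(np.asarray(caipi_shift, dtype=int)),
    )
    nav_lines = np.sum([n.lines for n in navs], axis=0)
    nav = NavigatorSet(
        lines=nav_lines, line_echo_times=navs[0].line_echo_times.copy(),
        frame_index=navs[0].frame_index, slice_group=navs[0].slice_group,
    )
    return out, nav


# ----------------------------------------------------------------------
# perturbation schedule + full series


@dataclass
class PerturbationSchedule:
    """Per-frame, per-slice-group linear field perturbation draws.

    Frame 0 is the unperturbed reference.  The per-axis gradient std is
    chosen so that the expected std of the field across the FOV equals
    ``field_std_hz`` (spread equally over the active axes).
    """

    fields: list  # fields[p][g] -> FieldModel
    field_std_hz: float = 20.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.fields)

    @classmethod
    def draw(
        cls,
        n_frames: int,
        scene: PhantomScene,
        field_std_hz: float = 20.0,
        axes: tuple = ("x", "y", "z"),
        n_groups: int = 1,
        seed: int = 0,
    ) -> "PerturbationSchedule":
        active = [a for a in axes if a != "z" or scene.n_slices > 1]
        x, y = scene.grid_m()
        coord_var = {
            "x": float(np.var(x[:, 0])),
            "y": float(np.var(y[0, :])),
        }
        if scene.n_slices > 1:
            zs = np.array([scene.slice_z_m(s) for s in range(scene.n_slices)])
            coord_var["z"] = float(np.var(zs))
        active = [a for a in active if coord_var.get(a, 0.0) > 0]
        rng = np.random.default_rng(seed)
        sigma = {
            a: field_std_hz / np.sqrt(len(active)) / np.sqrt(coord_var[a])
            for a in active
        }
        fields = [[FieldModel() for _ in range(n_groups)]]
        for _ in range(1, n_frames):
            row = []
            for _ in range(n_groups):
                g = [
                    rng.normal(0.0, sigma[a]) if a in active else 0.0
                    for a in ("x", "y", "z")
                ]
                row.append(FieldModel(gradient=tuple(g)))
            fields.append(row)
        return cls(fields=fields, field_std_hz=field_std_hz, seed=seed)

    def scaled(self, factor: float) -> "PerturbationSchedule":
        return PerturbationSchedule(
            fields=[[f.scaled(factor) for f in row] for row in self.fields],
            field_std_hz=self.field_std_hz * factor, seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "field_std_hz": self.field_std_hz,
            "seed": self.seed,
            "fields": [
                [
                    {"gradient": list(f.gradient), "global_offset": f.global_offset}
                    for f in row
                ]
                for row in self.fields
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PerturbationSchedule":
        fields = [
            [FieldModel(tuple(f["gradient"]), f["global_offset"]) for f in row]
            for row in payload["fields"]
        ]
        return cls(fields=fields, field_std_hz=payload["field_std_hz"],
                   seed=payload["seed"])


def make_series(
    scene: PhantomScene,
    schedule: PerturbationSchedule,
    n_frames: int | None = None,
    caipi_shift: tuple | None = None,
) -> RawDataset:
    """Simulate a full accelerated fMRI series as a raw dataset.

    Per-slice fully sampled noiseless calibration (clean, as a FLEET-style
    calibration would be), then per-frame field-corrupted, CAIPI-collapsed,
    undersampled k-space with navigators.  The ground-truth schedule is
    stored alongside for recovery tests.
    """
    n_frames = n_frames if n_frames is not None else schedule.n_frames
    if schedule.n_frames < n_frames:
        raise ValidationError("schedule shorter than the requested series")
    mb = scene.n_slices
    if caipi_shift is None:
        caipi_shift = tuple(range(mb))

    calib_traj = EpiTrajectory(
        n_ky=scene.n, echo_spacing=scene.echo_spacing, r_factor=1
    )
    quiet = PhantomScene(
        objects=scene.objects, coils=scene.coils, fov=scene.fov,
        echo_spacing=scene.echo_spacing, noise_sigma=0.0, seed=scene.seed,
        slice_positions=scene.slice_positions,
        n_slices_total=scene.n_slices_total, trajectory=calib_traj,
    )
    calibration = [
        encode_epi(quiet, FieldModel(), s, calib_traj)[0] for s in range(mb)
    ]

    rng = np.random.default_rng(scene.seed)
    frames, navigators = [], []
    for p in range(n_frames):
        fld = schedule.fields[p][0]
        per_slice = [
            encode_epi(scene, fld, s, scene.trajectory, rng=rng) for s in range(mb)
        ]
        frame, nav = collapse_sms(
            [f for f, _ in per_slice], [n for _, n in per_slice], caipi_shift
        )
        nav.frame_index = p
        frame_obj = frame
        frame_obj.caipi_shift = np.asarray(caipi_shift, dtype=int)
        frames.append(frame_obj)
        navigators.append(nav)

    return RawDataset(
        calibration=calibration,
        frames=frames,
        navigators=navigators,
        slice_positions=tuple(scene.slice_positions),
        n_slices_total=scene.n_slices_total,
        ground_truth={
            "schedule": schedule.to_dict(),
            "noise_sigma": scene.noise_sigma,
            "fov": list(scene.fov),
            "echo_spacing": scene.echo_spacing,
        },
    )
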