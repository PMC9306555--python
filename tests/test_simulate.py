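"""The synthetic scanner: phantom, coils, EPI encoding, MFI warping,
SMS collapsing, perturbation schedules and full series generation."""

import numpy as np
import pytest

import navb0 as nb
from navb0.errors import ValidationError
from navb0.estimation import FieldModel
from navb0.fourier import fft2c, ifft2c, ifftc, centered_coords
from navb0.metrics import nrmse
from navb0.recon import root_sum_of_squares, unalias_sms, train_split_slice_grappa


class TestCoilProfiles:
    def test_sum_of_squares_normalized(self):
        coils = nb.make_coil_profiles(12, 64, nz=2, seed=3)
        sos = np.sqrt(np.sum(np.abs(coils.profiles) ** 2, axis=0))
        assert sos.min() > 0.99 and sos.max() < 1.01

    def test_channels_pairwise_distinct(self):
        coils = nb.make_coil_profiles(12, 64, seed=0)
        flat = coils.profiles.reshape(12, -1)
        flat = flat / np.linalg.norm(flat, axis=1, keepdims=True)
        gram = np.abs(flat @ flat.conj().T)
        dist = np.sqrt(np.clip(2 - 2 * gram, 0, None))
        np.fill_diagonal(dist, np.inf)
        assert dist.min() > 0.1

    def test_single_channel_allowed_for_forward_simulation(self):
        coils = nb.make_coil_profiles(1, 32)
        assert coils.n_channels == 1
        # but unusable for operator training
        scene_img = coils.slice(0) * nb.shepp_logan_object(32)
        with pytest.raises(ValidationError, match="coil sensitivity"):
            nb.train_operator(fft2c(scene_img), "phase")


class TestPhantom:
    def test_support_strictly_inside_fov(self):
        obj = nb.shepp_logan_object(64)
        mag = np.abs(obj)
        border = max(2, int(0.1 * 64))
        ring = np.ones((64, 64), bool)
        ring[border:-border, border:-border] = False
        assert mag[ring].max() == 0.0

    def test_slices_are_distinct(self):
        a, b = nb.shepp_logan_object(64, 0), nb.shepp_logan_object(64, 1)
        assert np.linalg.norm(a - b) / np.linalg.norm(a) > 0.05


class TestEncodeEpi:
    def test_zero_field_roundtrips_to_coil_weighted_object(self, scene_mb1):
        frame, _ = nb.encode_epi(scene_mb1, FieldModel(), 0)
        img = ifft2c(frame.data)
        truth = scene_mb1.coils.slice(0) * scene_mb1.objects[0]
        assert np.linalg.norm(img - truth) < 1e-8 * np.linalg.norm(truth)

    def test_constant_field_is_pure_per_line_phase(self, scene_mb1):
        clean, _ = nb.encode_epi(scene_mb1, FieldModel(), 0)
        shifted, _ = nb.encode_epi(scene_mb1, FieldModel(global_offset=40.0), 0)
        acq = clean.acquired_ky
        t = clean.line_times[acq]
        expected = clean.data[:, :, acq] * np.exp(
            -2j * np.pi * 40.0 * t
        )[None, None, :]
        assert np.allclose(shifted.data[:, :, acq], expected)
        assert np.allclose(np.abs(shifted.data), np.abs(clean.data))

    def test_linear_field_shifts_navigator_lines(self, scene_mb1):
        """Line l moves by b*fov*t_l samples; checked against a sub-sample
        cross-correlation (phase-slope) estimate on the hybrid projection."""
        d = 0.15  # samples per echo along readout
        b = d / (scene_mb1.echo_spacing * scene_mb1.fov[0])
        _, nav0 = nb.encode_epi(scene_mb1, FieldModel(), 0)
        _, nav = nb.encode_epi(scene_mb1, FieldModel(gradient=(b, 0, 0)), 0)
        m = nav.n_readout
        u = centered_coords(m)
        for l in range(3):
            a = ifftc(nav.lines[l], (1,))
            r = ifftc(nav0.lines[l], (1,))
            xprod = np.sum(a * np.conj(r), axis=0)
            w = np.abs(xprod)
            slope = np.polyfit(u, np.unwrap(np.angle(xprod)), 1, w=w)[0]
            measured = -slope / (2 * np.pi)
            assert measured == pytest.approx(d * (l + 1), abs=0.01)

    def test_deterministic_given_seed(self, scene_series):
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        f1, n1 = nb.encode_epi(scene_series, FieldModel(), 0, rng=rng1)
        f2, n2 = nb.encode_epi(scene_series, FieldModel(), 0, rng=rng2)
        assert np.array_equal(f1.data, f2.data)
        assert np.array_equal(n1.lines, n2.lines)


class TestMultifrequencyWarp:
    @pytest.fixture(scope="class")
    def warp_setup(self, scene_mb1):
        img = scene_mb1.coils.slice(0) * scene_mb1.objects[0]
        traj = scene_mb1.trajectory
        # a 0 +/- 20 Hz-scale linear field
        field = FieldModel(gradient=(250.0, -300.0, 0.0))
        x, y = scene_mb1.grid_m()
        fmap = field.evaluate((x, y, 0.0))
        direct, _ = nb.encode_epi(scene_mb1, field, 0)
        return img, fmap, traj.line_times, direct.data

    def test_uniform_field_single_bin_exact(self, scene_mb1):
        img = scene_mb1.coils.slice(0) * scene_mb1.objects[0]
        times = scene_mb1.trajectory.line_times
        fmap = np.full((64, 64), 17.0)
        out = nb.warp_multifrequency(img, fmap, times, n_freq_bins=1)
        direct, _ = nb.encode_epi(scene_mb1, FieldModel(global_offset=17.0), 0)
        assert np.linalg.norm(out - direct.data) < 1e-10 * np.linalg.norm(
            direct.data
        )

    def test_nine_bins_within_one_percent_of_direct(self, warp_setup):
        img, fmap, times, direct = warp_setup
        out = nb.warp_multifrequency(img, fmap, times, n_freq_bins=9)
        assert np.linalg.norm(out - direct) / np.linalg.norm(direct) < 0.01

    def test_more_bins_monotonically_better(self, warp_setup):
        img, fmap, times, direct = warp_setup
        errs = [
            np.linalg.norm(
                nb.warp_multifrequency(img, fmap, times, n_freq_bins=nb_)
                - direct
            )
            for nb_ in (4, 8, 16)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_nonuniform_field_needs_two_bins(self, warp_setup):
        img, fmap, times, _ = warp_setup
        with pytest.raises(ValidationError):
            nb.warp_multifrequency(img, fmap, times, n_freq_bins=1)


class TestCollapseSms:
    def test_single_slice_collapse_is_identity(self, scene_mb2):
        f, n = nb.encode_epi(scene_mb2, FieldModel(), 0)
        collapsed, nav = nb.collapse_sms([f], [n], (0,))
        assert np.array_equal(collapsed.data, f.data)
        assert np.array_equal(nav.lines, n.lines)

    def test_collapsed_energy_bounded_by_sum(self, scene_mb2):
        frames, navs = zip(*[
            nb.encode_epi(scene_mb2, FieldModel(), s) for s in range(2)
        ])
        collapsed, _ = nb.collapse_sms(list(frames), list(navs), (0, 1))
        assert np.linalg.norm(collapsed.data) <= (
            np.linalg.norm(frames[0].data) + np.linalg.norm(frames[1].data)
        ) * (1 + 1e-12)

    def test_collapse_then_unalias_roundtrips(self, scene_mb2, ks_mb2):
        frames, navs = zip(*[
            nb.encode_epi(scene_mb2, FieldModel(), s) for s in range(2)
        ])
        collapsed, _ = nb.collapse_sms(list(frames), list(navs), (0, 1))
        kernels = train_split_slice_grappa(ks_mb2, (0, 1), np.arange(64))
        slices = unalias_sms(collapsed, kernels)
        for s in range(2):
            ref = root_sum_of_squares(ifft2c(ks_mb2[s]))
            got = root_sum_of_squares(ifft2c(slices[s].data))
            assert nrmse(got, ref) < 0.03

    def test_geometry_mismatch_rejected(self, scene_mb2):
        f, n = nb.encode_epi(scene_mb2, FieldModel(), 0)
        small = nb.MultiChannelKSpace(
            data=f.data[:, :32, :32], mask=f.mask[:32],
            echo_spacing=f.echo_spacing, fov=f.fov,
        )
        with pytest.raises(ValidationError):
            nb.collapse_sms([f, small], [n, n], (0, 1))


class TestPerturbationSchedule:
    def test_frame_zero_unperturbed(self, scene_series):
        sched = nb.PerturbationSchedule.draw(5, scene_series, seed=4)
        assert sched.fields[0][0].gradient == (0.0, 0.0, 0.0)

    def test_field_std_matches_target_within_ten_percent(self, scene_series):
        """RMS of the field over the FOV across draws ~ 20 Hz."""
        sched = nb.PerturbationSchedule.draw(
            400, scene_series, field_std_hz=20.0, seed=8
        )
        x, y = scene_series.grid_m()
        zs = [scene_series.slice_z_m(s) for s in range(2)]
        stds = []
        for row in sched.fields[1:]:
            f = row[0]
            vals = np.concatenate([
                f.evaluate((x, y, z)).ravel() for z in zs
            ])
            stds.append(np.std(vals))
        rms = np.sqrt(np.mean(np.square(stds)))
        assert abs(rms - 20.0) / 20.0 < 0.10

    def test_draws_reproducible_and_json_roundtrip(self, scene_series):
        a = nb.PerturbationSchedule.draw(4, scene_series, seed=13)
        b = nb.PerturbationSchedule.draw(4, scene_series, seed=13)
        assert a.to_dict() == b.to_dict()
        back = nb.PerturbationSchedule.from_dict(a.to_dict())
        assert back.fields[2][0].gradient == a.fields[2][0].gradient


class TestMakeSeries:
    def test_zero_schedule_frame_matches_collapsed_calibration(self,
                                                               scene_mb2):
        scene = nb.default_scene(n=64, j=12, mb=2, r_factor=1, snr_db=None,
                                 seed=0)
        sched = nb.PerturbationSchedule.draw(1, scene, field_std_hz=0.0,
                                             seed=0)
        ds = nb.make_series(scene, sched)
        from navb0.recon import caipi_phases

        acq = ds.frames[0].acquired_ky
        phases = caipi_phases((0, 1), len(acq), 2)
        predicted = sum(
            ds.calibration[s].data[:, :, acq] * phases[s][None, None, :]
            for s in range(2)
        )
        assert np.allclose(ds.frames[0].data[:, :, acq], predicted)

    def test_identical_seeds_identical_series(self, scene_series):
        sched = nb.PerturbationSchedule.draw(3, scene_series, seed=6)
        d1 = nb.make_series(scene_series, sched)
        d2 = nb.make_series(scene_series, sched)
        for p in range(3):
            assert np.array_equal(d1.frames[p].data, d2.frames[p].data)
            assert np.array_equal(d1.navigators[p].lines,
                                  d2.navigators[p].lines)

    def test_ground_truth_stored(self, small_series):
        dataset, schedule = small_series
        assert dataset.ground_truth is not None
        back = nb.PerturbationSchedule.from_dict(
            dataset.ground_truth["schedule"]
        )
        assert back.fields[3][0].gradient == schedule.fields[3][0].gradient
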