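"""Off-resonance coefficient estimation from the 3-line navigator.

Ground truth comes from the forward simulator: a linear field with
gradient ``b`` produces per-echo shift increments ``d = b * fov * esp``
per axis (offset ``c = 0`` when the field acts from excitation onward).
"""

import numpy as np
import pytest

import navb0 as nb
from navb0.errors import ValidationError
from navb0.estimation import (
    GAMMA_BAR,
    FieldModel,
    OffResonanceModel,
    gradient_to_shift,
    navigator_shift_model,
    shift_to_gradient,
)

from conftest import collapsed_navigator


def d_from_field(field, scene):
    return np.array(field.gradient) * np.array(scene.fov) * scene.echo_spacing


@pytest.fixture(scope="module")
def nav_ref(scene_mb2):
    return collapsed_navigator(scene_mb2, FieldModel())


class TestForwardModel:
    def test_zero_coefficients_reproduce_reference(self, nav_ref, ops_mb2):
        pred = navigator_shift_model((0, 0, 0), (0, 0, 0), nav_ref, ops_mb2)
        assert np.array_equal(pred.lines, nav_ref.lines)

    def test_per_line_deltas_grow_linearly(self, nav_ref, ops_mb2):
        """Line l of the prediction carries shift c + l*d exactly."""
        d = (0.0, 0.05, 0.0)
        pred = navigator_shift_model((0, 0, 0), d, nav_ref, ops_mb2)
        for l in (1, 2, 3):
            direct = nb.compose_shifts(
                ops_mb2, nav_ref.lines[l - 1], (0, 0.05 * l, 0),
                warn_extrapolation=False,
            )
            assert np.allclose(pred.lines[l - 1], direct)

    def test_prediction_matches_forward_simulation(self, scene_mb2, nav_ref,
                                                   ops_mb2):
        """Shift model vs the full signal-equation encoding of a known field."""
        d_true = np.array([0.03, -0.04, 0.01])
        field = FieldModel(gradient=tuple(
            d_true / (scene_mb2.echo_spacing * np.array(scene_mb2.fov))
        ))
        nav_p = collapsed_navigator(scene_mb2, field)
        pred = navigator_shift_model((0, 0, 0), d_true, nav_ref, ops_mb2,
                                     warn_extrapolation=False)
        err = np.linalg.norm(pred.lines - nav_p.lines) / np.linalg.norm(
            nav_p.lines
        )
        assert err < 0.05


class TestEstimation:
    def test_reference_frame_estimates_to_zero(self, nav_ref, ops_mb2):
        res = OffResonanceModel(nav_ref, nav_ref, ops_mb2).fit()
        assert np.all(np.abs(res.c) < 1e-3)
        assert np.all(np.abs(res.d) < 1e-3)

    def test_noiseless_self_consistency(self, nav_ref, ops_mb2):
        """Coefficients used to synthesize navigators are recovered < 1e-3."""
        c_true = np.array([0.01, 0.0, 0.0])
        d_true = np.array([0.02, 0.04, 0.0])
        nav_p = navigator_shift_model(c_true, d_true, nav_ref, ops_mb2)
        res = OffResonanceModel(nav_p, nav_ref, ops_mb2).fit()
        assert np.all(np.abs(res.c - c_true) < 1e-3)
        assert np.all(np.abs(res.d - d_true) < 1e-3)

    def test_known_field_recovery_with_noise(self, scene_mb2, ops_mb2):
        """d = (0.02, 0.04, 0.00), c ~ 0, SNR 30 dB: error < 0.005 samples."""
        scene = nb.default_scene(n=64, j=12, mb=2, snr_db=30.0, seed=0)
        d_true = np.array([0.02, 0.04, 0.0])
        field = FieldModel(gradient=tuple(
            d_true / (scene.echo_spacing * np.array(scene.fov))
        ))
        rng = np.random.default_rng(5)
        ref = collapsed_navigator(scene, FieldModel(), rng)
        nav = collapsed_navigator(scene, field, rng)
        res = OffResonanceModel(nav, ref, ops_mb2).fit()
        assert np.all(np.abs(res.d - d_true) < 0.005)
        assert np.all(np.abs(res.c) < 0.005)

    def test_residual_no_worse_than_null_model(self, scene_mb2, ops_mb2):
        """Fitted residual <= residual of (c, d) = 0 under perturbation."""
        field = FieldModel(gradient=(150.0, -120.0, 0.0))
        ref = collapsed_navigator(scene_mb2, FieldModel())
        nav = collapsed_navigator(scene_mb2, field)
        model = OffResonanceModel(nav, ref, ops_mb2)
        res = model.fit()
        assert res.residual <= model.residual(np.zeros(6)) + 1e-12

    def test_low_energy_navigator_flagged(self, nav_ref, ops_mb2):
        faint = nav_ref.copy()
        faint.lines = faint.lines * 1e-12
        res = OffResonanceModel(faint, nav_ref, ops_mb2,
                                noise_floor=1e-6).fit()
        assert res.low_confidence
        assert np.all(res.c == 0) and np.all(res.d == 0)

    def test_mismatched_navigators_rejected(self, nav_ref, ops_mb2):
        small = nb.NavigatorSet(
            lines=np.zeros((3, 12, 32), complex),
            line_echo_times=nav_ref.line_echo_times,
        )
        with pytest.raises(ValidationError):
            OffResonanceModel(small, nav_ref, ops_mb2)

    def test_summary_mentions_coefficients(self, nav_ref, ops_mb2):
        res = OffResonanceModel(nav_ref, nav_ref, ops_mb2).fit()
        text = res.summary()
        assert "residual" in text and "d [samples/echo]" in text


class TestRecoveryEnsemble:
    """Recovery statistics over seeded random draws at SNR 30 dB."""

    @pytest.fixture(scope="class")
    def ensemble(self, ops_mb2):
        scene = nb.default_scene(n=64, j=12, mb=2, snr_db=30.0, seed=0)
        rng = np.random.default_rng(2024)
        errors = []
        for _ in range(50):
            d_true = rng.uniform(-0.1, 0.1, size=3)
            field = FieldModel(gradient=tuple(
                d_true / (scene.echo_spacing * np.array(scene.fov))
            ))
            ref = collapsed_navigator(scene, FieldModel(), rng)
            nav = collapsed_navigator(scene, field, rng)
            res = OffResonanceModel(nav, ref, ops_mb2).fit()
            errors.append(res.d - d_true)
        return np.array(errors)

    def test_median_absolute_error_below_five_thousandths(self, ensemble):
        assert np.median(np.abs(ensemble)) < 0.005

    def test_readout_axis_more_precise_than_phase_axis(self, ensemble):
        """Navigators are fully sampled along readout, so dx beats dy."""
        assert np.var(ensemble[:, 0]) <= np.var(ensemble[:, 1])


class TestUnitConversions:
    def test_zero_maps_to_zero(self):
        assert shift_to_gradient(0.0, 5e-4, 0.192) == 0.0

    def test_closed_form_example_and_roundtrip(self):
        """5 uT/m at 0.5 ms echo spacing, 0.192 m FOV -> ~0.0204 samples."""
        d = gradient_to_shift(5.0, 5e-4, 0.192)
        assert d == pytest.approx(GAMMA_BAR * 5e-6 * 5e-4 * 0.192)
        assert d == pytest.approx(0.02044, abs=2e-4)
        assert shift_to_gradient(d, 5e-4, 0.192) == pytest.approx(5.0)

    def test_gradient_inversely_proportional_to_echo_spacing(self):
        g1 = shift_to_gradient(0.02, 5e-4, 0.192)
        g2 = shift_to_gradient(0.02, 1e-3, 0.192)
        assert g1 == pytest.approx(2 * g2)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            shift_to_gradient(0.1, 0.0, 0.192)


class TestRefinement:
    @pytest.fixture(scope="class")
    def refine_setup(self, small_series, pipeline):
        dataset, schedule = small_series
        return dataset, schedule, pipeline

    def test_corruption_free_frame_keeps_dy(self, refine_setup):
        dataset, _, pipe = refine_setup
        frame, nav = dataset.frames[0], dataset.navigators[0]
        _, est = pipe.recon_frame(frame, nav, correct=True, refine=True)
        assert abs(est.d[1]) < 0.006

    def test_single_point_grid_returns_input(self, refine_setup):
        dataset, _, pipe = refine_setup
        frame, nav = dataset.frames[1], dataset.navigators[1]
        est = pipe.estimate_frame(frame, nav)
        refined = nb.refine_dy(
            est, frame, pipe.reference_images,
            corrector=pipe._corrector,
            reconstructor=pipe._unalias_and_fill,
            n_points=1,
        )
        assert refined.d[1] == est.d[1]

    def test_misestimated_dy_pulled_toward_truth(self, refine_setup):
        """Perturbing dy by +0.03 and refining reduces the dy error."""
        dataset, schedule, pipe = refine_setup
        scene_fov = np.array(dataset.ground_truth["fov"])
        esp = dataset.ground_truth["echo_spacing"]
        p = 2
        frame, nav = dataset.frames[p], dataset.navigators[p]
        d_true = np.array(schedule.fields[p][0].gradient) * scene_fov * esp
        est = pipe.estimate_frame(frame, nav)
        bad = est.replace(d=est.d + np.array([0.0, 0.03, 0.0]))
        refined = nb.refine_dy(
            bad, frame, pipe.reference_images,
            corrector=pipe._corrector,
            reconstructor=pipe._unalias_and_fill,
            window=0.05, n_points=11,
        )
        assert abs(refined.d[1] - d_true[1]) < abs(bad.d[1] - d_true[1])


class TestSidecar:
    def test_estimates_roundtrip_through_json(self, tmp_path, nav_ref,
                                              ops_mb2):
        res = OffResonanceModel(nav_ref, nav_ref, ops_mb2).fit()
        path = tmp_path / "estimates.json"
        nb.estimation.write_estimates([res], path)
        back = nb.estimation.read_estimates(path)
        assert len(back) == 1
        assert np.allclose(back[0].c, res.c)
        assert np.allclose(back[0].d, res.d)
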