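"""Shared fixtures: standard synthetic scenes and calibration-trained assets.

Everything is generated programmatically and seeded; session scope keeps
the expensive assets (operator training, pipelines) shared across tests.
"""

import warnings

import numpy as np
import pytest

import navb0 as nb
from navb0.fourier import fft2c


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def scene_mb1():
    """Single-slice noiseless standard scene (64x64, J=12)."""
    return nb.default_scene(n=64, j=12, mb=1, snr_db=None, seed=0)


@pytest.fixture(scope="session")
def k_mb1(scene_mb1):
    """Fully sampled multichannel k-space of the single-slice scene."""
    return fft2c(scene_mb1.coils.slice(0) * scene_mb1.objects[0])


@pytest.fixture(scope="session")
def ops_mb1(k_mb1):
    return {
        "readout": nb.train_operator(k_mb1, "readout"),
        "phase": nb.train_operator(k_mb1, "phase"),
    }


@pytest.fixture(scope="session")
def scene_mb2():
    """Two-slice (MB=2) noiseless standard scene."""
    return nb.default_scene(n=64, j=12, mb=2, snr_db=None, seed=0)


@pytest.fixture(scope="session")
def ks_mb2(scene_mb2):
    """Per-slice fully sampled k-space of the MB=2 scene."""
    return [
        fft2c(scene_mb2.coils.slice(s) * scene_mb2.objects[s]) for s in range(2)
    ]


@pytest.fixture(scope="session")
def proxy_mb2(scene_mb2, ks_mb2):
    return nb.build_proxy_3d_calibration(
        ks_mb2, scene_mb2.slice_positions, scene_mb2.n_slices_total
    )


@pytest.fixture(scope="session")
def ops_mb2(ks_mb2, proxy_mb2):
    """Operators for all three axes (slice via the proxy 3D volume)."""
    stacked = np.stack(ks_mb2, axis=-1)
    return {
        "readout": nb.train_operator(stacked, "readout"),
        "phase": nb.train_operator(stacked, "phase"),
        "slice": nb.train_operator(
            proxy_mb2.volume, "slice", min_eig_modulus=0.5
        ),
    }


@pytest.fixture(scope="session")
def scene_series():
    """Standard accelerated series scene: MB=2, R=2, 30 dB noise."""
    return nb.default_scene(n=64, j=12, mb=2, r_factor=2, snr_db=30.0, seed=0)


@pytest.fixture(scope="session")
def small_series(scene_series):
    """An 8-frame corrupted series (frame 0 is the clean reference)."""
    schedule = nb.PerturbationSchedule.draw(
        8, scene_series, field_std_hz=20.0, seed=11
    )
    return nb.make_series(scene_series, schedule), schedule


@pytest.fixture(scope="session")
def pipeline(small_series):
    dataset, _ = small_series
    return nb.ReconPipeline(dataset)


def collapsed_navigator(scene, field, rng=None):
    """Encode all slices of a group under one field and collapse the navs."""
    per = [
        nb.encode_epi(scene, field, s, rng=rng)
        for s in range(scene.n_slices)
    ]
    caipi = tuple(range(scene.n_slices))
    _, nav = nb.collapse_sms([f for f, _ in per], [n for _, n in per], caipi)
    return nav
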