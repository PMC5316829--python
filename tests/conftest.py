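import numpy as np
import pytest

from tsyslab.calcium import CalibrationParams
from tsyslab.phantom import NoiseModel, PhantomSpec


@pytest.fixture
def calib():
    return CalibrationParams(f_min=100.0, f_max=1100.0)


@pytest.fixture
def small_spec():
    """Fast phantom: 5 sarcomeres, 2 um radius, ~1.4 Mvoxel grid."""
    return PhantomSpec(fibre_radius=2.0, fibre_length=11.5,
                       grid_shape=(32, 128, 96), rng_seed=0)


@pytest.fixture
def medium_spec():
    """Default-radius fibre on a shorter grid, for vacuole morphometrics."""
    return PhantomSpec(fibre_radius=4.0, fibre_length=11.5,
                       grid_shape=(64, 128, 128), rng_seed=0)


def make_vacuole_spec(seed: int, count: int, axes=(0.9, 1.0, 0.9), glow=True):
    """Vacuole-quantification phantom: raw-image glow pedestal at tubule level.

    The percentile threshold convention isolates vacuoles when the in-fibre
    intensity plateau (out-of-focus glow in raw confocal images) sits at or
    above the tubule level, leaving only vacuoles in the top tail.  Uses a
    2 um-radius fibre (~145 um^3) so a handful of ~1 um vacuoles spans the
    0.5-5% volume-fraction range.
    """
    return PhantomSpec(fibre_radius=2.0, fibre_length=11.5,
                       grid_shape=(32, 128, 96), rng_seed=seed,
                       vacuole_count=count, vacuole_axes=axes,
                       tubule_intensity=1.0, vacuole_intensity=6.0,
                       fibre_glow=1.0 if glow else 0.0)


@pytest.fixture
def default_noise():
    return NoiseModel(photon_scale=2000.0, read_noise_sd=0.002)
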