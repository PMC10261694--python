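import numpy as np
import pytest

from dbpet import PhantomSpec, PETVolume, SensitivityModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A small phantom spec that keeps every test fast."""
    return PhantomSpec(
        n_slices=24,
        slice_shape=(48, 48),
        gland_fraction=0.6,
        gland_texture_sigma_mm=5.0,
        sensitivity=SensitivityModel(edge_min=0.3),
    )


@pytest.fixture
def uniform_spec():
    """Whole-breast gland at a single SUV: a uniform-activity phantom."""
    return PhantomSpec(
        n_slices=64,
        slice_shape=(64, 64),
        gland_fraction=1.0,
        sensitivity=SensitivityModel(edge_min=0.3),
    )


def make_volume(values, spacing=0.78, duration=3.0, meta="LC"):
    return PETVolume(values=np.asarray(values, dtype=float), spacing=spacing,
                     duration_min=duration, meta=meta)


@pytest.fixture
def volume_factory():
    return make_volume
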