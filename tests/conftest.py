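import numpy as np
import pytest

from eatquant import MaskGrid, PhantomParams, SeriesModel, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Phantom small enough for fast tests (~10 mL fat shell)."""
    return PhantomParams(
        shape=(32, 32, 32),
        spacing=(2.0, 2.0, 2.0),
        r_blood=8.0,
        r_myocardium=12.0,
        r_fat=18.0,
        r_sac=22.0,
    )


@pytest.fixture
def noiseless_models():
    """Degenerate series models: zero spread, means strictly in-window."""
    return (
        SeriesModel("TNC", -80.0, 0.0),
        SeriesModel("VNC_Conv", -80.0, 0.0, shift_delta=5.0),
        SeriesModel("VNC_PC", -80.0, 0.0, shift_delta=2.0),
        SeriesModel("CTA", -80.0, 0.0, shift_delta=-2.0),
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0), label="TNC", patient="P000"):
    return VolumeGrid(np.asarray(values, dtype=float), spacing, label, patient)


def make_mask(flags, spacing=(1.0, 1.0, 1.0)):
    return MaskGrid(np.asarray(flags, dtype=bool), spacing)


@pytest.fixture
def cube_volume():
    """5x5x5 volume, all voxels −100 HU, full mask."""
    vol = make_volume(np.full((5, 5, 5), -100.0))
    mask = make_mask(np.ones((5, 5, 5)))
    return vol, mask
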