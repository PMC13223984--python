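import pytest

from sweepvep.design import make_sweep_design
from sweepvep.simulate import NoiseModel, default_response_model, simulate_sweep_recording

#: Reduced montage for fast tests: the occipital reference set, the
#: mediofrontal reference, and a few distant electrodes.
SMALL_MONTAGE = ("Oz", "O1", "O2", "POz", "Iz", "Pz", "Cz", "Fpz")


@pytest.fixture(scope="session")
def small_montage():
    return SMALL_MONTAGE


@pytest.fixture(scope="session")
def contrast_design():
    return make_sweep_design("contrast", "increasing")


@pytest.fixture(scope="session")
def noiseless_recording(contrast_design):
    """Two noise-free contrast sweep trials on the reduced montage."""
    return simulate_sweep_recording(
        contrast_design,
        default_response_model("contrast"),
        NoiseModel(white_sd=0.0, pink_scale=0.0),
        montage=SMALL_MONTAGE,
        srate=250.0,
        seed=0,
        n_trials=2,
    )


def simulate_noisy(
    condition="contrast",
    direction="increasing",
    seed=0,
    n_trials=6,
    montage=SMALL_MONTAGE,
    srate=250.0,
    **response_overrides,
):
    design = make_sweep_design(condition, direction)
    rec = simulate_sweep_recording(
        design,
        default_response_model(condition, **response_overrides),
        NoiseModel(),
        montage=montage,
        srate=srate,
        seed=seed,
        n_trials=n_trials,
    )
    return design, rec
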