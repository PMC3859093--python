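import numpy as np
import pytest

from powdercal import (
    ComponentSpectrumSpec,
    NoiseModel,
    SpectralDataset,
    design_spec,
    generate_design,
    lnir_grid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Hand-built 3-sample, 5-wavelength dataset."""
    return SpectralDataset(
        wavelengths=np.array([100.0, 200.0, 300.0, 400.0, 500.0]),
        reflectance=np.array(
            [
                [0.10, 0.20, 0.30, 0.40, 0.50],
                [0.15, 0.25, 0.35, 0.45, 0.55],
                [0.20, 0.30, 0.40, 0.50, 0.60],
            ]
        ),
        np_percent=np.array([100.0, 90.0, 80.0]),
        sfp_percent=np.array([0.0, 10.0, 20.0]),
        cf_percent=np.array([0.0, 0.0, 0.0]),
        treatment_id=np.array([1, 2, 3]),
        design_id="A",
    )


@pytest.fixture(scope="session")
def design_a_lnir():
    """Default-noise Design A on the LNIR grid (100 samples x 241 vars)."""
    return generate_design("A", noise=NoiseModel(seed=42), grid=lnir_grid())


def planted_components(centers=(1200.0, 1700.0, 2200.0), depths=(0.30, 0.25, 0.20),
                       width=3.0):
    """NP/SFP/CF specs where only 3 narrow bands separate NP from SFP.

    CF carries no contrast at all; channels away from the planted bands
    are identical across components, so with zero noise they are constant
    across samples.
    """
    shared = ((1940.0, 80.0, 0.25),)
    np_spec = ComponentSpectrumSpec(
        "NP", shared + tuple((c, width, d) for c, d in zip(centers, depths)), 0.7
    )
    sfp_spec = ComponentSpectrumSpec("SFP", shared, 0.7)
    cf_spec = ComponentSpectrumSpec("CF", shared, 0.7)
    return np_spec, sfp_spec, cf_spec


@pytest.fixture
def planted_design_a():
    """Noise-free Design A whose NP signal lives in 3 narrow LNIR bands."""
    comps = planted_components()
    noise = NoiseModel(0.0, 0.0, 0.0, 0.0, seed=0)
    ds = generate_design(design_spec("A", 20), components=comps, noise=noise,
                         grid=lnir_grid())
    return ds, (1200.0, 1700.0, 2200.0)
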