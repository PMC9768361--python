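import numpy as np
import pytest

from mucomap.synthetic import SynthParams, generate_case, generate_slide


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale generator settings: small slides, small lesions."""
    return SynthParams(
        slide_size=(96, 160),
        n_cancer_lesions=1,
        n_metaplasia_lesions=1,
        lesion_radius_range=(10, 16),
        microns_per_pixel=20.0,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_slide(small_params):
    return generate_slide(small_params)


@pytest.fixture(scope="session")
def small_case():
    """A 4-section synthetic specimen at coarse resolution."""
    params = SynthParams(
        slide_size=(64, 360),
        n_cancer_lesions=2,
        n_metaplasia_lesions=2,
        lesion_radius_range=(14, 24),
        microns_per_pixel=40.0,
        photo_scale=0.5,
        rng_seed=7,
    )
    return generate_case(params, n_sections=4)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
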