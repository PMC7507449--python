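import numpy as np
import pytest

import thighcomp as tc

QUAD = ("RF", "VL", "VI", "VM")


@pytest.fixture(scope="session")
def quad_spec_noiseless():
    """Four-muscle noiseless phantom spec with mixed IntraMAT fractions."""
    return tc.default_phantom_spec(
        muscles=QUAD, n_slices=2,
        intramat_fraction={"RF": 0.0, "VL": 0.10, "VI": 0.15, "VM": 0.20},
        noise_sd=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def quad_phantom_noiseless(quad_spec_noiseless):
    return tc.generate_phantom(quad_spec_noiseless)


@pytest.fixture(scope="session")
def quad_phantom_snr20():
    spec = tc.default_phantom_spec(
        muscles=QUAD, n_slices=1, intramat_fraction=0.15, noise_sd=5.0, seed=12,
    )
    return spec, tc.generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
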