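import numpy as np
import pytest
from hypothesis import settings

from adipoquant import PhantomSpec, make_phantom

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    """32x32x3 noiseless phantom: (truth maps, truth seg, echo series)."""
    return make_phantom(PhantomSpec(shape=(32, 32, 3), snr=None, seed=0))


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """48x48x4 SNR-40 phantom with a field-map ramp."""
    return make_phantom(
        PhantomSpec(shape=(48, 48, 4), snr=40.0, seed=7, fieldmap_model="ramp")
    )


@pytest.fixture(scope="session")
def default_cohort():
    from adipoquant import CohortSpec, simulate_cohort

    return simulate_cohort(CohortSpec(seed=11))
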