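import numpy as np
import pytest

from flavopk import box_behnken, results_from_coefficients
from flavopk.presets import BBD_FACTORS, BBD_MODEL_COEFFICIENTS


@pytest.fixture(scope="session")
def bbd17():
    """The 17-run Box-Behnken design over the published ESI factor ranges."""
    return box_behnken(BBD_FACTORS, n_center=5)


@pytest.fixture(scope="session")
def published_surface(bbd17):
    """ResponseSurfaceResults carrying the published quadratic coefficients."""
    c = BBD_MODEL_COEFFICIENTS
    return results_from_coefficients(
        bbd17, c["b0"], c["linear"], c["quadratic"], c["interaction"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
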