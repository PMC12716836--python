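import numpy as np
import pytest

import flimcal as fc


@pytest.fixture(scope="session")
def endpoints_37c() -> fc.CalibrationEndpoints:
    """Endpoints built from the published 37 degC apo/sat lifetime pairs."""
    return fc.synthetic.paper_like_endpoints("37C")


@pytest.fixture(scope="session")
def hill_37c() -> fc.HillParams:
    return fc.synthetic.paper_like_hill("37C")


@pytest.fixture(scope="session")
def calib_37c(endpoints_37c, hill_37c) -> fc.CalibrationResult:
    """A calibration result carrying the published truth (no fitting)."""
    return fc.CalibrationResult(
        params=hill_37c,
        ci95={},
        endpoints=endpoints_37c,
        residual_norm=0.0,
        converged=True,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
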