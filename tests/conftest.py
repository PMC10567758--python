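import numpy as np
import pytest

import virextinct as vx


@pytest.fixture(scope="session")
def baseline():
    """SARS-CoV-2 in-host baseline: n_I = 1, beta fixed from R0 = 7.69."""
    return vx.czuppon_baseline()


@pytest.fixture(scope="session")
def fig5_params():
    """Baseline under a p-antiviral tuned so T*/N_cells = 0.5."""
    return vx.treated_preset(0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230930)
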