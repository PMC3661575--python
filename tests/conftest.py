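import numpy as np
import pytest

from metabotaxis import calibrate_default_params, default_spec


@pytest.fixture(scope="session")
def params():
    """The frozen default metabolism preset."""
    return calibrate_default_params()


@pytest.fixture(scope="session")
def specs():
    """Shipped behavior presets for all four controllers."""
    return {kind: default_spec(kind) for kind in ("B1", "B2", "B3", "B4")}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
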