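import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170227)


@pytest.fixture(scope="session")
def default_params():
    from gnrhinfo.model import build_default_parameters

    return build_default_parameters()
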