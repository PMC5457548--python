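import os

import numpy as np
import pytest

from claimsce import claims_io

FIXTURE_DIR = os.path.join(os.path.dirname(__file__), "data", "fixture_bundle")


@pytest.fixture(scope="session")
def fixture_dir() -> str:
    return FIXTURE_DIR


@pytest.fixture(scope="session")
def fixture_bundle() -> claims_io.ClaimsBundle:
    return claims_io.read_bundle(FIXTURE_DIR, strict=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
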