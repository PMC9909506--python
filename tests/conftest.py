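from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from t2tkit.seqio import Config

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
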