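from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spinemorph import StudyConfig, calibrate_rate_table, generate_study

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def rate_table():
    return calibrate_rate_table()


@pytest.fixture(scope="session")
def small_study():
    """Default-sized study (4 × 77 segments, 19 animals), classified."""
    ds = generate_study(StudyConfig(seed=0))
    ds.classify()
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_paths():
    return {
        "spines": DATA_DIR / "toy_spines.tsv",
        "segments": DATA_DIR / "toy_segments.tsv",
        "biometrics": DATA_DIR / "toy_biometrics.tsv",
    }
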