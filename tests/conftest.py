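import warnings

import numpy as np
import pytest

from helpers import make_site

from phosite_evo.integrate import ProteinRecord, PTMSiteRecord, SiteCatalog
from phosite_evo.pipeline import run_synthetic_pipeline
from phosite_evo.synthetic_data import SimulationConfig

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=101, n_groups=15)


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    """One modest end-to-end run shared by read-only tests."""
    return run_synthetic_pipeline(small_config)


@pytest.fixture()
def toy_proteins():
    return [
        ProteinRecord("P1", "mel", "MSTAYKLSPQR"),
        ProteinRecord("P2", "mel", "MSTAYKLSPQR"),  # duplicate of P1
        ProteinRecord("P3", "mel", "AKSPYLTRRGS"),
    ]


@pytest.fixture()
def make_site_record():
    return make_site


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
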