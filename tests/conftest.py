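import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from rfa_radiomics import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: small-footprint generator settings used across tests (fast phantoms)
SMALL_IMAGE = dict(image_shape=(40, 40, 40), spacing_mm=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-lesion strong-signal cohort shared by read-only tests."""
    cfg = synth.GeneratorConfig(n_lesions=20, seed=7, **SMALL_IMAGE)
    cases, manifest = synth.generate_cohort(cfg)
    return cases, manifest, cfg
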