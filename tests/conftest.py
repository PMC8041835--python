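import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from g4atlas import plant_profile_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale metagene cohort: 0.8 Mb, 60 genes, peaks planted at 0.6/0.3/0.1."""
    return plant_profile_cohort(n_genes=60, chrom_lengths=(400_000, 400_000), seed=3)
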