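import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from panmum import FixtureParams, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def snp_fixture():
    """Small SNP+indel pangenome with truth record (session-cached)."""
    params = FixtureParams(
        ancestor_length=20_000, m=5, snp_rate=1e-3, indel_rate=1e-4, seed=11
    )
    ancestor, seqs, truth = generate(params)
    return ancestor, seqs, truth, params


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
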