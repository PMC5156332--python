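import zlib

import numpy as np
import pytest

from c2kit.io import cds_sequence
from c2kit.simulate import generate_phage_pair


@pytest.fixture()
def rng(request):
    # seeded per test (not shared), so results never depend on test order
    name_hash = zlib.crc32(request.node.name.encode()) % 100_000
    return np.random.default_rng(20160801 + name_hash)


@pytest.fixture(scope="session")
def cohort():
    """One default-condition synthetic parental pair, shared across tests."""
    return generate_phage_pair(seed=11)


@pytest.fixture(scope="session")
def cohort_genes(cohort):
    """(CdsRecord, sequence) pairs for both genomes of the shared cohort."""
    return [(r, cds_sequence(cohort.genome_a, r)) for r in cohort.cds_a] + [
        (r, cds_sequence(cohort.genome_b, r)) for r in cohort.cds_b
    ]
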