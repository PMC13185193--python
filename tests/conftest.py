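import numpy as np
import pytest
from hypothesis import settings

from elephkin.core import GenotypeMatrix, MarkerMap
from elephkin.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(calls, pos=None, chrom=None, sample_ids=None):
    """Small GenotypeMatrix from a nested list of dosage codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    chrom = np.array(["chr1"] * m, dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    mm = MarkerMap(
        chrom,
        pos,
        np.array(["A"] * m, dtype=object),
        np.array(["G"] * m, dtype=object),
    )
    ids = sample_ids or [f"S{i}" for i in range(n)]
    return GenotypeMatrix(ids, calls, mm)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced study-shaped dataset shared across tests."""
    return simulate_dataset(
        SimConfig(
            seed=5,
            n_samples=80,
            n_markers=1200,
            n_founder_females=14,
            n_founder_males=8,
            n_wild_males=4,
        )
    )
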