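import numpy as np
import pytest

from msatbot import (PriorSet, build_reference_table, generate_fixture)
from msatbot.genotype_io import GenotypeDataset, Locus


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dataset(rng, n_ind=12, n_loci=4, missing_rate=0.0,
                   species_id="toy"):
    calls = rng.integers(8, 20, size=(n_ind, n_loci, 2)).astype(np.int64)
    if missing_rate:
        miss = rng.random((n_ind, n_loci)) < missing_rate
        miss[0, :] = False
        calls[miss] = 0
    loci = [Locus(f"L{j}", 2, "repeat_units") for j in range(n_loci)]
    return GenotypeDataset(species_id, loci,
                           [f"i{k}" for k in range(n_ind)], calls)


@pytest.fixture
def toy_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(params=["monomorphic", "missing_heavy", "two_allele_hwe",
                        "off_lattice", "tiny"])
def fixture_dataset(request):
    return generate_fixture(request.param)


@pytest.fixture(scope="session")
def small_table():
    """Small reference table shared by the ABC unit tests (2000 rows per
    model keeps each accepted neighbourhood meaningful while staying
    fast)."""
    return build_reference_table(
        PriorSet(), n_per_model=2000, rng=np.random.default_rng(77)
    )
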