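import numpy as np
import pytest

from kmeridx.index import build_index
from kmeridx.synthetic import CohortSpec, simulate_experiments


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 20-experiment cohort small enough for unit tests, built with a tiny
    bucket cap so that multiple buckets are exercised."""
    d = tmp_path_factory.mktemp("small_cohort")
    spec = CohortSpec(
        n_experiments=20,
        n_core_transcripts=8,
        n_variable_transcripts=20,
        transcript_length=(100, 300),
        private_kmers_per_experiment=300,
        seed=5,
    )
    return simulate_experiments(spec, d)


@pytest.fixture(scope="session")
def small_index(small_cohort):
    return build_index(small_cohort.manifest, group_size=7, cap_bytes=2 << 10, seed=7)


@pytest.fixture(scope="session")
def full_cohort(tmp_path_factory):
    """The default study-scale cohort: 100 experiments, ~5e5 distinct k-mers
    with the U-shaped occurrence-frequency structure."""
    d = tmp_path_factory.mktemp("full_cohort")
    return simulate_experiments(CohortSpec(seed=1), d)


@pytest.fixture(scope="session")
def full_index(full_cohort):
    return build_index(full_cohort.manifest, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
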