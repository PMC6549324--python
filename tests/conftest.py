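import pytest
from hypothesis import HealthCheck, settings

import genetables as gt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def edge_set():
    return gt.make_edge_fixtures()


@pytest.fixture(scope="session")
def edge_rows(edge_set):
    kept, _ = gt.apply_curation(edge_set.genes)
    return gt.derive_all(kept)


@pytest.fixture(scope="session")
def small_set():
    """Seeded 20-gene synthetic set with ground truth."""
    return gt.generate(gt.GeneratorParams(n_genes=20, seed=11))


@pytest.fixture(scope="session")
def small_curated(small_set):
    aset, _ = small_set
    kept, report = gt.apply_curation(aset.genes)
    return kept, report


@pytest.fixture(scope="session")
def small_rows(small_curated):
    kept, _ = small_curated
    return gt.derive_all(kept)
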