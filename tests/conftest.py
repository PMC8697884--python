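import numpy as np
import pytest

from quillnet.ingest import build_web, load_tables


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def web(tables):
    """The survey web under the default (prevalence-score) weighting."""
    return build_web(
        tables.interactions, tables.occurrences, hosts=tables.hosts, weighting="prevalence"
    )


@pytest.fixture(scope="session")
def counts_web(tables):
    return build_web(
        tables.interactions, tables.occurrences, hosts=tables.hosts, weighting="counts"
    )


@pytest.fixture(scope="session")
def counted_occurrences(tables):
    return [r for r in tables.occurrences if r.examined is not None]


@pytest.fixture(scope="session")
def best_partition(web):
    """Best-of-ten annealing partition of the survey web (shared across
    the modularity unit tests and the acceptance suite)."""
    from quillnet.modularity import optimize_modules

    return optimize_modules(web, seed=1, restarts=10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210331)
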