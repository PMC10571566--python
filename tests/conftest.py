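import warnings

import pytest

from blcasig.ingest import load_cohort
from blcasig.simulate import SimConfig, generate_cohort, write_fixtures


@pytest.fixture(scope="session")
def small_synth():
    """A small cohort with planted signal, cheap enough for unit tests."""
    cfg = SimConfig(n_samples=60, n_genes=300, n_informative=8,
                    effect_size=1.2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_synth, tmp_path_factory):
    """The small cohort round-tripped through the fixture files."""
    d = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(small_synth, d)
    return load_cohort(paths["expression"], paths["clinical"],
                       paths["metadata"])


@pytest.fixture(scope="session")
def signal_cohort(tmp_path_factory):
    """A mid-sized cohort for selection-procedure tests."""
    cfg = SimConfig(n_samples=120, n_genes=600, n_informative=12,
                    effect_size=1.2, seed=7)
    synth = generate_cohort(cfg)
    d = tmp_path_factory.mktemp("signal")
    paths = write_fixtures(synth, d)
    cohort = load_cohort(paths["expression"], paths["clinical"],
                         paths["metadata"])
    return synth, cohort


@pytest.fixture(autouse=True)
def _quiet_convergence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield
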