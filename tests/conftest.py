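import numpy as np
import pytest

from glycoprox import enrichment as en
from glycoprox.simulate import LfqSimConfig, generate_lfq_table


@pytest.fixture(scope="session")
def small_lfq():
    """A small simulated LFQ experiment: (config, table, truth, design)."""
    config = LfqSimConfig(n_proteins=300, seed=7)
    table, truth = generate_lfq_table(config)
    return config, table, truth, config.design()


@pytest.fixture(scope="session")
def small_records(small_lfq):
    """Enrichment records of the small experiment (uncalled)."""
    config, table, truth, design = small_lfq
    return en.enrich(en.filter_contaminants(table), design, "MB")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
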