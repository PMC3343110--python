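import numpy as np
import pytest

import retroarray as ra


@pytest.fixture(scope="session")
def toy_dataset():
    """The bundled toy scenario: eight elements, one spiked +2 log2, 3v3."""
    return ra.simulate_all(ra.default_config(seed=0))


@pytest.fixture(scope="session")
def toy_genome(toy_dataset):
    return ra.Genome(toy_dataset.genome)


@pytest.fixture(scope="session")
def toy_annotations(toy_dataset, toy_genome):
    return ra.annotate_platform(
        toy_dataset.probes, toy_genome, toy_dataset.truth.records, ra.Parameters()
    )


@pytest.fixture(scope="session")
def toy_de(toy_dataset):
    _, results = ra.run_de(toy_dataset.expression, "case", "control")
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
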