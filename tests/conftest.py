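import numpy as np
import pytest

from dendtrans import simdata


@pytest.fixture(scope="session")
def strong_params():
    return simdata.preset_params("strong", n_genes=1000, seed=11)


@pytest.fixture(scope="session")
def strong_truth(strong_params):
    return simdata.make_truth(strong_params)


@pytest.fixture(scope="session")
def strong_transcriptome(strong_params, strong_truth):
    return simdata.simulate_transcriptome(strong_params, strong_truth)


@pytest.fixture(scope="session")
def strong_rna(strong_params, strong_truth):
    return simdata.simulate_rna_counts(strong_params, strong_truth)


@pytest.fixture(scope="session")
def strong_footprints(strong_params, strong_truth, strong_transcriptome):
    models, _, _ = strong_transcriptome
    return simdata.simulate_footprints(strong_params, models, strong_truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
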