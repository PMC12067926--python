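import numpy as np
import pytest

from phylotox import growth_metrics as gm
from phylotox import synthetic_data as sd


@pytest.fixture(scope="session")
def yule50():
    """A fixed 50-tip Yule tree shared by signal-statistics tests."""
    return sd.simulate_tree(50, birth_rate=1.0, seed=3)


@pytest.fixture(scope="session")
def dataset():
    """One default-condition synthetic study (26 isolates, 23 chemicals)."""
    return sd.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def response_matrix(dataset):
    """Isolate dAUC matrix of the shared dataset (fixed spline smoothing)."""
    return gm.build_response_matrix(dataset.growth_curves, screen=False, smoothing=1.0)


@pytest.fixture(scope="session")
def community_metrics(dataset):
    """Diversity and SES.MPD tables of the shared dataset."""
    from phylotox import community_structure as cs

    div = cs.diversity(dataset.abundance)
    ses = cs.ses_mpd(dataset.abundance, dataset.tree, n_rand=199, seed=0)
    return div, ses


def logistic_od(t, capacity=1.0, rate=0.3, lag=24.0):
    return capacity / (1.0 + np.exp(-rate * (t - lag)))
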