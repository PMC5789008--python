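import numpy as np
import pandas as pd
import pytest

from genoclime import SyntheticConfig, simulate_dataset
from genoclime.gene_index import CorrelationEstimate


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study under the default conditions."""
    return simulate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Synthetic study with all noise switched off (exact identities hold)."""
    return simulate_dataset(
        SyntheticConfig(seed=11, trait_noise_sd=0.0, freq_noise_sd=0.0)
    )


def correlation_from_matrix(m, n_pairs: int = 50) -> CorrelationEstimate:
    """Wrap a plain correlation matrix as a CorrelationEstimate for tests."""
    m = np.asarray(m, dtype=float)
    k = m.shape[0]
    labels = [f"v{i}" for i in range(k)]
    return CorrelationEstimate(
        matrix=pd.DataFrame(m, index=labels, columns=labels),
        pair_counts=pd.DataFrame(
            np.full((k, k), n_pairs), index=labels, columns=labels
        ),
    )
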