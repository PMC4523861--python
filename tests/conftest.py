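import pandas as pd
import pytest
from hypothesis import settings

from silacphos.quant import compute_ratio, normalize_replicates, sum_by_peptide
from silacphos.simulate import SyntheticConfig, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small but fully featured experiment: biases, missingness, motifs."""
    return SyntheticConfig(
        n_proteins=120,
        n_phosphopeptides=600,
        n_nonphospho_peptides=300,
        global_bias=(0.0, 0.5, -0.4, 0.25),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def normalized_small(small_dataset) -> pd.DataFrame:
    table, _ = small_dataset
    ratios = compute_ratio(sum_by_peptide(table))
    normalized, _ = normalize_replicates(ratios)
    return normalized
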