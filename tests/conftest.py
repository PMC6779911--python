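import numpy as np
import pandas as pd
import pytest

from nitrosense.pipeline import PipelineConfig, run_transcriptome
from nitrosense.synthetic import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=600, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def small_transcriptome(small_dataset, small_config):
    cfg = PipelineConfig(sim=small_config, k_rt=40)
    return run_transcriptome(small_dataset, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide_table(rng, n_proteins=5, n_channels=6, max_pep=5, missing=0.3):
    rows = []
    for p in range(n_proteins):
        n_pep = rng.integers(1, max_pep + 1)
        base = rng.normal(20, 3, n_channels)
        for j in range(n_pep):
            vals = base + rng.normal(0, 1.5) + rng.normal(0, 0.5, n_channels)
            mask = rng.random(n_channels) < missing
            if mask.all():
                mask[rng.integers(n_channels)] = False
            vals = np.where(mask, np.nan, vals)
            rows.append([f"p{p}_pep{j}", f"prot{p}", *vals])
    cols = ["peptide_id", "protein_id", *[f"s{i}" for i in range(n_channels)]]
    return pd.DataFrame(rows, columns=cols)
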