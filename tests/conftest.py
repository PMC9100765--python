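import numpy as np
import pytest

from pleioscan import io as pio
from pleioscan import pipeline as pl
from pleioscan import synthdata as sd


@pytest.fixture(scope="session")
def small_dataset() -> sd.SyntheticDataset:
    """A compact synthetic panel shared by read-only tests."""
    cfg = sd.SimulationConfig(
        n_lines=120, n_genes=20, n_snps=300, n_pwms=15, seed=7
    )
    return sd.generate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def e2e_run():
    """Full pipeline at the reference study conditions (400 lines, 2000
    SNPs, 20 traits, 3 planted clusters); shared by the end-to-end
    recovery tests.  Reference analysis settings: 500-tree forests, IFS
    stride 1, at most 40 Boruta shadow iterations (decisions at the default
    alpha need ~12-16 iterations on this panel; the cap only bounds
    undecidable stragglers)."""
    dataset = sd.generate_dataset(sd.SimulationConfig(seed=1))
    config = pio.PipelineConfig(seed=1, n_trees=500, max_iter=40, stride=1)
    result = pl.analyze(
        dataset.snps, dataset.line_ids, dataset.genome, dataset.annotations,
        dataset.pwms, dataset.phenotypes, dataset.counts, config,
    )
    return dataset, result
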