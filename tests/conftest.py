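import numpy as np
import pytest

import chmarray as ca


def small_config(seed: int = 11, **overrides) -> ca.SimulationConfig:
    """A fast, fully-featured simulation: 1 chromosome would lose the
    between-chromosome structure, so keep 2 but shrink everything else."""
    defaults = dict(
        seed=seed,
        n_samples=20,
        n_chromosomes=2,
        n_blocks=8,
        snps_per_block=12,
        block_span_bp=50_000,
        cnv_spec=[
            ca.CNVSpec("chr1", 200_000, 250_000, "loss", 0.5),
            ca.CNVSpec("chr2", 300_000, 350_000, "gain", 0.25),
        ],
    )
    defaults.update(overrides)
    return ca.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset() -> ca.SimulatedDataset:
    return ca.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def default_dataset() -> ca.SimulatedDataset:
    """The generator's default study conditions (84 samples, 2 chromosomes)."""
    return ca.simulate_dataset(ca.SimulationConfig(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
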