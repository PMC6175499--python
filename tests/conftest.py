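import numpy as np
import pytest

from phaseloop import (
    ExpressionDataset,
    SimulationConfig,
    center_to_baseline,
    generate,
    impute_missing_timepoints,
    synthetic_stage_map,
)


@pytest.fixture
def tiny_ds():
    """3 genes x 4 samples (2 individuals x 2 times), hand-checkable values."""
    return ExpressionDataset(
        genes=["IL1A", "TNIP3", "GAPDH"],
        samples=[("D1", 0.0), ("D1", 2.0), ("D2", 0.0), ("D2", 2.0)],
        values=np.array(
            [
                [1.0, 3.0, 2.0, 5.0],
                [0.5, 1.5, 0.5, 2.5],
                [7.0, 7.0, 7.0, 7.0],
            ]
        ),
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation with one planted pair (plus tiny background)."""
    cfg = SimulationConfig(
        seed=5,
        noise_sd=0.0,
        indiv_offset_sd=0.0,
        n_planted_pairs=1,
        n_background_genes=5,
        n_individuals=4,
    )
    return cfg, *generate(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default study-condition simulation (12 individuals, 500 background)."""
    cfg = SimulationConfig(seed=7)
    return cfg, *generate(cfg)


@pytest.fixture(scope="session")
def prepared_noisy(noisy_sim):
    cfg, ds, truth = noisy_sim
    return cfg, center_to_baseline(impute_missing_timepoints(ds)), truth


@pytest.fixture(scope="session")
def stage_map_default():
    return synthetic_stage_map(SimulationConfig(seed=0).times)
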