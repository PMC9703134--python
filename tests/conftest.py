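import numpy as np
import pandas as pd
import pytest

from methdrift.simulate import SimulationConfig, generate_cohort, generate_tracks


@pytest.fixture(scope="session")
def small_cohort():
    """2,000 CpGs x 40 samples with default planted fractions."""
    cfg = SimulationConfig(n_cpgs=2000, n_samples=40, n_donors=12, seed=42)
    beta, sheet, truth = generate_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """5,000 CpGs x 80 samples at the study's sample size."""
    cfg = SimulationConfig(n_cpgs=5000, n_samples=80, n_donors=46, seed=7)
    beta, sheet, truth = generate_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def cohort_with_tracks(small_cohort):
    cfg, beta, sheet, truth = small_cohort
    annotation, tracks = generate_tracks(
        n_features=120, genome_length=8_000_000, ground_truth=truth, seed=11
    )
    return beta, sheet, truth, annotation, tracks


@pytest.fixture()
def toy_sheet():
    """10 samples, passages 1..10, two donors."""
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(1, 11)],
            "donor_id": ["A"] * 5 + ["B"] * 5,
            "passage": list(range(1, 11)),
            "segment": ["TI", "SC"] * 5,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
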