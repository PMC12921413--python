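import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chronometab.dataio import AnalysisConfig, MetaboliteTable
from chronometab.synthetic import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> AnalysisConfig:
    return AnalysisConfig(seed=1)


@pytest.fixture(scope="session")
def study_dataset():
    """Full study-scale synthetic dataset (398 x 32) with ground truth."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 40-metabolite dataset for pipeline-level tests."""
    gcfg = GeneratorConfig(n_metabolites=40, frac_rhythmic=10 / 40,
                           frac_disrupted_given_rhythmic=0.3,
                           frac_abolished_given_rhythmic=0.3,
                           n_fc_effects=5, seed=7)
    return generate_dataset(gcfg)


@pytest.fixture
def tiny_table() -> MetaboliteTable:
    """Hand-built 3-metabolite x 8-sample table (one group, 4 ZTs x 2 reps)."""
    meta = pd.DataFrame({
        "sample_id": [f"LD_ZT{z}_r{r}" for z in (0, 6, 12, 18) for r in (1, 2)],
        "group": ["LD"] * 8,
        "zt": [z for z in (0.0, 6.0, 12.0, 18.0) for _ in (1, 2)],
        "replicate": [r for _ in range(4) for r in (1, 2)],
    }).set_index("sample_id")
    t = meta["zt"].to_numpy()
    rows = {
        "rhythmic": 10 + 3 * np.cos(2 * np.pi * (t - 12) / 24),
        "flat": np.full(8, 5.0),
        "noisy": np.array([4.1, 5.2, 3.9, 6.1, 5.5, 4.4, 5.0, 4.8]),
    }
    abundance = pd.DataFrame(rows, index=meta.index).T
    return MetaboliteTable(abundance, meta)
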