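import numpy as np
import pytest

from tnbcscm.cohort import CohortConfig, generate_cohort
from tnbcscm.pipeline import build_feature_space


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A small cohort keeping the published class mix and view structure."""
    return CohortConfig(
        n_samples=150,
        view_widths={"isoform": 120, "mirna": 15, "methyl_450": 30, "methyl_27": 12},
        shared_methyl_probes=6,
        isoforms_per_gene=3,
        n_planted_down=4,
        n_planted_up=2,
        effect_size=2.5,
        missing_rate=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_feature_space(small_cohort):
    cohort, _ = small_cohort
    return build_feature_space(cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
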