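import numpy as np
import pandas as pd
import pytest

from csfgwas import pipeline, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-effect cohort reused across pipeline-level tests."""
    cfg = synthetic.SimConfig(
        n_samples=500,
        n_snps=300,
        maf_range=(0.1, 0.5),
        snp_effects=[synthetic.SnpEffect(150, 1, -0.9)],
        seed=21,
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def structured_panel_cohort():
    """Cohort at the biomarker-sample size with the canonical factor structure."""
    cfg = synthetic.SimConfig(n_samples=1158, n_snps=2, seed=3)
    return synthetic.simulate_cohort(cfg)


def sex_covariates(cohort) -> pd.DataFrame:
    """Age/ancestry/study covariates plus diagnosis dummies."""
    return pd.concat(
        [
            cohort.covariates().reset_index(drop=True),
            pipeline._diag_dummies(cohort.diagnosis),
        ],
        axis=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
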