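import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import collidermr as cmr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_data() -> cmr.IndividualData:
    """A modest IVW-scenario dataset shared by fast structural tests."""
    cfg = cmr.preset("ivw", n=3000, k=10, seed=42)
    return cmr.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_summary(small_data) -> cmr.ColliderSummary:
    return cmr.collider_summary(small_data)


@pytest.fixture
def tiny_summary() -> cmr.ColliderSummary:
    """A hand-sized 3-SNP summary for closed-form oracle checks."""
    return cmr.ColliderSummary(
        snp_ids=["g1", "g2", "g3"],
        beta_xg=np.array([0.1, 0.2, 0.3]),
        se_xg=np.array([0.01, 0.01, 0.01]),
        alpha_star=np.array([0.05, 0.08, 0.16]),
        se_alpha_star=np.array([0.01, 0.01, 0.01]),
        beta_star=1.0,
        se_beta_star=0.05,
        n=1000,
        k=3,
    )
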