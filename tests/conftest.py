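import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsmr import (
    HarmonizationConfig,
    HarmonizedDataset,
    HarmonizedInstrument,
    harmonize,
    load_lst_dr_instruments,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: harmonization policy for the packaged pre-screened instrument set
KEEP_CFG = HarmonizationConfig(palindrome_policy="keep")
#: permissive policy for simulator output (instruments are valid by construction)
PERMISSIVE_CFG = HarmonizationConfig(palindrome_policy="keep", pval_threshold=1.0)


@pytest.fixture(scope="session")
def lst_dr_tables():
    return load_lst_dr_instruments()


@pytest.fixture(scope="session")
def lst_dr_dataset(lst_dr_tables):
    exposure, outcome = lst_dr_tables
    return harmonize(exposure, outcome, KEEP_CFG)


def random_dataset(seed, L=8, ratio_scale=0.5):
    """Small random harmonized dataset for oracle/property checks."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 1.0, L) * rng.choice([-1.0, 1.0], L)
    sg = rng.uniform(0.01, 0.2, L)
    G = ratio_scale * g + rng.normal(0, 0.1, L)
    sG = rng.uniform(0.01, 0.5, L)
    return HarmonizedDataset(
        instruments=[
            HarmonizedInstrument(
                rsid=f"rs{j}",
                beta_exp=float(g[j]),
                se_exp=float(sg[j]),
                beta_out=float(G[j]),
                se_out=float(sG[j]),
            )
            for j in range(L)
        ]
    )
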