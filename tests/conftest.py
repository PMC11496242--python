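import numpy as np
import pandas as pd
import pytest

from triomr.simulate import SimConfig, simulate_trios


@pytest.fixture(scope="session")
def base_config() -> SimConfig:
    return SimConfig(seed=11, n=4000)


@pytest.fixture(scope="session")
def base_cohort(base_config):
    return simulate_trios(base_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_sumstats(snps, eas, neas, betas, ses, **extra) -> pd.DataFrame:
    n = len(snps)
    base = dict(
        SNP=snps,
        CHR=[1] * n,
        BP=list(range(1000, 1000 + n)),
        EA=eas,
        NEA=neas,
        EAF=[0.3] * n,
        BETA=betas,
        SE=ses,
        P=[1e-9] * n,
        N=[10_000] * n,
    )
    base.update(extra)
    return pd.DataFrame(base)
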