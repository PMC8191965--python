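import numpy as np
import pandas as pd
import pytest

import wellcount as wc


@pytest.fixture(scope="session")
def fixture_z() -> pd.DataFrame:
    """The deterministic 579-respondent domain-sufficiency table."""
    return wc.sa2020_fixture()


@pytest.fixture(scope="session")
def default_cfg() -> wc.GeneratorConfig:
    """Calibrated study-condition generator config (shared; treat as read-only)."""
    return wc.default_config(seed=0)


def profiles_from_z(z: pd.DataFrame, covariates: pd.DataFrame | None = None,
                    k: int | None = None) -> wc.WellbeingProfiles:
    """Wrap a 0/1 domain-sufficiency table as WellbeingProfiles."""
    summary = wc.classify_overall(z, k=k)
    if k is None:
        k = wc.domain_threshold(len(z.columns))
    return wc.WellbeingProfiles(
        domain_scores=z.copy(),
        domain_sufficiency=z,
        summary=summary,
        k=k,
        covariates=pd.DataFrame(index=z.index) if covariates is None else covariates,
    )


def random_sufficiency(rng: np.random.Generator, n: int, d: int) -> pd.DataFrame:
    cols = [f"D{j}" for j in range(d)]
    return pd.DataFrame(rng.integers(0, 2, size=(n, d)), columns=cols)
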