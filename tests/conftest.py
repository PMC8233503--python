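import numpy as np
import pytest

from jafsim import DemographyParams, SampleConfig


@pytest.fixture(scope="session")
def baseline_im() -> DemographyParams:
    """The baseline recent-divergence IM scenario: equal-size ancestral
    population splitting 0.05 x 4 N_REF generations ago into populations of
    relative size 1 and 0.25 with symmetric migration M = 4."""
    return DemographyParams(nu1=1.0, nu2=0.25, t_s=0.05, m12=4.0, m21=4.0)


@pytest.fixture(scope="session")
def small_cfg() -> SampleConfig:
    return SampleConfig(n1=10, n2=10, n_loci=100_000)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
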