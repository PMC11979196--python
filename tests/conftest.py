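import numpy as np
import pytest

from cgfiboot import parse_model, sample_covariance, synthetic


@pytest.fixture(scope="session")
def one_factor_spec7():
    return parse_model("L =~ q1 + q2 + q3 + q4 + q5 + q6 + q7")


@pytest.fixture(scope="session")
def small_continuous():
    """7-item one-factor continuous data at the small-sample scenario."""
    pop = synthetic.small_scale_scenario(seed=101)
    return pop, synthetic.generate_continuous(pop)


@pytest.fixture(scope="session")
def small_moments(small_continuous):
    _, data = small_continuous
    return sample_covariance(data)


@pytest.fixture(scope="session")
def exact_one_factor_moments():
    """Moments that exactly equal a one-factor implied matrix (k=7)."""
    from cgfiboot.moments import SampleMoments

    lam = np.full(7, 0.7)
    sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
    return SampleMoments(
        matrix=sigma, names=[f"q{i}" for i in range(1, 8)],
        n_effective=193, kind="covariance",
    )
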