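import numpy as np
import pytest

from ginarchart import ChartSpec, GINARParams

#: parameters of the worked monitoring example used throughout: counts
#: with geometric marginal mean 0.5872 and lag-1 autocorrelation 0.165
P_ILLUS = 0.63
RHO_ILLUS = 0.165
UCL_ILLUS = 5


@pytest.fixture(scope="session")
def illus_params() -> GINARParams:
    return GINARParams(p=P_ILLUS, rho=RHO_ILLUS)


@pytest.fixture(scope="session")
def illus_chart() -> ChartSpec:
    return ChartSpec(U=UCL_ILLUS, init=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230302)


def convolution_transition_prob(i: int, j: int, params: GINARParams) -> float:
    """Brute-force oracle for the one-step transition probability.

    Convolves the binomial(i, rho) survivor count with the innovation
    pmf directly — no closed form involved.
    """
    from scipy import stats

    from ginarchart import innovation_pmf

    p, rho = params.p, params.rho
    total = 0.0
    for m in range(min(i, j) + 1):
        total += stats.binom.pmf(m, i, rho) * innovation_pmf(j - m, params)
    return total
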