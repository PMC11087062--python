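import numpy as np
import pytest

from svyboot import FinitePopulation, TwoStageSample


def make_srswor_sample(N, M, m, y, design="srswor", pi1=None, p1=None):
    """Build a two-stage sample with SRSWOR-style probabilities filled in."""
    n = len(M)
    M = np.asarray(M, dtype=int)
    m = np.asarray(m, dtype=int)
    if pi1 is None:
        pi1 = np.full(n, n / N)
    if p1 is None:
        p1 = np.full(n, 1.0 / N)
    return TwoStageSample(
        design=design,
        psu_index=np.arange(n),
        M=M,
        m=m,
        y=[np.asarray(v, dtype=float) for v in y],
        elem_index=[np.arange(int(mi)) for mi in m],
        pi1=np.asarray(pi1, dtype=float),
        p1=np.asarray(p1, dtype=float),
        N=N,
        M0=int(M.sum()) if N == len(M) else int(round(M.mean() * N)),
    )


@pytest.fixture
def tiny_sample():
    """n=2 of N=6 psus, M_i=4, m_i=2: the minimal enumeration fixture."""
    return make_srswor_sample(
        N=6, M=[4, 4], m=[2, 2], y=[[1.0, 3.0], [2.0, 7.0]]
    )


@pytest.fixture
def sample3():
    """n=3 of N=6 psus with integer mirror-match constants."""
    return make_srswor_sample(
        N=6, M=[4, 4, 4], m=[2, 2, 2], y=[[1.0, 3.0], [2.0, 7.0], [0.0, 5.0]]
    )


@pytest.fixture
def constant_sample():
    """Equal-size psus with constant y: every variance estimator must be 0."""
    return make_srswor_sample(
        N=8, M=[5, 5, 5], m=[2, 2, 2], y=[[4.0, 4.0]] * 3
    )


@pytest.fixture
def toy_pop():
    rng = np.random.default_rng(42)
    sizes = rng.integers(3, 8, size=12)
    y = [rng.normal(10.0, 2.0, size=int(s)) for s in sizes]
    return FinitePopulation(psu_sizes=sizes, y=y, rho=0.0)
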