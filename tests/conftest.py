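import math

import numpy as np
import pytest

from redtia.cohort_simulation import CohortDistribution, LognormalSpec
from redtia.config import population_kinetics_from_mapping


def make_dist(
    structure: str,
    T_eff_h: float,
    C_MBq: float,
    bi_fraction: float = 0.3,
    s_lambda: float = 0.3,
    s_C: float = 0.5,
    uptake_T_h: float = 2.0,
) -> CohortDistribution:
    """Plausible per-structure cohort distribution for simulation tests."""
    lam = math.log(2) / T_eff_h

    def spec(mu, s):
        if s == 0:
            return LognormalSpec(0.0, mu, mu, mu)
        return LognormalSpec(s, mu, mu * math.exp(-3.5 * s), mu * math.exp(3.5 * s))

    mono = {"C": spec(C_MBq, s_C), "lambda1": spec(lam, s_lambda)}
    bi = {**mono, "lambda2": spec(math.log(2) / uptake_T_h, s_lambda)}
    n_bi = int(round(bi_fraction * 10))
    labels = tuple(["mono"] * (10 - n_bi) + ["bi"] * n_bi)
    return CohortDistribution(structure, labels, mono, bi if n_bi else None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pop_kinetics():
    return population_kinetics_from_mapping()


@pytest.fixture
def default_dists():
    """Four-structure distribution set matching the package defaults."""
    return {
        "kidney": make_dist("kidney", 50.0, 90.0),
        "healthy_liver": make_dist("healthy_liver", 65.0, 250.0),
        "spleen": make_dist("spleen", 70.0, 120.0),
        "tumor": make_dist("tumor", 90.0, 60.0),
    }


@pytest.fixture
def mono_only_dists():
    """Zero-spread, mono-only cohort: every curve identical, errors must vanish."""
    return {
        "kidney": make_dist("kidney", 50.0, 90.0, bi_fraction=0.0, s_lambda=0.0, s_C=0.0),
        "tumor": make_dist("tumor", 90.0, 60.0, bi_fraction=0.0, s_lambda=0.0, s_C=0.0),
    }
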