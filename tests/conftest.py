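import numpy as np
import pytest

from demvar import (
    MixingDistribution,
    absorbing_chain,
    assemble_fertvec,
    assemble_transitions,
    decompose,
    fundamental,
    initial_stage_slice,
    longevity_moments,
    lro_moments,
    poisson_rewards,
    random_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def analytic_decomposition(model, pi, j, outcome):
    """Full pipeline: model -> variance decomposition (shared test helper)."""
    Ut = assemble_transitions(model)
    if outcome == "longevity":
        mom = longevity_moments(fundamental(Ut))
    else:
        mom = lro_moments(absorbing_chain(Ut), poisson_rewards(assemble_fertvec(model)))
    m, v = initial_stage_slice(mom, j, model.g)
    mix = MixingDistribution(pi=pi, j=j)
    return decompose(mix, m, v, outcome=outcome), mom


def random_pi(g, rng):
    p = rng.random(g) + 0.1
    return p / p.sum()


@pytest.fixture
def small_model():
    return random_model(3, 2, seed=7)


@pytest.fixture
def fixed_model():
    return random_model(3, 2, seed=11, fixed_heterogeneity=True)
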