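"""Case-study builders and the seeded random-model generator."""

import numpy as np
import pytest

from demvar import (
    FireEnvironmentConfig,
    MixingDistribution,
    WeibullFrailtyConfig,
    assemble_transitions,
    decompose,
    env_stationary,
    fire_environment_matrix,
    fire_model,
    fundamental,
    initial_stage_slice,
    longevity_moments,
    random_model,
    weibull_frailty_model,
)
from demvar.casemodels import load_builtin_config


class TestWeibullFrailty:
    def test_exponential_special_case_has_constant_hazard(self):
        # shape b=1: memoryless, sigma = exp(-1/a) at every age
        cfg = WeibullFrailtyConfig(a=[10.0], b=[1.0], age_cap=300, truncation_tol=1e-9)
        model = weibull_frailty_model(cfg)
        sigma = np.exp(-model.mu_list[0])
        assert np.allclose(sigma, np.exp(-0.1), atol=1e-12)

    def test_exponential_longevity_matches_geometric_closed_form(self):
        cfg = WeibullFrailtyConfig(a=[10.0], b=[1.0], age_cap=400, truncation_tol=1e-12)
        model = weibull_frailty_model(cfg)
        mom = longevity_moments(fundamental(assemble_transitions(model)))
        m, _ = initial_stage_slice(mom, 1, 1)
        # geometric with survival exp(-0.1), lightly truncated at the age cap
        assert np.isclose(m[0], 1.0 / (1.0 - np.exp(-0.1)), rtol=1e-6)

    def test_discretization_preserves_integer_age_survivorship(self):
        """Cumulative product of per-day survivals equals the Weibull
        survivorship exp(-(t/a)^b) exactly at integer ages."""
        cfg = WeibullFrailtyConfig(a=[12.0, 30.0], b=[0.8, 2.3])
        with pytest.warns(UserWarning, match="age cap"):  # heavy-tailed b<1 group
            model = weibull_frailty_model(cfg)
        for i, (a, b) in enumerate([(12.0, 0.8), (30.0, 2.3)]):
            surv = np.cumprod(np.exp(-model.mu_list[i]))
            t = np.arange(1, model.s + 1, dtype=float)
            assert np.allclose(surv, np.exp(-((t / a) ** b)), rtol=1e-12)

    def test_age_cap_warning(self):
        cfg = WeibullFrailtyConfig(a=[50.0], b=[1.0], age_cap=30)
        with pytest.warns(UserWarning, match="age cap"):
            model = weibull_frailty_model(cfg)
        assert model.s == 30

    def test_age_structure_is_subdiagonal_shift(self):
        cfg = WeibullFrailtyConfig(a=[8.0], b=[1.5])
        model = weibull_frailty_model(cfg)
        U = model.U_list[0]
        assert np.array_equal(U[np.triu_indices(model.s)], np.zeros(model.s * (model.s + 1) // 2))
        assert (np.diag(U, k=-1) > 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            WeibullFrailtyConfig(a=[-1.0], b=[1.0])
        with pytest.raises(ValueError):
            WeibullFrailtyConfig(a=[1.0], b=[1.0], truncation_tol=2.0)


class TestFireEnvironment:
    def test_matrix_structure_at_extremes(self):
        D1 = fire_environment_matrix(1.0)
        assert np.array_equal(D1[0], np.ones(4))  # every year burns
        D0 = fire_environment_matrix(0.0)
        # deterministic march to the last state, which is then absorbing
        start = np.array([1.0, 0.0, 0.0, 0.0])
        x = start
        for _ in range(3):
            x = D0 @ x
        assert np.array_equal(x, [0, 0, 0, 1])
        assert np.array_equal(D0 @ x, x)

    def test_stationary_distribution_closed_form(self):
        """Hand-solved stationary equations: pi = (r, r(1-r), r(1-r)^2,
        (1-r)^3), which sums to 1 algebraically."""
        for r in (0.2, 0.49, 0.77):
            pi = env_stationary(fire_environment_matrix(r))
            expected = np.array([r, r * (1 - r), r * (1 - r) ** 2, (1 - r) ** 3])
            assert np.allclose(pi, expected, atol=1e-12)
            assert np.allclose(fire_environment_matrix(r) @ pi, pi, atol=1e-12)

    def test_stationary_at_r1_is_pure_fire(self):
        assert np.allclose(env_stationary(fire_environment_matrix(1.0)), [1, 0, 0, 0], atol=1e-12)

    def test_stationary_requires_unique_eigenvector(self):
        with pytest.raises(ValueError, match="stationary"):
            env_stationary(np.eye(3))

    def test_fire_model_column_sums_are_stage_survivals(self):
        """Column sums of the assembled joint matrix equal the survival of
        the departing stage in the departing environment (group dynamics
        conserve individuals)."""
        cfg = FireEnvironmentConfig.from_dict(load_builtin_config("fire"), r=0.3)
        model = fire_model(cfg)
        Ut = assemble_transitions(model)
        colsum = Ut.sum(axis=0)
        for j in range(model.s):
            for i in range(model.g):
                assert np.isclose(
                    colsum[model.state_index(j + 1, i + 1)], cfg.sigma[i][j], atol=1e-12
                )

    def test_fire_frequency_bounds(self):
        with pytest.raises(ValueError):
            fire_environment_matrix(1.2)


class TestRandomModel:
    def test_seed_determinism(self):
        a = random_model(3, 2, seed=123)
        b = random_model(3, 2, seed=123)
        for Ua, Ub in zip(a.U_list, b.U_list):
            assert np.array_equal(Ua, Ub)
        for fa, fb in zip(a.fert_list, b.fert_list):
            assert np.array_equal(fa, fb)

    def test_fixed_heterogeneity_flag(self):
        m = random_model(2, 3, seed=5, fixed_heterogeneity=True)
        for D in m.D_list:
            assert np.array_equal(D, np.eye(3))
        m2 = random_model(2, 3, seed=5, with_fertility=False)
        assert m2.fert_list is None

    def test_generated_models_satisfy_invariants(self):
        # construction runs full validation; sweep a spread of shapes/seeds
        for seed in range(250):
            m = random_model(1 + seed % 4, 1 + (seed // 4) % 4, seed=seed)
            for U in m.U_list:
                assert U.sum(axis=0).max() <= 0.95 + 1e-12
                assert U.min() >= 0


def test_builtin_configs_are_labelled_synthetic():
    for name in ("fruitfly", "fire"):
        d = load_builtin_config(name)
        assert "SYNTHETIC" in d["provenance"]


def test_fruitfly_builder_full_pipeline_runs():
    d = load_builtin_config("fruitfly")
    cfg = WeibullFrailtyConfig.from_dict(d)
    model = weibull_frailty_model(cfg)
    assert model.g == 6 and model.s <= cfg.age_cap
    mom = longevity_moments(fundamental(assemble_transitions(model)))
    m, v = initial_stage_slice(mom, 1, model.g)
    dec = decompose(MixingDistribution(pi=cfg.pi, provenance="estimated"), m, v)
    assert dec.expectation > 1 and dec.Vw > 0 and dec.Vb > 0 and 0 < dec.K < 1
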