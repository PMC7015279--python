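"""Analytic gradients of the variance components against independent oracles."""

import numpy as np
import pytest

from demvar import (
    MixingDistribution,
    fd_gradient,
    k_gradient,
    longevity_sensitivity,
    lro_fertility_sensitivity,
    lro_mortality_sensitivity,
    random_model,
    variance_gradients,
)
from tests.conftest import analytic_decomposition, random_pi


def target_value(model, pi, j, outcome, target):
    dec, _ = analytic_decomposition(model, pi, j, outcome)
    return {"Vw": dec.Vw, "Vb": dec.Vb, "K": dec.K}[target]


def fd_check(model, pi, j, outcome, parameter, group, tol=1e-5):
    """Max relative error of all three gradients vs central differences."""
    mix = MixingDistribution(pi=pi, j=j)
    if parameter == "mortality":
        op = longevity_sensitivity if outcome == "longevity" else lro_mortality_sensitivity
    else:
        op = lro_fertility_sensitivity
    res = op(model, mix, j, group=group)
    worst = 0.0
    for target in ("Vw", "Vb", "K"):
        if parameter == "mortality":
            base = model.mu_list[0 if group == "all" else group - 1]

            def f(theta):
                if group == "all":
                    mdl = model.with_hazard([mu + (theta - base) for mu in model.mu_list])
                else:
                    mdl = model.with_hazard([theta], group=group)
                return target_value(mdl, pi, j, outcome, target)

        else:
            base = model.fert_list[0 if group == "all" else group - 1]

            def f(theta):
                if group == "all":
                    mdl = model.with_fertility([fv + (theta - base) for fv in model.fert_list])
                else:
                    mdl = model.with_fertility([theta], group=group)
                return target_value(mdl, pi, j, outcome, target)

        fd = fd_gradient(f, np.asarray(base, dtype=float))
        an = res[target].gradient
        denom = max(np.abs(fd).max(), np.abs(an).max(), 1e-12)
        worst = max(worst, float(np.abs(an - fd).max() / denom))
    assert worst < tol, f"{outcome}/{parameter}/group={group}: rel err {worst:.2e}"
    return worst


def test_variance_gradient_heads():
    # single group: no between-group variance, so dVb/dm = 0
    _, dVb = variance_gradients(np.array([1.0]), np.array([5.0]), np.array([1.0]))
    assert np.array_equal(dVb, [0.0])
    # hand-differentiated two-point case
    _, dVb = variance_gradients(np.array([0.5, 0.5]), np.array([0.0, 2.0]), np.zeros(2))
    assert np.allclose(dVb, [-1.0, 1.0], atol=1e-14)
    # dVw/dv is always pi itself
    pi = np.array([0.2, 0.3, 0.5])
    dVw, _ = variance_gradients(pi, np.ones(3), np.ones(3))
    assert np.array_equal(dVw, pi)


class TestKGradient:
    def test_limits(self):
        # K = 0 (Vb = 0): dK = dVb / (Vb + Vw)
        dK = k_gradient(0.0, 0.0, 2.0, np.array([1.0]), np.array([5.0]))
        assert np.allclose(dK, [0.5])
        # flat components: flat K
        assert np.allclose(k_gradient(0.3, 1.0, 2.0, np.zeros(2), np.zeros(2)), 0.0)
        with pytest.raises(ValueError):
            k_gradient(0.0, 0.0, 0.0, np.zeros(1), np.zeros(1))

    def test_quotient_form_matches_fd_along_parameter_path(self, rng):
        """K(theta) composed from smooth Vb(theta), Vw(theta): the analytic
        combination must match central differences; the (1+K)-coefficient
        variant must not (it fails whenever Vb > 0)."""
        A = rng.random((2, 3))
        b = rng.random(2) + 0.5

        def components(theta):
            z = A @ theta + b
            return z[0] ** 2, z[1] ** 2  # Vb, Vw > 0

        theta0 = rng.random(3)

        def K_of(theta):
            Vb, Vw = components(theta)
            return Vb / (Vb + Vw)

        Vb, Vw = components(theta0)
        K = Vb / (Vb + Vw)
        dVb = fd_gradient(lambda t: components(t)[0], theta0)
        dVw = fd_gradient(lambda t: components(t)[1], theta0)
        fd_K = fd_gradient(K_of, theta0)
        good = k_gradient(K, Vb, Vw, dVb, dVw, form="quotient")
        bad = k_gradient(K, Vb, Vw, dVb, dVw, form="as-printed")
        assert np.allclose(good, fd_K, rtol=1e-6, atol=1e-9)
        assert not np.allclose(bad, fd_K, rtol=1e-3, atol=1e-6)


@pytest.mark.parametrize("fixed", [True, False], ids=["fixed-het", "dynamic-het"])
@pytest.mark.parametrize(
    "outcome,parameter",
    [("longevity", "mortality"), ("lro", "mortality"), ("lro", "fertility")],
)
def test_gradients_match_finite_differences(outcome, parameter, fixed, rng):
    for seed in range(4):
        model = random_model(3, 2, seed=300 + seed, fixed_heterogeneity=fixed)
        pi = random_pi(2, rng)
        for group in (1, 2, "all"):
            fd_check(model, pi, 1, outcome, parameter, group)


def test_gradients_from_later_initial_stage(rng):
    model = random_model(4, 2, seed=91)
    pi = random_pi(2, rng)
    fd_check(model, pi, 3, "longevity", "mortality", "all")
    fd_check(model, pi, 3, "lro", "fertility", 1)


@pytest.mark.parametrize(
    "outcome,parameter",
    [("longevity", "mortality"), ("lro", "mortality"), ("lro", "fertility")],
)
def test_all_groups_gradient_is_sum_of_per_group(outcome, parameter, rng):
    model = random_model(3, 3, seed=55)
    mix = MixingDistribution(pi=random_pi(3, rng))
    if parameter == "mortality":
        op = longevity_sensitivity if outcome == "longevity" else lro_mortality_sensitivity
    else:
        op = lro_fertility_sensitivity
    total = op(model, mix, 1, group="all")
    for target in ("Vw", "Vb", "K"):
        summed = sum(op(model, mix, 1, group=i)[target].gradient for i in (1, 2, 3))
        assert np.allclose(total[target].gradient, summed, atol=1e-10)


def test_zero_mixing_weight_zeroes_gradients_under_fixed_heterogeneity():
    """A group no individual starts in (and, heterogeneity being fixed, can
    never enter) cannot influence the variance components."""
    model = random_model(3, 3, seed=77, fixed_heterogeneity=True)
    mix = MixingDistribution(pi=[0.5, 0.5, 0.0])
    for op in (longevity_sensitivity, lro_mortality_sensitivity, lro_fertility_sensitivity):
        res = op(model, mix, 1, group=3)
        for target in ("Vw", "Vb", "K"):
            assert np.allclose(res[target].gradient, 0.0, atol=1e-12), (op, target)


def test_survival_scale_gradients(rng):
    """sigma = exp(-mu): gradients on the survival scale must equal
    -grad_mu / sigma, and match FD with respect to sigma directly."""
    model = random_model(3, 2, seed=42)
    pi = random_pi(2, rng)
    mix = MixingDistribution(pi=pi)
    res_mu = longevity_sensitivity(model, mix, 1, group=1)
    res_sg = longevity_sensitivity(model, mix, 1, group=1, scale="survival")
    sigma = np.exp(-model.mu_list[0])
    assert np.allclose(res_sg["Vw"].gradient, -res_mu["Vw"].gradient / sigma, atol=1e-12)

    def f(sg):
        mdl = model.with_hazard([-np.log(sg)], group=1)
        return target_value(mdl, pi, 1, "longevity", "Vw")

    fd = fd_gradient(f, sigma)
    assert np.allclose(res_sg["Vw"].gradient, fd, rtol=1e-5, atol=1e-8)


def test_requires_hazard_parameterization():
    from demvar import StageGroupModel

    model = StageGroupModel(
        s=1, g=1, U_list=[np.array([[0.5]])], D_list=[np.eye(1)], fert_list=[np.ones(1)]
    )
    with pytest.raises(ValueError, match="hazard"):
        longevity_sensitivity(model, MixingDistribution(pi=[1.0]), 1)
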