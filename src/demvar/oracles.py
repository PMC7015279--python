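"""Independent verification machinery.

Two oracles, deliberately dumb and independent of the analytic code paths:

* :func:`simulate_cohort` — individual-based simulation of the absorbing
  chain, with per-step Poisson reproduction, giving sample moments of
  longevity and lifetime reproductive output;
* :func:`fd_gradient` — central finite differences of any scalar functional
  of a parameter vector, used to cross-validate every analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multistate import AbsorbingChain
from .outcomes import RewardModel

__all__ = ["SimulationResult", "simulate_cohort", "fd_gradient"]


@dataclass
class SimulationResult:
    """Sample moments of a simulated cohort."""

    outcome: str
    n: int
    seed: int
    mean: float
    variance: float
    se_mean: float
    se_variance: float
    group_means: np.ndarray | None = None
    group_variances: np.ndarray | None = None

    def z_mean(self, analytic: float) -> float:
        return (self.mean - analytic) / self.se_mean

    def z_variance(self, analytic: float) -> float:
        return (self.variance - analytic) / self.se_variance


def _sample_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    n = x.size
    mean = float(x.mean())
    var = float(x.var(ddof=1)) if n > 1 else 0.0
    se_mean = float(np.sqrt(var / n)) if n > 1 else np.inf
    # SE of the sample variance from the fourth central moment
    if n > 1:
        m4 = float(((x - mean) ** 4).mean())
        se_var = float(np.sqrt(max(m4 - var**2 * (n - 3) / (n - 1), 0.0) / n))
        se_var = max(se_var, 1e-300)
    else:
        se_var = np.inf
    return mean, var, se_mean, se_var


def simulate_cohort(
    chain: AbsorbingChain,
    rewards: RewardModel | None,
    j: int,
    g: int,
    start,
    n: int = 100_000,
    seed: int = 0,
    max_steps: int = 100_000,
) -> SimulationResult:
    """Simulate n individuals from stage j until absorption.

    ``start`` is either a 1-based group index (degenerate start) or a
    length-g probability vector over groups.  Longevity counts occupancies
    of live states (so it is at least 1); LRO sums Poisson draws with the
    per-state means of ``rewards`` over every occupied live state.  Returns
    LRO statistics when ``rewards`` is given, longevity otherwise.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    gs = chain.gs
    dead = gs  # absorbing state index
    cum = np.cumsum(chain.P, axis=0)  # column-wise cumulative transition law

    if np.isscalar(start):
        groups = np.full(n, int(start) - 1)
    else:
        p = np.asarray(start, dtype=float).ravel()
        groups = rng.choice(p.size, size=n, p=p / p.sum())
    state = (j - 1) * g + groups

    longevity = np.zeros(n, dtype=np.int64)
    lro = np.zeros(n, dtype=np.float64)
    f = rewards.ftilde if rewards is not None else None
    if rewards is not None and f is None:
        raise ValueError("simulation requires a per-state mean reward vector")

    alive = np.arange(n)
    for _ in range(max_steps):
        longevity[alive] += 1
        if f is not None:
            means = f[state[alive]]
            nz = means > 0
            if nz.any():
                draws = np.zeros(alive.size)
                draws[nz] = rng.poisson(means[nz])
                lro[alive] += draws
        u = rng.random(alive.size)
        # column state[k] of cum is the cdf of the next state
        nxt = (u[None, :] > cum[:, state[alive]]).sum(axis=0)
        state[alive] = nxt
        alive = alive[nxt != dead]
        if alive.size == 0:
            break
    else:
        raise RuntimeError("individuals still alive after max_steps; chain nearly non-absorbing")

    outcome = "lro" if rewards is not None else "longevity"
    x = lro if rewards is not None else longevity.astype(float)
    mean, var, se_m, se_v = _sample_moments(x)

    gm = gv = None
    if not np.isscalar(start):
        gm = np.full(groups.max() + 1, np.nan)
        gv = np.full(groups.max() + 1, np.nan)
        for i in range(gm.size):
            xi = x[groups == i]
            if xi.size > 1:
                gm[i], gv[i] = xi.mean(), xi.var(ddof=1)
    return SimulationResult(
        outcome=outcome,
        n=n,
        seed=seed,
        mean=mean,
        variance=var,
        se_mean=se_m,
        se_variance=se_v,
        group_means=gm,
        group_variances=gv,
    )


def fd_gradient(func, theta0: np.ndarray, h: float | None = None) -> np.ndarray:
    """Central-difference gradient of a scalar function of a vector.

    Step per coordinate: ``max(1e-6, 1e-6 |theta_k|)`` unless ``h`` given.
    """
    theta0 = np.asarray(theta0, dtype=float).ravel()
    grad = np.empty_like(theta0)
    for k in range(theta0.size):
        hk = h if h is not None else max(1e-6, 1e-6 * abs(theta0[k]))
        up = theta0.copy()
        dn = theta0.copy()
        up[k] += hk
        dn[k] -= hk
        grad[k] = (func(up) - func(dn)) / (2.0 * hk)
    return grad
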