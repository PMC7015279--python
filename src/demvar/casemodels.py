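"""Case-study model builders and a seeded random-model generator.

Two classes of worked models are provided:

* an **age-by-frailty** model: age-classified survival with a finite
  mixture of Weibull mortality schedules, one per latent frailty group
  (fixed heterogeneity), for longevity analysis;
* a **stage-by-environment** model: a stage-classified plant life cycle in
  a stochastically varying fire environment that follows its own Markov
  chain (dynamic heterogeneity), for lifetime-reproductive-output analysis.

The numerical vital rates for the published case studies are not printed in
any main text and are treated as replaceable inputs; the parameter files
shipped under ``demvar/data`` are clearly-labelled *synthetic stand-ins*
with the published structure (see their ``provenance`` fields).  The mixing
distributions and the fire-environment transition matrix are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import linalg

from .multistate import StageGroupModel

__all__ = [
    "WeibullFrailtyConfig",
    "FireEnvironmentConfig",
    "weibull_frailty_model",
    "fire_model",
    "fire_environment_matrix",
    "env_stationary",
    "random_model",
    "load_builtin_config",
]


def load_builtin_config(name: str) -> dict:
    """Load a packaged parameter file (``fruitfly`` or ``fire``)."""
    fname = {
        "fruitfly": "fruitfly_weibull_synthetic.json",
        "fire": "lomatium_fire_synthetic.json",
    }[name]
    with resources.files("demvar").joinpath("data", fname).open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Weibull frailty (age-classified, fixed heterogeneity)
# ---------------------------------------------------------------------------


@dataclass
class WeibullFrailtyConfig:
    """Mixture of Weibull mortality schedules over latent frailty groups.

    Group i has cumulative hazard H_i(t) = (t / a_i)^b_i (t in days);
    ``a`` are scales (days), ``b`` shapes.  ``dt`` is fixed at 1 day.  The
    age axis is truncated at the first age where every group's survivorship
    falls below ``truncation_tol``, capped at ``age_cap``.
    """

    a: np.ndarray
    b: np.ndarray
    pi: np.ndarray | None = None
    dt: float = 1.0
    age_cap: int = 200
    truncation_tol: float = 1e-10

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.a.size != self.b.size:
            raise ValueError("need one (a, b) pair per group")
        if (self.a <= 0).any() or (self.b <= 0).any():
            raise ValueError("Weibull parameters must be positive")
        if not 0 < self.truncation_tol < 1:
            raise ValueError("truncation tolerance must lie in (0, 1)")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float).ravel()

    @property
    def g(self) -> int:
        return self.a.size

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullFrailtyConfig":
        groups = d["groups"]
        return cls(
            a=[gr["a"] for gr in groups],
            b=[gr["b"] for gr in groups],
            pi=d.get("pi"),
            age_cap=d.get("age_cap", 200),
            truncation_tol=d.get("truncation_tol", 1e-10),
        )


def weibull_frailty_model(cfg: WeibullFrailtyConfig) -> StageGroupModel:
    """Age-by-frailty model with exact 1-day discretization of the hazard.

    The per-day hazard is the exact cumulative-hazard increment
    mu_i(x) = H_i(x+1) - H_i(x), so that survivorship to integer age t is
    exactly exp(-(t/a_i)^b_i).  Age transitions are a subdiagonal shift
    Y weighted by survival: U_i = Y o (1 sigma_i'); heterogeneity is fixed
    (D_j = I).
    """
    import warnings

    g = cfg.g
    H = lambda t, i: (t / cfg.a[i]) ** cfg.b[i]
    # smallest age where every group's survivorship < tol
    s = None
    for t in range(1, cfg.age_cap + 1):
        if all(np.exp(-H(t, i)) < cfg.truncation_tol for i in range(g)):
            s = t
            break
    if s is None:
        s = cfg.age_cap
        warnings.warn(
            f"age cap {cfg.age_cap} reached before survivorship fell below "
            f"{cfg.truncation_tol}; truncating there",
            stacklevel=2,
        )
    Y = np.diag(np.ones(s - 1), k=-1) if s > 1 else np.zeros((1, 1))
    ages = np.arange(s, dtype=float)
    G_list, mu_list, U_list = [], [], []
    for i in range(g):
        mu = H(ages + 1, i) - H(ages, i)
        sigma = np.exp(-mu)
        G_list.append(Y.copy())
        mu_list.append(mu)
        U_list.append(Y * sigma[None, :])
    return StageGroupModel(
        s=s,
        g=g,
        U_list=U_list,
        D_list=[np.eye(g)] * s,
        G_list=G_list,
        mu_list=mu_list,
        stage_labels=[f"age{x}" for x in range(s)],
        group_labels=[f"frailty{i+1}" for i in range(g)],
    )


# ---------------------------------------------------------------------------
# fire environment (stage-classified, dynamic heterogeneity)
# ---------------------------------------------------------------------------


def fire_environment_matrix(r: float) -> np.ndarray:
    """Markov chain over environments (fire year; 1, 2, >=3 years post-fire).

    Column-stochastic: a fire occurs each year with probability r from any
    state; otherwise time-since-fire advances (and saturates at the last
    state).
    """
    if not 0 <= r <= 1:
        raise ValueError("fire frequency r must lie in [0, 1]")
    return np.array(
        [
            [r, r, r, r],
            [1 - r, 0, 0, 0],
            [0, 1 - r, 0, 0],
            [0, 0, 1 - r, 1 - r],
        ]
    )


@dataclass
class FireEnvironmentConfig:
    """Stage-classified vital rates per fire environment.

    ``G`` holds g conditional stage-transition matrices (column-stochastic
    growth/stasis/retrogression), ``sigma`` g stage-survival vectors,
    ``fert`` g stage-fertility vectors; ``r`` is the annual fire frequency.
    """

    r: float
    G: list[np.ndarray]
    sigma: list[np.ndarray]
    fert: list[np.ndarray]
    stage_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = [np.asarray(G, dtype=float) for G in self.G]
        self.sigma = [np.asarray(x, dtype=float).ravel() for x in self.sigma]
        self.fert = [np.asarray(x, dtype=float).ravel() for x in self.fert]
        if not len(self.G) == len(self.sigma) == len(self.fert):
            raise ValueError("G, sigma, fert must have one entry per environment")
        for i, (G, sg) in enumerate(zip(self.G, self.sigma), start=1):
            if (np.abs(G.sum(axis=0) - 1) > 1e-9).any():
                raise ValueError(f"growth matrix G{i} is not column-stochastic")
            if (sg <= 0).any() or (sg > 1).any():
                raise ValueError(f"survival vector sigma{i} must lie in (0, 1]")

    @property
    def g(self) -> int:
        return len(self.G)

    @property
    def s(self) -> int:
        return self.G[0].shape[0]

    @classmethod
    def from_dict(cls, d: dict, r: float | None = None) -> "FireEnvironmentConfig":
        envs = d["environments"]
        return cls(
            r=d["r"] if r is None else r,
            G=[e["G"] for e in envs],
            sigma=[e["sigma"] for e in envs],
            fert=[e["fert"] for e in envs],
            stage_labels=d.get("stage_labels", []),
        )


def fire_model(cfg: FireEnvironmentConfig) -> StageGroupModel:
    """Stage-by-environment model: U_i = G_i Sigma_i, D_j = D(r) for all j."""
    D = fire_environment_matrix(cfg.r)
    mu_list = [-np.log(sg) for sg in cfg.sigma]
    U_list = [G @ np.diag(sg) for G, sg in zip(cfg.G, cfg.sigma)]
    return StageGroupModel(
        s=cfg.s,
        g=cfg.g,
        U_list=U_list,
        D_list=[D] * cfg.s,
        fert_list=[f.copy() for f in cfg.fert],
        G_list=[G.copy() for G in cfg.G],
        mu_list=mu_list,
        stage_labels=cfg.stage_labels or [f"stage{j+1}" for j in range(cfg.s)],
        group_labels=["fire", "post-fire 1y", "post-fire 2y", "post-fire 3y+"][: cfg.g]
        if cfg.g <= 4
        else [f"env{i+1}" for i in range(cfg.g)],
    )


def env_stationary(D_env: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Stationary distribution of a column-stochastic environment chain.

    The dominant right eigenvector of D, normalized to sum 1.  Raises if the
    eigenvalue 1 is not simple (reducible/periodic chain).
    """
    D_env = np.asarray(D_env, dtype=float)
    if (np.abs(D_env.sum(axis=0) - 1) > 1e-9).any():
        raise ValueError("environment matrix must be column-stochastic")
    vals, vecs = linalg.eig(D_env)
    near_one = np.abs(vals - 1.0) < tol
    if near_one.sum() != 1:
        raise ValueError(
            "environment chain lacks a unique stationary distribution "
            "(reducible or periodic)"
        )
    v = np.real(vecs[:, near_one].ravel())
    v = v / v.sum()
    if (v < -1e-12).any():
        raise ValueError("stationary eigenvector has negative entries")
    return np.clip(v, 0.0, None)


# ---------------------------------------------------------------------------
# random fixtures
# ---------------------------------------------------------------------------


def random_model(
    s: int,
    g: int,
    seed: int,
    fixed_heterogeneity: bool = False,
    with_fertility: bool = True,
) -> StageGroupModel:
    """Seeded random stage-by-group model satisfying all invariants.

    Column sums of each U_i are drawn in [0.2, 0.95]; D_j are random
    column-stochastic (or identity when ``fixed_heterogeneity``); fertility
    is uniform on [0, 2].  Identical seeds give identical models.
    """
    if s < 1 or g < 1:
        raise ValueError("s and g must be >= 1")
    rng = np.random.default_rng(seed)
    G_list, mu_list, U_list = [], [], []
    for _ in range(g):
        M = rng.random((s, s)) + 0.05
        G = M / M.sum(axis=0)
        surv = rng.uniform(0.2, 0.95, size=s)
        mu = -np.log(surv)
        G_list.append(G)
        mu_list.append(mu)
        U_list.append(G @ np.diag(surv))
    D_list = []
    for _ in range(s):
        if fixed_heterogeneity:
            D_list.append(np.eye(g))
        else:
            M = rng.random((g, g)) + 0.05
            D_list.append(M / M.sum(axis=0))
    fert = [rng.uniform(0.0, 2.0, size=s) for _ in range(g)] if with_fertility else None
    return StageGroupModel(
        s=s,
        g=g,
        U_list=U_list,
        D_list=D_list,
        fert_list=fert,
        G_list=G_list,
        mu_list=mu_list,
    )
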