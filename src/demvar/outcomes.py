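"""Moments of demographic outcomes on the joint stage-by-group chain.

Two outcomes are supported:

* **Longevity** — remaining lifetime (in time steps, counting the current
  one) of an individual in each joint state, from the fundamental matrix
  ``Ntilde = (I - Utilde)^{-1}``:

  eta1' = 1' Ntilde,    eta2' = eta1' (2 Ntilde - I),
  m = eta1,             v = eta2 - eta1 o eta1.

* **Lifetime reproductive output (LRO)** — reproduction treated as a random
  reward collected on every departure from a live state (occupancy-based:
  the reward is paid regardless of the destination, including death), with
  per-state first/second moment reward matrices R1, R2:

  rho1 = Ntilde' Z (P o R1)' 1,
  rho2 = Ntilde' [ Z (P o R2)' 1 + 2 (Utilde o Rhat1)' rho1 ],
  m = rho1,  v = rho2 - rho1 o rho1.

The default reward model is Poisson per-step reproduction with mean
``ftilde_j`` in state j, for which R2 = R1 + R1 o R1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .blockkit import structural_constants
from .multistate import AbsorbingChain

__all__ = [
    "OutcomeMoments",
    "RewardModel",
    "fundamental",
    "longevity_moments",
    "poisson_rewards",
    "lro_moments",
    "initial_stage_slice",
]

#: small negative variances from float cancellation are clamped to zero
VARIANCE_TOL = 1e-9


@dataclass
class OutcomeMoments:
    """First/second moments of an outcome for every joint state."""

    outcome: str  # "longevity" | "lro"
    mtilde: np.ndarray  # conditional means, length gs
    vtilde: np.ndarray  # conditional variances, length gs
    raw1: np.ndarray  # eta1 or rho1
    raw2: np.ndarray  # eta2 or rho2
    units: str = ""

    def __post_init__(self) -> None:
        if (self.vtilde < -VARIANCE_TOL).any():
            raise ValueError(
                f"negative conditional variance {self.vtilde.min():.3g} in {self.outcome}"
            )
        self.vtilde = np.clip(self.vtilde, 0.0, None)


@dataclass
class RewardModel:
    """Moment matrices of per-transition reproductive rewards.

    ``R1[i, j]`` / ``R2[i, j]`` are the first/second moments of the reward
    collected on the transition j -> i.  The dead column is zero: no rewards
    once absorbed.  ``Rhat1`` is the transient (live-to-live) submatrix of R1.
    ``ftilde`` is the per-state mean used by the Poisson builder (None for
    user-supplied moment matrices).
    """

    R1: np.ndarray
    R2: np.ndarray
    Rhat1: np.ndarray
    ftilde: np.ndarray | None = None
    kind: str = "poisson"

    def __post_init__(self) -> None:
        if np.abs(self.R1[:, -1]).max() > 0 or np.abs(self.R2[:, -1]).max() > 0:
            raise ValueError("dead individuals cannot collect rewards: last column must be 0")


def fundamental(Utilde: np.ndarray) -> np.ndarray:
    """Fundamental matrix ``Ntilde`` solving (I - Utilde) Ntilde = I.

    Entry (i, j) is the expected number of visits to state i by an
    individual now in state j, before death.  Computed by LU solves.
    """
    Utilde = np.asarray(Utilde, dtype=float)
    gs = Utilde.shape[0]
    A = np.eye(gs) - Utilde
    try:
        lu = lu_factor(A)
    except Exception as exc:  # pragma: no cover - scipy raises LinAlgError
        raise ValueError("I - Utilde is singular; chain is not absorbing") from exc
    if np.abs(np.diag(lu[0])).min() < 1e-13:
        raise ValueError("I - Utilde is numerically singular; spectral radius of Utilde ~ 1")
    N = lu_solve(lu, np.eye(gs))
    if N.min() < -1e-9:
        raise ValueError("fundamental matrix has negative entries; Utilde is not substochastic")
    return np.clip(N, 0.0, None)


def longevity_moments(Ntilde: np.ndarray) -> OutcomeMoments:
    """Mean and variance of remaining longevity for every joint state."""
    Ntilde = np.asarray(Ntilde, dtype=float)
    gs = Ntilde.shape[0]
    eta1 = Ntilde.T @ np.ones(gs)
    eta2 = (2.0 * Ntilde - np.eye(gs)).T @ eta1
    return OutcomeMoments(
        outcome="longevity",
        mtilde=eta1,
        vtilde=eta2 - eta1 * eta1,
        raw1=eta1,
        raw2=eta2,
        units="time steps",
    )


def poisson_rewards(ftilde: np.ndarray) -> RewardModel:
    """Reward moment matrices for Poisson per-step reproduction.

    Every transition out of live state j carries a Poisson reward with mean
    ``ftilde[j]``; hence R1 has ftilde' replicated down its live columns and
    R2 = R1 + R1 o R1 (Poisson second moment f + f^2).
    """
    f = np.asarray(ftilde, dtype=float).ravel()
    if (f < 0).any():
        raise ValueError("fertility must be nonnegative")
    gs = f.size
    Z, _, _ = structural_constants(gs)
    col_means = Z.T @ f  # length gs+1, dead entry 0
    R1 = np.ones((gs + 1, 1)) @ col_means[None, :]
    R2 = R1 + R1 * R1
    Rhat1 = Z @ R1 @ Z.T
    return RewardModel(R1=R1, R2=R2, Rhat1=Rhat1, ftilde=f, kind="poisson")


def lro_moments(chain: AbsorbingChain, rewards: RewardModel) -> OutcomeMoments:
    """Mean and variance of lifetime reproductive output for every state."""
    if chain.alpha != 1:
        raise NotImplementedError("LRO moments support a single absorbing state")
    U = chain.Utilde
    P = chain.P
    gs = U.shape[0]
    Z, _, _ = structural_constants(gs)
    N = fundamental(U)
    h1 = Z @ ((P * rewards.R1).T @ np.ones(gs + 1))
    rho1 = N.T @ h1
    h2 = Z @ ((P * rewards.R2).T @ np.ones(gs + 1))
    rho2 = N.T @ (h2 + 2.0 * (U * rewards.Rhat1).T @ rho1)
    return OutcomeMoments(
        outcome="lro",
        mtilde=rho1,
        vtilde=rho2 - rho1 * rho1,
        raw1=rho1,
        raw2=rho2,
        units="offspring",
    )


def initial_stage_slice(
    moments: OutcomeMoments, j: int, g: int
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional (m, v) over groups for a cohort initialized in stage j.

    Applies (e_j' kron I_g) to the joint moment vectors: with
    group-within-stage ordering this extracts the g consecutive entries of
    stage block j.
    """
    gs = moments.mtilde.size
    s = gs // g
    if not 1 <= j <= s:
        raise ValueError(f"initial stage {j} out of range 1..{s}")
    block = slice((j - 1) * g, j * g)
    return moments.mtilde[block].copy(), moments.vtilde[block].copy()
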