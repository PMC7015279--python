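"""Variance decomposition over heterogeneity groups.

Given conditional means m and variances v of an outcome (one entry per
group, for a cohort initialized in a chosen stage) and a mixing
distribution pi over groups, the law of total variance splits the cohort
variance into

* within-group variance  Vw = pi' v  — individual stochasticity: chance
  differences among individuals experiencing identical rates, and
* between-group variance Vb = pi' (m o m) - (pi' m)^2 — heterogeneity:
  differences in the rates themselves.

The intraclass correlation K = Vb / (Vb + Vw) is the fraction of variance
attributable to heterogeneity (0: outcome independent of group; 1: outcome
fully determined by group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MixingDistribution", "VarianceDecomposition", "decompose"]


@dataclass
class MixingDistribution:
    """Probability distribution over groups at the initial stage.

    ``provenance`` records where pi came from (estimated, stationary
    environment distribution, assumed uniform, ...), for reporting only.
    """

    pi: np.ndarray
    j: int = 1
    provenance: str = "assumed"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        if (self.pi < 0).any():
            raise ValueError("mixing distribution has negative entries")
        err = abs(self.pi.sum() - 1.0)
        if err > 1e-8:
            raise ValueError(
                f"mixing distribution sums to {self.pi.sum():.10g}; must sum to 1"
            )
        if err > 1e-12:
            warnings.warn(
                f"renormalizing mixing distribution (deviation {err:.2e})",
                stacklevel=2,
            )
            self.pi = self.pi / self.pi.sum()

    @property
    def g(self) -> int:
        return self.pi.size


@dataclass
class VarianceDecomposition:
    """Within/between variance split of a demographic outcome."""

    expectation: float
    Vw: float
    Vb: float
    K: float | None  # None when Vw + Vb == 0 (degenerate outcome)
    outcome: str = ""
    units: str = ""
    j: int = 1
    provenance: str = ""

    @property
    def V(self) -> float:
        return self.Vw + self.Vb

    @property
    def heterogeneity_pct(self) -> float | None:
        return None if self.K is None else 100.0 * self.K

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "initial_stage": self.j,
            "E": self.expectation,
            "Vw": self.Vw,
            "Vb": self.Vb,
            "V": self.V,
            "K": self.K,
            "heterogeneity_pct": self.heterogeneity_pct,
            "units": self.units,
            "pi_provenance": self.provenance,
        }


def decompose(
    mixing: MixingDistribution,
    m: np.ndarray,
    v: np.ndarray,
    outcome: str = "",
    units: str = "",
) -> VarianceDecomposition:
    """Split the cohort variance into within- and between-group components."""
    pi = mixing.pi
    m = np.asarray(m, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if m.size != pi.size or v.size != pi.size:
        raise ValueError(
            f"dimension mismatch: pi has {pi.size} groups, m {m.size}, v {v.size}"
        )
    E = float(pi @ m)
    Vw = float(pi @ v)
    Vb = float(pi @ (m * m) - E * E)
    if Vb < 0:
        if Vb < -1e-12 * max(1.0, E * E):
            raise ValueError(f"between-group variance {Vb:.3g} is negative beyond rounding")
        Vb = 0.0
    total = Vw + Vb
    K = None if total == 0.0 else Vb / total
    return VarianceDecomposition(
        expectation=E,
        Vw=Vw,
        Vb=Vb,
        K=K,
        outcome=outcome,
        units=units,
        j=mixing.j,
        provenance=mixing.provenance,
    )
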