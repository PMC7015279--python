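"""Analytic sensitivity of the variance components to vital rates.

Derivatives of the within-group variance Vw, the between-group variance Vb,
and the intraclass correlation K with respect to stage-specific mortality
hazards (per group, or all groups at once) and stage-specific fertilities.

Everything is computed as a chain of vector-Jacobian products (row-vector
pullbacks) along the dependency path

    pi, m, v  <-  (m~, v~)  <-  N~, R~1, R~2  <-  U~, f~  <-  U_i, f_i  <-  mu_i

so that no (gs)^2-by-(gs)^2 Jacobian is ever materialized; the largest
intermediate is a single row of length (gs)^2 (or (gs+1)^2 through the
reward matrices).  The scalar heads are::

    dVw/dv' = pi',
    dVb/dm' = 2 pi' D(m) - 2 (pi' m) pi',
    dK/dtheta' = ((1-K) dVb/dtheta' - K dVw/dtheta') / (Vb + Vw),

followed by the stage slice (e_j' kron I_g), the outcome Jacobians with
respect to N~ (longevity) or to U~, R~1, R~2 (lifetime reproductive
output), the vec-permutation assembly (K kron DK), the block placement
(Q_i' kron L_i), and finally the hazard parameterization
U_i = G_i D(exp(-mu_i)).

Mortality is parameterized on the hazard scale mu (sigma = exp(-mu));
``scale="survival"`` converts via d sigma / d mu = -D(sigma).

Note on the intraclass-correlation derivative: one published rendering of
this quantity carries the coefficient (1+K)/(Vb+Vw) on the dVb term; the
quotient rule on K = Vb/(Vb+Vw) gives (1-K)/(Vb+Vw), and only the latter
agrees with finite differences.  Both are available via ``form=`` in
:func:`k_gradient`; the quotient-rule form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blockkit import kron_vjp
from .decomp import MixingDistribution, decompose
from .multistate import StageGroupModel, absorbing_chain, assemble_fertvec, assemble_transitions
from .blockkit import block_diagonal
from .outcomes import (
    RewardModel,
    fundamental,
    initial_stage_slice,
    longevity_moments,
    lro_moments,
    poisson_rewards,
)

__all__ = [
    "SensitivityResult",
    "variance_gradients",
    "k_gradient",
    "longevity_sensitivity",
    "lro_fertility_sensitivity",
    "lro_mortality_sensitivity",
]


@dataclass
class SensitivityResult:
    """Gradient of a variance component with respect to a parameter vector."""

    target: str  # "Vw" | "Vb" | "K"
    parameter: str  # "mortality" | "fertility"
    group: int | str  # 1-based group index or "all"
    gradient: np.ndarray  # length s
    outcome: str = ""
    scale: str = "hazard"  # "hazard" (mu) or "survival" (sigma); fertility: "fertility"


def variance_gradients(pi: np.ndarray, m: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Heads of the chains: (dVw/dv', dVb/dm')."""
    pi = np.asarray(pi, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    dVw_dv = pi.copy()
    dVb_dm = 2.0 * pi * m - 2.0 * (pi @ m) * pi
    return dVw_dv, dVb_dm


def k_gradient(
    K: float,
    Vb: float,
    Vw: float,
    dVb_dtheta: np.ndarray,
    dVw_dtheta: np.ndarray,
    form: str = "quotient",
) -> np.ndarray:
    """Gradient of the intraclass correlation from the component gradients."""
    total = Vb + Vw
    if total <= 0:
        raise ValueError("K is undefined: total variance is zero")
    if form == "quotient":
        cb = (1.0 - K) / total
    elif form == "as-printed":
        cb = (1.0 + K) / total
    else:
        raise ValueError(f"unknown form {form!r}")
    return cb * np.asarray(dVb_dtheta) - (K / total) * np.asarray(dVw_dtheta)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _embed_stage(row_g: np.ndarray, j: int, s: int, g: int) -> np.ndarray:
    """Pullback through the stage slice: row over (m, v) -> row over (m~, v~)."""
    out = np.zeros(s * g)
    out[(j - 1) * g : j * g] = row_g
    return out


class _Workspace:
    """Assembled model quantities reused across chains."""

    def __init__(self, model: StageGroupModel, mixing: MixingDistribution, j: int, outcome: str):
        if not model.has_hazard:
            raise ValueError(
                "sensitivity analysis requires the hazard parameterization "
                "(G_list/mu_list) on the model"
            )
        self.model = model
        self.mixing = mixing
        self.j = j
        self.outcome = outcome
        self.s, self.g, self.gs = model.s, model.g, model.gs
        self.K = model.K
        self.D = block_diagonal(model.D_list)
        self.U = assemble_transitions(model)
        self.N = fundamental(self.U)
        if outcome == "longevity":
            self.moments = longevity_moments(self.N)
            self.chain = None
            self.rewards = None
        elif outcome == "lro":
            self.chain = absorbing_chain(self.U)
            self.f = assemble_fertvec(model)
            self.rewards = poisson_rewards(self.f)
            if self.rewards.kind != "poisson":  # pragma: no cover - guard
                raise NotImplementedError("analytic dR2/dR1 is known only for Poisson rewards")
            self.moments = lro_moments(self.chain, self.rewards)
            self.P = self.chain.P
            self.vecP = self.P.ravel(order="F")
            self.vecR1 = self.rewards.R1.ravel(order="F")
            self.vecR2 = self.rewards.R2.ravel(order="F")
            self.rho1 = self.moments.raw1
            self.rho2 = self.moments.raw2
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        m, v = initial_stage_slice(self.moments, j, self.g)
        self.m, self.v = m, v
        self.dec = decompose(mixing, m, v, outcome=outcome)
        self.dVw_dv, self.dVb_dm = variance_gradients(mixing.pi, m, v)
        # heads lifted to the joint state space
        self.row_m = _embed_stage(self.dVb_dm, j, self.s, self.g)  # over m~
        self.row_v = _embed_stage(self.dVw_dv, j, self.s, self.g)  # over v~

    # -- tail: row over vec(U~) -> per-group hazard gradient -------------
    def vecU_to_mu(self, rowU: np.ndarray, group: int) -> np.ndarray:
        """Pullback through (K kron DK) . (Q_i' kron L_i) . dvecU_i/dmu_i'."""
        gs, s = self.gs, self.s
        Y = rowU.reshape(gs, gs, order="F")
        # row (K kron DK) = vec( (DK)' Y K ) = vec( K' D' Y K )
        T = self.D.T @ Y
        T = self.K.apply_t(T)  # K' on the left
        T = self.K.permute_cols(T)  # K on the right
        blk = slice((group - 1) * s, group * s)
        B = T[blk, blk]  # row (Q_i' kron L_i) = block (i, i)
        G = self.model.G_list[group - 1]
        sigma = np.exp(-self.model.mu_list[group - 1])
        # row ( -(I kron G_i) D(vec I) (I kron 1) D(sigma) ):
        # grad_k = -sigma_k * (G_i' B)_kk
        return -sigma * np.einsum("ik,ik->k", G, B)

    def fvec_to_fi(self, row_f: np.ndarray, group: int) -> np.ndarray:
        """Pullback through df~/df_i' = K L_i: permute then take block i."""
        s = self.s
        swg = self.K.apply_t(row_f)  # row . K
        return swg[(group - 1) * s : group * s].copy()


# ---------------------------------------------------------------------------
# longevity chains
# ---------------------------------------------------------------------------


def _long_mean_to_vecN(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Row over m~ -> row over vec(N~) via dm~/dvecN~ = I kron 1'."""
    return np.repeat(y, ws.gs)


def _long_var_to_vecN(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Row over v~ -> row over vec(N~).

    v~ = eta2 - eta1 o eta1 with eta1 = N~'1, eta2 = (2N~ - I)' eta1 gives
    dv~/dvecN~ = (2N~' - I - 2D(eta1)) (I kron 1') + 2 (I kron eta1').
    """
    eta1 = ws.moments.raw1
    a = 2.0 * (ws.N @ y) - y - 2.0 * y * eta1
    return np.repeat(a, ws.gs) + 2.0 * np.kron(y, eta1)


def _vecN_to_vecU(row_vecN: np.ndarray, ws: _Workspace) -> np.ndarray:
    """dvecN~/dvecU~' = N~' kron N~ as a pullback."""
    return kron_vjp(row_vecN, ws.N.T, ws.N)


# ---------------------------------------------------------------------------
# lifetime reproductive output chains
# ---------------------------------------------------------------------------


def _rho_head_to_vecR(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Row over rho-space -> row over a vec(R) space.

    Pullback of N~' Z (I kron 1') D(vecP~), the operator appearing in both
    d rho1/d vecR1 and d rho2/d vecR2 (occupancy rewards).
    """
    c = ws.N @ y
    cz = np.append(c, 0.0)
    return np.repeat(cz, ws.gs + 1) * ws.vecP


def _pad_ZZ(row_hat: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Row over vec(Rhat) -> row over vec(R) via (Z kron Z): zero-pad."""
    gs = ws.gs
    Y = row_hat.reshape(gs, gs, order="F")
    out = np.zeros((gs + 1, gs + 1))
    out[:gs, :gs] = Y
    return out.ravel(order="F")


def _lro_mean_to_vecR1(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """d m~/d vecR1' pullback (m~ = rho1 depends on R1 only directly)."""
    return _rho_head_to_vecR(y, ws)


def _lro_var_to_vecR1(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """d v~/d vecR1' pullback at fixed U~, including the Poisson R2(R1) link.

    Three routes: through R2 = R1 + R1 o R1; through Rhat1 inside
    2 (U~ o Rhat1)' rho1; and through rho1 itself (which also shifts the
    -rho1 o rho1 term).
    """
    gs = ws.gs
    c = ws.N @ y
    # route 1: d v~/d vecR2 . (I + 2 D(vecR1))
    row = _rho_head_to_vecR(y, ws) * (1.0 + 2.0 * ws.vecR1)
    # route 2: 2 N~' (I kron rho1') D(vec U~) (Z kron Z)
    row += _pad_ZZ(2.0 * np.kron(c, ws.rho1) * ws.U.ravel(order="F"), ws)
    # route 3: [2 N~'(U~ o Rhat1)' - 2 D(rho1)] d rho1/d vecR1
    q = 2.0 * (ws.U * ws.rewards.Rhat1) @ c - 2.0 * ws.rho1 * y
    row += _rho_head_to_vecR(q, ws)
    return row


def _vecR1_to_f(row_vecR1: np.ndarray, ws: _Workspace) -> np.ndarray:
    """d vecR1/d f~' = Z' kron 1 as a pullback: per-column block sums."""
    gs = ws.gs
    return row_vecR1.reshape(gs + 1, gs + 1, order="F").sum(axis=0)[:gs]


def _vecP_rows_to_vecU(row_vecP: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Pullback through dvecP~/dvecU~' = C1 - C2 (I kron 1').

    The transient block of P~ is U~ itself; the death row is
    d' = 1'(I - U~), whence the second (negative, column-replicated) term.
    """
    gs = ws.gs
    Yp = row_vecP.reshape(gs + 1, gs + 1, order="F")
    return Yp[:gs, :gs].ravel(order="F") - np.repeat(Yp[gs, :gs], gs)


def _lro_mean_to_vecU(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """d m~/d vecU~' pullback.

    rho1 = N~' h with h = Z (P~ o R1)' 1; U~ enters through N~ and through
    the transition law P~.
    """
    c = ws.N @ y
    cz = np.append(c, 0.0)
    rowP = np.repeat(cz, ws.gs + 1) * ws.vecR1
    rowU = _vecP_rows_to_vecU(rowP, ws)
    rowU += np.outer(ws.rho1, c).ravel(order="F")  # (rho1' kron N~') K2 term
    return rowU


def _lro_var_to_vecU(y: np.ndarray, ws: _Workspace) -> np.ndarray:
    """d v~/d vecU~' pullback at fixed rewards."""
    gs = ws.gs
    c = ws.N @ y
    cz = np.append(c, 0.0)
    # through P~ in the R2 reward sum
    rowU = _vecP_rows_to_vecU(np.repeat(cz, gs + 1) * ws.vecR2, ws)
    # direct U~ o Rhat1 dependence: 2 (I kron rho1') D(vec Rhat1)
    rowU += 2.0 * np.kron(c, ws.rho1) * ws.rewards.Rhat1.ravel(order="F")
    # fundamental-matrix route of the outer N~': (rho2' kron N~') K2
    rowU += np.outer(ws.rho2, c).ravel(order="F")
    # through rho1 (also shifts -rho1 o rho1)
    q = 2.0 * (ws.U * ws.rewards.Rhat1) @ c - 2.0 * ws.rho1 * y
    rowU += _lro_mean_to_vecU(q, ws)
    return rowU


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _groups_of(group, g: int) -> list[int]:
    if group == "all":
        return list(range(1, g + 1))
    if not 1 <= int(group) <= g:
        raise ValueError(f"group index {group} out of range 1..{g}")
    return [int(group)]


def _package(
    ws: _Workspace,
    rowsU_or_f: dict[str, np.ndarray],
    group,
    parameter: str,
    to_param,
    scale: str,
) -> dict[str, SensitivityResult]:
    """Push Vw/Vb rows through the shared tail, add the K combination."""
    grads = {t: np.zeros(ws.s) for t in ("Vw", "Vb")}
    for i in _groups_of(group, ws.g):
        for t in ("Vw", "Vb"):
            gi = to_param(rowsU_or_f[t], i)
            if scale == "survival" and parameter == "mortality":
                sigma = np.exp(-ws.model.mu_list[i - 1])
                gi = -gi / sigma
            grads[t] += gi
    out = {
        t: SensitivityResult(
            target=t,
            parameter=parameter,
            group=group,
            gradient=grads[t],
            outcome=ws.outcome,
            scale=scale if parameter == "mortality" else "fertility",
        )
        for t in ("Vw", "Vb")
    }
    dec = ws.dec
    if dec.K is not None:
        out["K"] = SensitivityResult(
            target="K",
            parameter=parameter,
            group=group,
            gradient=k_gradient(dec.K, dec.Vb, dec.Vw, grads["Vb"], grads["Vw"]),
            outcome=ws.outcome,
            scale=out["Vw"].scale,
        )
    return out


def longevity_sensitivity(
    model: StageGroupModel,
    mixing: MixingDistribution,
    j: int = 1,
    group="all",
    scale: str = "hazard",
) -> dict[str, SensitivityResult]:
    """Gradients of Vw, Vb, K of longevity with respect to mortality hazards."""
    ws = _Workspace(model, mixing, j, "longevity")
    rowsU = {
        "Vb": _vecN_to_vecU(_long_mean_to_vecN(ws.row_m, ws), ws),
        "Vw": _vecN_to_vecU(_long_var_to_vecN(ws.row_v, ws), ws),
    }
    return _package(ws, rowsU, group, "mortality", ws.vecU_to_mu, scale)


def lro_fertility_sensitivity(
    model: StageGroupModel,
    mixing: MixingDistribution,
    j: int = 1,
    group="all",
) -> dict[str, SensitivityResult]:
    """Gradients of Vw, Vb, K of lifetime reproductive output w.r.t. fertility."""
    ws = _Workspace(model, mixing, j, "lro")
    rows_f = {
        "Vb": _vecR1_to_f(_lro_mean_to_vecR1(ws.row_m, ws), ws),
        "Vw": _vecR1_to_f(_lro_var_to_vecR1(ws.row_v, ws), ws),
    }
    return _package(ws, rows_f, group, "fertility", ws.fvec_to_fi, "fertility")


def lro_mortality_sensitivity(
    model: StageGroupModel,
    mixing: MixingDistribution,
    j: int = 1,
    group="all",
    scale: str = "hazard",
) -> dict[str, SensitivityResult]:
    """Gradients of Vw, Vb, K of lifetime reproductive output w.r.t. mortality."""
    ws = _Workspace(model, mixing, j, "lro")
    rowsU = {
        "Vb": _lro_mean_to_vecU(ws.row_m, ws),
        "Vw": _lro_var_to_vecU(ws.row_v, ws),
    }
    return _package(ws, rowsU, group, "mortality", ws.vecU_to_mu, scale)
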