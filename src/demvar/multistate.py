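"""Stage-by-group multistate model and block-structured chain assembly.

Individuals are jointly classified by a life-cycle stage (1..s: age class,
size, developmental stage) and a heterogeneity group (1..g: frailty class,
environment, genotype).  Per-group stage dynamics ``U_i`` (s-by-s,
column-substochastic: survival plus movement) and per-stage group dynamics
``D_j`` (g-by-g, column-stochastic) are woven into a single gs-by-gs
transition matrix with the vec-permutation construction::

    Utilde = D K U K',   U = sum_i L_i U_i Q_i,   D = blockdiag(D_1..D_s)

The joint state vector is ordered **group-within-stage**: state index
(stage-1)*g + group (0-based internally).  One time step applies stage
transitions first, then group transitions.  If heterogeneity is fixed,
every ``D_j`` is the identity and the groups decouple exactly.

Appending a death state to ``Utilde`` yields an absorbing Markov chain
P = [[Utilde, 0], [d, 1]] with d' = 1' (I - Utilde); longevity and lifetime
reproductive output are functionals of this chain (see :mod:`demvar.outcomes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blockkit import VecPermutation, block_diagonal, placement, vec_perm

__all__ = [
    "StageGroupModel",
    "AbsorbingChain",
    "assemble_transitions",
    "assemble_fertility",
    "assemble_fertvec",
    "absorbing_chain",
]

#: tolerance on substochasticity / stochasticity of input matrices
STOCHASTIC_TOL = 1e-12


@dataclass
class StageGroupModel:
    """A life cycle classified by s stages and g heterogeneity groups.

    Parameters
    ----------
    U_list
        g stage-transition matrices (s-by-s), column sums <= 1.
    D_list
        s group-transition matrices (g-by-g), column-stochastic.  Identity
        for fixed heterogeneity.
    fert_list
        Optional g per-stage mean-fertility vectors (length s).
    F_list
        Optional g fertility matrices (s-by-s); default places ``fert_list``
        on the first row (offspring enter stage 1).
    H_list
        Optional s offspring group-allocation matrices (g-by-g,
        column-stochastic); default identity (offspring inherit the
        parent's group).
    G_list, mu_list
        Optional hazard parameterization U_i = G_i D(exp(-mu_i)): G_i is the
        conditional growth/movement matrix (column sums <= 1), mu_i the
        stage-specific mortality hazard vector.  Required by the sensitivity
        engine; when given, U_list is derived and must not disagree.
    """

    s: int
    g: int
    U_list: list[np.ndarray]
    D_list: list[np.ndarray]
    fert_list: list[np.ndarray] | None = None
    F_list: list[np.ndarray] | None = None
    H_list: list[np.ndarray] | None = None
    G_list: list[np.ndarray] | None = None
    mu_list: list[np.ndarray] | None = None
    stage_labels: list[str] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U_list = [np.asarray(U, dtype=float) for U in self.U_list]
        self.D_list = [np.asarray(D, dtype=float) for D in self.D_list]
        if self.fert_list is not None:
            self.fert_list = [np.asarray(f, dtype=float).ravel() for f in self.fert_list]
        if self.G_list is not None:
            self.G_list = [np.asarray(G, dtype=float) for G in self.G_list]
        if self.mu_list is not None:
            self.mu_list = [np.asarray(m, dtype=float).ravel() for m in self.mu_list]
        if not self.stage_labels:
            self.stage_labels = [f"stage{j+1}" for j in range(self.s)]
        if not self.group_labels:
            self.group_labels = [f"group{i+1}" for i in range(self.g)]
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        s, g = self.s, self.g
        if len(self.U_list) != g:
            raise ValueError(f"expected {g} stage-transition matrices, got {len(self.U_list)}")
        if len(self.D_list) != s:
            raise ValueError(f"expected {s} group-transition matrices, got {len(self.D_list)}")
        for i, U in enumerate(self.U_list, start=1):
            if U.shape != (s, s):
                raise ValueError(f"U{i} has shape {U.shape}, expected ({s}, {s})")
            if (U < 0).any():
                raise ValueError(f"U{i} has negative entries")
            bad = np.where(U.sum(axis=0) > 1 + STOCHASTIC_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"U{i} column {bad[0]+1} sums to {U.sum(axis=0)[bad[0]]:.6g} > 1"
                )
        for j, D in enumerate(self.D_list, start=1):
            if D.shape != (g, g):
                raise ValueError(f"D{j} has shape {D.shape}, expected ({g}, {g})")
            if (D < 0).any():
                raise ValueError(f"D{j} has negative entries")
            dev = np.abs(D.sum(axis=0) - 1.0)
            if (dev > STOCHASTIC_TOL).any():
                k = int(np.argmax(dev))
                raise ValueError(
                    f"D{j} column {k+1} sums to {D.sum(axis=0)[k]:.12g}, not 1"
                )
        if self.fert_list is not None:
            if len(self.fert_list) != g:
                raise ValueError(f"expected {g} fertility vectors, got {len(self.fert_list)}")
            for i, f in enumerate(self.fert_list, start=1):
                if f.size != s:
                    raise ValueError(f"f{i} has length {f.size}, expected {s}")
                if (f < 0).any():
                    raise ValueError(f"f{i} has negative entries")
        if self.H_list is not None:
            for j, H in enumerate(self.H_list, start=1):
                dev = np.abs(np.asarray(H).sum(axis=0) - 1.0)
                if (dev > STOCHASTIC_TOL).any():
                    raise ValueError(f"H{j} is not column-stochastic")
        if (self.G_list is None) != (self.mu_list is None):
            raise ValueError("G_list and mu_list must be supplied together")
        if self.G_list is not None:
            for i, (G, mu, U) in enumerate(
                zip(self.G_list, self.mu_list, self.U_list), start=1
            ):
                rebuilt = G @ np.diag(np.exp(-mu))
                if not np.allclose(rebuilt, U, atol=1e-10):
                    raise ValueError(
                        f"U{i} disagrees with its hazard parameterization G{i} D(exp(-mu{i}))"
                    )

    # -- convenience -----------------------------------------------------
    @property
    def gs(self) -> int:
        return self.s * self.g

    @property
    def has_hazard(self) -> bool:
        return self.G_list is not None

    @property
    def K(self) -> VecPermutation:
        """The internal vec-permutation converting stage-within-group
        vectors to the model's group-within-stage ordering."""
        return vec_perm(self.s, self.g)

    def state_index(self, stage: int, group: int) -> int:
        """0-based joint index of (stage, group), both 1-based."""
        return (stage - 1) * self.g + (group - 1)

    def with_hazard(
        self, mu_list: list[np.ndarray], group: int | None = None
    ) -> "StageGroupModel":
        """Rebuild the model with replaced hazard vectors.

        ``group`` (1-based) replaces a single group's hazard; ``None``
        replaces all groups.  Used by finite-difference oracles.
        """
        if not self.has_hazard:
            raise ValueError("model lacks a hazard parameterization")
        new_mu = [m.copy() for m in self.mu_list]
        if group is None:
            if len(mu_list) != self.g:
                raise ValueError("need one hazard vector per group")
            new_mu = [np.asarray(m, dtype=float).ravel() for m in mu_list]
        else:
            new_mu[group - 1] = np.asarray(mu_list[0], dtype=float).ravel()
        new_U = [G @ np.diag(np.exp(-m)) for G, m in zip(self.G_list, new_mu)]
        return StageGroupModel(
            s=self.s,
            g=self.g,
            U_list=new_U,
            D_list=[D.copy() for D in self.D_list],
            fert_list=None if self.fert_list is None else [f.copy() for f in self.fert_list],
            F_list=self.F_list,
            H_list=self.H_list,
            G_list=[G.copy() for G in self.G_list],
            mu_list=new_mu,
            stage_labels=list(self.stage_labels),
            group_labels=list(self.group_labels),
        )

    def with_fertility(
        self, fert: list[np.ndarray], group: int | None = None
    ) -> "StageGroupModel":
        """Rebuild with replaced fertility vector(s) (FD oracle support)."""
        if self.fert_list is None:
            raise ValueError("model has no fertility vectors")
        new_f = [f.copy() for f in self.fert_list]
        if group is None:
            new_f = [np.asarray(f, dtype=float).ravel() for f in fert]
        else:
            new_f[group - 1] = np.asarray(fert[0], dtype=float).ravel()
        return StageGroupModel(
            s=self.s,
            g=self.g,
            U_list=[U.copy() for U in self.U_list],
            D_list=[D.copy() for D in self.D_list],
            fert_list=new_f,
            F_list=self.F_list,
            H_list=self.H_list,
            G_list=None if self.G_list is None else [G.copy() for G in self.G_list],
            mu_list=None if self.mu_list is None else [m.copy() for m in self.mu_list],
            stage_labels=list(self.stage_labels),
            group_labels=list(self.group_labels),
        )


@dataclass
class AbsorbingChain:
    """Absorbing Markov chain over the joint stage-by-group state space.

    ``P = [[Utilde, 0], [mortality, I_alpha]]`` with column sums exactly 1;
    ``mortality`` holds the per-state probabilities of entering each
    absorbing (death) state.
    """

    Utilde: np.ndarray
    P: np.ndarray
    mortality: np.ndarray
    alpha: int = 1
    Ftilde: np.ndarray | None = None
    ordering: str = "group-within-stage"

    @property
    def gs(self) -> int:
        return self.Utilde.shape[0]


def assemble_transitions(model: StageGroupModel) -> np.ndarray:
    """Joint transition matrix ``Utilde = D K U K'`` (group-within-stage)."""
    U = block_diagonal(model.U_list)  # stage-within-group
    D = block_diagonal(model.D_list)  # group-within-stage
    K = model.K
    # D @ K @ U @ K': apply K' to columns, K to rows of U, then D.
    KUKt = K.apply(K.permute_cols_t(U))
    Ut = D @ KUKt
    colsum = Ut.sum(axis=0)
    if (colsum > 1 + 1e-12).any():
        k = int(np.argmax(colsum))
        raise ValueError(f"assembled Utilde column {k+1} sums to {colsum[k]:.12g} > 1")
    return Ut


def assemble_fertility(model: StageGroupModel) -> np.ndarray:
    """Joint fertility matrix ``Ftilde = H K F K'``.

    Uses ``F_list`` if given, else builds F_i = e_1 f_i' (offspring enter
    stage 1).  Offspring group allocation H_j defaults to the identity.
    """
    s, g = model.s, model.g
    if model.F_list is not None:
        F_blocks = [np.asarray(F, dtype=float) for F in model.F_list]
    elif model.fert_list is not None:
        F_blocks = []
        for f in model.fert_list:
            F = np.zeros((s, s))
            F[0, :] = f
            F_blocks.append(F)
    else:
        raise ValueError("model supplies neither fertility vectors nor matrices")
    F = block_diagonal(F_blocks)
    H = block_diagonal(
        model.H_list if model.H_list is not None else [np.eye(g)] * s
    )
    K = model.K
    return H @ K.apply(K.permute_cols_t(F))


def assemble_fertvec(model: StageGroupModel) -> np.ndarray:
    """Per-state mean reproduction ``ftilde = K sum_i L_i f_i``.

    Entry for joint state (stage j, group i) is f_i[j].
    """
    if model.fert_list is None:
        raise ValueError("model has no fertility vectors")
    stacked = np.concatenate(model.fert_list)  # stage-within-group
    return model.K.apply(stacked)


def absorbing_chain(Utilde: np.ndarray, Ftilde: np.ndarray | None = None) -> AbsorbingChain:
    """Append the death state: ``P = [[Utilde, 0], [d, 1]]``, d = 1'(I - Utilde)."""
    Utilde = np.asarray(Utilde, dtype=float)
    gs = Utilde.shape[0]
    d = 1.0 - Utilde.sum(axis=0)
    if (d < -STOCHASTIC_TOL).any():
        k = int(np.argmin(d))
        raise ValueError(
            f"negative death probability {d[k]:.3g} in column {k+1}: input is super-stochastic"
        )
    d = np.clip(d, 0.0, None)
    P = np.zeros((gs + 1, gs + 1))
    P[:gs, :gs] = Utilde
    P[gs, :gs] = d
    P[gs, gs] = 1.0
    return AbsorbingChain(Utilde=Utilde, P=P, mortality=d[None, :], alpha=1, Ftilde=Ftilde)


def project_two_phase(model: StageGroupModel, N: np.ndarray) -> np.ndarray:
    """One projection step computed directly on the g-by-s population array.

    Stage transitions within each group first, then group transitions
    within each stage.  Oracle for :func:`assemble_transitions`:
    ``vec(project_two_phase(model, N)) == Utilde @ vec(N)``.
    """
    N = np.asarray(N, dtype=float)
    N1 = np.vstack([model.U_list[i] @ N[i, :] for i in range(model.g)])
    N2 = np.column_stack([model.D_list[j] @ N1[:, j] for j in range(model.s)])
    return N2
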