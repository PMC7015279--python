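# Methods

This note records the model, the conventions, and the numerical and design
choices behind `demvar`, in the order the pipeline uses them.

## State space and ordering

An individual's state is the pair (stage, group). Stages are the life-cycle
axis (age classes, sizes, developmental stages); groups carry the
heterogeneity (frailty class, environment, genotype). The joint state vector
is ordered **groups within stages**: state index `(stage−1)·g + group`. The
companion convention — stages within groups — appears transiently inside the
assembly (the block-diagonal `U = Σ L_i U_i Q_i` is naturally stage-within-
group) and the fixed internal vec-permutation `K = K_{s,g}` converts between
the two. Both conventions are defensible; what matters is that one is fixed
and machine-checked, which the two-phase projection test does: one step of
the assembled `U~ = D K U K'` must equal stage transitions applied to each
group's row of the g×s population array followed by group transitions
applied to each stage's column.

Within a time step, stage transitions act **first**, then group transitions
(`U~` applies `U` before `D`). All matrices are column-oriented (column =
departing state); `U_i` columns may sum to less than one (mortality), `D_j`
and `H_j` columns must sum to one (group movement and offspring allocation
conserve individuals). Violations beyond 1e-12 are rejected at construction,
never clipped: a super-stochastic input is a data error, not noise.

## Outcomes

**Longevity.** With `N~ = (I − U~)⁻¹` (expected occupancies before death),
the first two moment vectors are `η₁' = 1'N~` and `η₂' = η₁'(2N~ − I)`;
mean `m~ = η₁`, variance `v~ = η₂ − η₁∘η₁`. Longevity counts the current
time step, so `m~ ≥ 1`.

**Lifetime reproductive output.** Reproduction is a random reward attached
to transitions of the absorbing chain `P = [[U~, 0], [d', 1]]`. We assume
*occupancy-based* rewards: a reward with state-specific mean `f~_j` is
collected on every departure from live state `j`, whatever the destination —
including the transition into death — and dead individuals collect nothing
(last column of every reward-moment matrix is zero). Under the default
Poisson assumption the second-moment matrix is `R₂ = R₁ + R₁∘R₁`. The
moment recursions are

```
ρ₁ = N~' Z (P ∘ R₁)' 1
ρ₂ = N~' [ Z (P ∘ R₂)' 1 + 2 (U~ ∘ R̂₁)' ρ₁ ]
```

where `Z = [I | 0]` drops the absorbing state and `R̂₁ = Z R₁ Z'`. The
bracket placement in ρ₂ (the factor `N~'` multiplying the whole sum) follows
the Markov-chains-with-rewards literature and is confirmed by the
individual-based simulation oracle; the same oracle-arbitration policy is
applied to every equation whose typeset grouping is ambiguous (see
*Sensitivity*, below). User-supplied `R₁, R₂` are accepted for moment
computation; the analytic fertility sensitivities require the Poisson link
(otherwise `dR₂/dR₁` is unknown and the code refuses rather than guesses).

**Conditioning and mixing.** A cohort is initialized in one stage `j`;
`(e_j' ⊗ I_g)` slices the g conditional means/variances out of `m~, v~`.
The mixing distribution π over groups at that stage is an *input*, with its
provenance (estimated / stationary / assumed) recorded verbatim in reports.
π is treated as fixed throughout; sensitivities with respect to π are out of
scope. Then `E = π'm`, `Vw = π'v`, `Vb = π'(m∘m) − (π'm)²`,
`K = Vb/(Vb+Vw)`. If the total variance is exactly zero, K is reported as
undefined (`None`), not 0/0.

## Sensitivity analysis

Gradients of `Vw`, `Vb`, `K` with respect to a stage-indexed parameter
vector θ — a group's mortality-hazard vector `μ_i`, or its fertility vector
`f_i`, or the same perturbation applied to every group — are computed as
chains of vector-Jacobian products. Starting from the scalar heads

```
dVw/dv' = π',        dVb/dm' = 2π'D(m) − 2(π'm)π',
```

a row vector is pulled back through, in order: the stage slice
`(e_j' ⊗ I_g)`; the outcome Jacobians (`dm~/dvecN~ = I ⊗ 1'`, the
corresponding variance form, and `dvecN~/dvecU~' = N~' ⊗ N~` for longevity;
for LRO the Jacobians with respect to `vecR₁`, `vecR₂`, and `vecU~`,
including the death-row coupling `dvecP/dvecU~' = C₁ − C₂(I ⊗ 1')`); the
assembly `dvecU~/dvecU' = K ⊗ DK`; the placement `dvecU/dvecU_i' = Q_i' ⊗
L_i` (a block extraction); and finally the hazard parameterization.
Kronecker factors are never expanded: a pullback `y(A ⊗ B)` is evaluated as
`vec(B' Y A)` with `Y` the unvec of `y`, so memory stays O((gs)²) — a single
row — rather than O((gs)⁴).

**Hazard parameterization.** Both case-study forms are instances of
`U_i = G_i D(σ_i)` with `σ_i = exp(−μ_i)`: for age-classified models `G_i`
is the subdiagonal shift (age advances or you die), for stage-classified
models it is the conditional growth/stasis/retrogression matrix. The
pullback tail is `grad_k = −σ_k (G_i' B)_kk` with `B` the extracted block.
Gradients are reported on the hazard scale by default; a `scale="survival"`
flag converts with `dσ/dμ = −D(σ)`. "All groups" gradients are the sum of
the per-group gradients, a property that is also asserted in the tests.

**Resolved ambiguities.** Two printed forms in circulation for pieces of
this calculus do not survive a derivative check, and central finite
differences (the package's independent oracle, relative agreement required
at 1e-4 and observed at ~1e-8) were used as the arbiter:

* the coefficient on `dVb` in `dK/dθ' = c·dVb/dθ' − K/(Vb+Vw)·dVw/dθ'` is
  `c = (1−K)/(Vb+Vw)`, as the quotient rule gives — not `(1+K)/(Vb+Vw)`.
  The alternative remains available as `k_gradient(..., form="as-printed")`
  and demonstrably fails the finite-difference check whenever `Vb > 0`;
* the stage slice is `(e_j' ⊗ I_g)` (dimension g output, matching the
  conditional-moment definitions), not `(e_j' ⊗ I_s)`;
* in the LRO Jacobians with respect to `vecU~`, the leading `N~'` multiplies
  the whole bracket — including the `2(U~∘R̂₁)'·(dρ₁/d·)` feedback term —
  while the `−2D(ρ₁)·(dρ₁/d·)` term from the `ρ₁∘ρ₁` subtraction sits
  outside it.

## Case-study builders

**Age × frailty (Weibull mixture).** Group `i` has cumulative hazard
`H_i(t) = (t/a_i)^{b_i}` (t in days). The 1-day discretization uses the
exact increment `μ_i(x) = H_i(x+1) − H_i(x)` rather than a midpoint hazard,
so the discrete survivorship equals `exp(−H_i(t))` exactly at integer ages
(a property the tests assert). The age axis ends at the first age where
every group's survivorship is below 1e-10, capped at 200 days (reaching the
cap warns and proceeds). Heterogeneity is fixed: `D_j = I`.

**Stage × environment (fire).** Four environments (fire year; 1, 2, ≥3
years since fire) follow the Markov chain `D(r)` — fire with probability
`r` from any state, otherwise time-since-fire advances and saturates — and
every stage shares it (`D_j = D(r)`). Stage dynamics are
`U_i = G_i D(σ_i)` per environment; the stationary environment distribution
`(r, r(1−r), r(1−r)², (1−r)³)` is computed as the dominant right
eigenvector and doubles as the default mixing distribution.

**Parameter provenance.** The numerical vital rates of the two published
case studies (the six fitted Weibull pairs; the Rose Prairie matrices) are
not printed in any main text and are treated as user-replaceable inputs.
The packaged files are **synthetic stand-ins**, labelled as such in both
filename and a `provenance` field, chosen to respect the documented
structure: group 3 longest-lived in the frailty mixture; reproduction
confined to the three reproductive stages and strongly elevated in fire
years; survival increasing with size; no retrogression to the yearling
stage. Analyses of these files exercise the machinery and the structural
predictions (e.g. a yearling-stage fertility increase applied in all
environments cannot change `Vb`, because the yearling state is occupied
exactly once and before any environment-dependent mortality); they do not
reproduce the published decomposition values, and the tests that assert
those published values are expected to fail until the fitted rates are
supplied.

## Verification oracles and what they show

The **individual-based simulator** realizes the chain directly from the
columns of `P` with per-step Poisson reproduction, and is compared with the
analytic moments at n = 100 000 within 4 standard errors (of the sample
mean, and of the sample variance via its fourth-moment standard error); the
4-SE band keeps the false-failure probability negligible across the suite.
The **finite-difference oracle** uses central differences with step
`max(1e-6, 1e-6·|θ_k|)`.

The random-model generator draws column-stochastic `G_i` (dense positive),
survival per stage uniform on [0.2, 0.95], random column-stochastic `D_j`
(or identity under the fixed-heterogeneity flag), and fertility uniform on
[0, 2]. These are dense, well-mixed, short-lived life cycles: they probe the
algebra thoroughly (every state reachable, all chains exercised), but they
do not emulate sparse life cycles, near-singular `I − U~` (survival → 1),
zero-inflated fertility, or overdispersed (non-Poisson) reproduction.
Passing tests therefore certify the correctness of the computations, not
the realism of any particular biological application.

## Numerical choices

* Linear solves (LU) for `N~` and everything derived from it; explicit
  inverses appear only in test oracles. Numerically singular `I − U~`
  (pivot < 1e-13) raises rather than returning garbage.
* Substochasticity/stochasticity tolerance 1e-12 at validation; mixing
  distributions off by ≤1e-8 are renormalized with a warning, larger errors
  are rejected.
* Conditional variances are clamped at zero only within 1e-9 (float
  cancellation in `η₂ − η₁∘η₁`); more negative values raise.
* Dense algebra throughout: the intended scale (gs up to ~1200, as in the
  age×frailty demo) fits comfortably; the VJP formulation keeps sensitivity
  memory at O((gs)²).
* Problem sizes in the shipped verification runs: random models with
  s ∈ {2,3,4}, g ∈ {1,…,4} (50 models per gradient case, 20 for the
  Monte Carlo comparison at n = 100 000) — small enough that the whole
  suite runs in well under a minute while covering every code path.
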