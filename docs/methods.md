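# Methods

## The model

Sperm of a *Drosophila melanogaster* male are the endpoints of a lineage of
`D` cell divisions from the zygote (36–42; 38 fits screening data best).
Write `u_i` for the recessive-lethal mutation rate per cell division within
the `i`-th of `I` consecutive division intervals `[t_{i-1}+1, t_i]`.  A
mutation arising at division `d` on a branch ancestral to `s` of the `f`
sampled offspring lines of one father is inherited by exactly those `s`
lines, so a family's mutations are summarized by a *pattern*
`κ = <i, j, k, …>` — the multiset of mutation sizes.  Because a second
mutation in a line that already carries a high-lethality mutation is
effectively undetectable (masking), each mutant line is attributed to one
mutation and `Σκ ≤ f`.

### Genealogy coefficients

The distribution of branch counts is set by the germline population
trajectory `N(0)…N(D)`:

* cleavage: `N(i) = 2^i` through division 7;
* PGC bottleneck: the `n8 = N(8)` primordial germ cells are a uniform draw
  from the `8·n5` division-8 descendants of `n5` ancestor cells chosen at
  division 5.  `n5 = 32` is the random-sampling limit; small `n5` makes the
  PGCs a tight clone cluster ("sampling bias");
* expansion: doubling from `n8`, capped at a configurable stem pool
  (`stem_cap`, default 128), reached by division 14;
* stem-cell stage: constant pool size, one surviving daughter per cell per
  division (divisions pass mutations but produce no coalescence);
* spermatogenesis: the last five divisions double the population.

The post-bottleneck shape (doubling to a capped stem pool, constant stem
stage, doubling spermatogenesis) is the simplest trajectory consistent with
the growth-then-stem-stage narrative; the exact historical pool sizes are
not recoverable, so `stem_cap` is exposed as a parameter.  Sensitivity to it
is low because coalescence after the bottleneck is dominated by the
bottleneck itself.

Sample genealogies are simulated backward: at each division the `N(i)`
daughter cells map to the `N(i-1)` parents with exactly `N(i) − N(i-1)`
parents dividing, assignment uniform at random subject to those
multiplicities (the simplest exchangeable birth process satisfying
`N(i) ≤ 2·N(i-1)`).  Lineages are routed through the bottleneck by placing
them uniformly in the `n5` complete division-5..8 subtrees.  Each replicate
genealogy `G` yields branch counts `B_G(d, s)` (branches at division `d`
with `s` sampled descendants).  A brute-force forward oracle — every cell
simulated with explicit parent pointers, sample drawn at the leaves —
validates the backward engine on trajectories up to 4096 cells; the two
agree in distribution (chi-square goodness of fit on coalescence times).

### Pattern likelihood

Conditional on `G`, the number of mutations of size `s` is modeled as
Poisson with mean `λ_s(G, u) = Σ_d u_{I(d)} B_G(d, s)`, independent across
sizes; the pattern probability is the Monte-Carlo average over `M` stored
genealogies of the product of Poisson terms.  This Poisson-thinning
construction is the natural small-rate approximation and is validated
against exact enumeration on a miniature six-division tree (all 41,664
three-leaf samples) and against forward simulation.  Masking is *not*
modeled in the likelihood: patterns violating `Σκ ≤ f` get probability 0
and no renormalization is applied.  The forward synthetic generator *does*
mask, so the approximation error is measurable; at the rates of interest
the unnormalized mass is below 1%, and it grows with the overall rate —
which is also why the likelihood-based overall rate and the classical
mutant-per-line estimator drift apart when rates are far above 1% per
generation.

The experiment log-likelihood is `Σ_f Σ_κ n_f(κ) log p_f(κ)` with explicit
empty-pattern terms for non-mutant families.  All accumulation is in log
space with the `0·log 0 = 0` convention.

### Estimation and tests

Rates are estimated by box-constrained L-BFGS-B on log-rates (floor 1e-12,
snapped to 0 below 1e-9 for reporting, since quiet intervals genuinely sit
on the boundary) with analytic gradients — the likelihood is linear in the
Poisson means, so the gradient is a softmax-weighted average over
genealogies and costs one extra matrix product.  Multi-start uses
deterministic starts first (a flat vector, then all mass concentrated on
each interval in turn, covering the basins that differ in which interval
carries the bulk of the rate) before random restarts; tolerance is 1e-8 on
the log-likelihood.  The overall rate per generation is the width-weighted
sum `μ̂ = Σ (t_i − t_{i-1}) û_i`; the classical estimator `μ̃ = mutants /
lines` needs no dynamics assumptions and serves as a cross-check.

Hypotheses H1–H7 impose equality classes on interval rates (H1 all equal;
H2 all internal equal; H3 `u1=u2`; H4 `u2=u3`; H4b `u3=u4`; H5/H6 equality
among the trailing intervals; H7 first = last) and are tested against the
unconstrained H8 by `2·(lnL_H8 − lnL_Hi)` with chi-square reference;
degrees of freedom are always counted structurally as the free-parameter
difference, never hard-coded.

The dynamics scan refits the model over a grid of `(n5, n8, D)` cells; a
grouped value such as `n5 ∈ 5–6` is realized by pooling equal-size
coefficient sets simulated at each member integer (the symmetric,
reproducible choice).  Cells share the same nominal `M` so log-likelihood
deficits are comparable; when a rare large branch size observed in the
data is absent from a cell's simulations (which would force Monte-Carlo
probability zero), that cell's depth is doubled up to three times, and if
still uncovered the offending pattern is scored with a large finite
penalty — the cell genuinely cannot produce the observation at any
plausible rate.  Infeasible cells (`n8 > 8·n5`) are flagged, never
silently dropped.

Identifiability caveat: the scan surface is steep against *stronger*
sampling bias (fewer PGCs, fewer ancestors) but shallow toward weaker
bias — at the original experiment's full size the deficit separating the
best group from its weak-bias neighbors is only on the order of 3–30
log-likelihood units, so a scaled-down dataset (~10³ families) cannot
reliably separate immediately adjacent groups.  Recovery checks at
reduced scale therefore contrast the generating group with
strong-restriction alternatives, whose deficits remain two orders of
magnitude larger.

### The first-division ratio

The display convention for the ratio of the first-division rate to the
mean internal rate is `u1 / [(u2 + u3 + 11·u4 + 18·u5) / 32]`, applied to
the rounded, printed rates exactly as written (its denominator enumerates
31 interval-divisions but divides by 32; ratios computed from unrounded
estimates differ by a few percent).  The expected male:female rate ratio
given `n_m`/`n_f` cell divisions and first-division fold `r` is
`(r + n_m − 1)/(r + n_f − 1)`.

## Screen analysis

A line's lethality is `d = 1 − zz/total` over its F3 offspring.  QC drops
lines with balancer offspring in F3 (non-virgin females), fewer than 40
offspring, and — when other candidates in the family were crossed — lines
above the candidate threshold (default `d > 0.92`) that were never crossed,
whose identity is undeterminable; a lone candidate needs no cross and is
kept.  Families with fewer than two surviving lines are rejected.

Crosses are tested with the binomial deviance statistic (chi-square(1)
under the shared-mutation null) at per-test level `α/m`, `m` counting the
crosses actually performed in the family (`α = 0.10` by default).  Lines
joined by non-significant crosses merge; a significant cross inside a
merged component is a conflict, resolved deterministically by cutting the
largest-statistic non-significant edge on the connecting path and logged.
Group lethality pools the member parental lines' F3 counts only (cross
offspring are not pooled), so every reported number is reproducible from
the line table.  Patterns are extracted per lethality window (`[99,100]`,
`[98,99)`, `[97,98)` by default; half-open below the top).

## Synthetic screen

The generator forward-simulates what the likelihood abstracts: a genealogy
per family, Poisson mutations on branches, masking by earliest division,
binomial F3 counts, and complementation crosses.  Design constants default
to the study conditions: up to 35 initiated lines thinned binomially to a
mean of ~28.3 recorded, ≥40 and mean ~118 F3 offspring per line, baseline
z/z proportion `p0 = 0.175` (z/z homozygotes are slightly less fit than
balancer heterozygotes, hence below 1/3), lethality of new mutations
uniform on [0.97, 1] (the three analysis windows receive roughly equal
mutation counts), 100 offspring per cross.  A carrier line's z/z proportion
is `(1 − d)·p0/0.175` — i.e. lethality is defined operationally against the
17.5% baseline, keeping the generator self-consistent with `line_stats`.

Cross design: the default is *adaptive sequential complementation* — each
candidate line is crossed against a representative of every group
established so far until one cross fails to complement.  A blind chain
through randomly ordered candidates (kept as `cross_policy="chain"`) is
provably insufficient: when a family carries two interleaved mutations of
similar lethality, every between-group chain edge is significant and
within-group members are never connected, shredding large groups.  Screens
resolve exactly this with interconnected crosses, which the adaptive policy
emulates.

What the generator does not emulate: dominance effects of lethals,
balancer-contamination sequences, batch/seasonal effects, and adaptive
changes of the non-tested-line threshold over the course of a real screen.
Passing recovery tests therefore demonstrates correctness of the inference
chain under the stated design, not robustness to those artifacts.

## Numerical and test-scale choices

* Coefficient sets: M = 2000 genealogies per family size for fits (u1
  standard error from coefficient noise is then well below sampling noise);
  scans use M = 1000 per cell.
* Full-chain recovery checks use 2000 families of 20 lines at rates typical
  of the ≥97% lethality class; the dynamics-scan recovery check uses 20
  replicates of 1200 families on the coarse 2×2 (n5, n8) group grid
  described above.  These sizes give the checks high per-replicate power
  against the contrasts they test; the original screen is ~10× larger in
  line count.
* Small-lethality leakage: with lethality uniform on [0.97, 1], a few
  percent of single-line mutations near the window edge are misclassified
  by binomial noise in `d̂`.  This barely touches the first-division rate
  (large clusters pool many lines) but biases the spermatogenesis/stem
  rates slightly low in end-to-end runs — visible in the recovery tests'
  tolerances.
* Degenerate inputs: all-non-mutant tallies short-circuit to `û = 0` with
  log-likelihood 0; empty families and zero-rate vectors are valid
  everywhere; `f > N(D)` samples sperm with replacement and warns.

## Known limitations

* Exact coalescent probabilities for arbitrary trajectories are out of
  scope; everything genealogical is Monte Carlo (plus the small-case
  forward oracle).
* The likelihood ignores masking and overlapping-lineage double mutations;
  at overall rates well above ~0.1 per generation the first-division rate
  is likely underestimated.
* Confidence intervals are limited to likelihood-ratio tests; no Bayesian
  machinery.
* The command-line pipeline holds all data in memory; the original screen's
  scale (~10^4 families) takes minutes, not hours, so this is not a
  practical constraint.
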