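# Methods

This note documents the statistical models implemented in `socpod`, the
choices made where the methodology is genuinely open, and what the synthetic
data generator does and does not emulate.

## Sampling design and association indices

The unit of association is the *sampling period*, one calendar day.  Two
individuals are "associated in a period" if they were recorded in the same
group at least once that day; an individual photographed in two groups on
one day is treated as a member of both, so its dyads with co-members of
either group score as associated.  This both-groups convention is a design
choice: field protocols rarely state how a same-day resight in a different
group should be scored, and the chain-rule definition of a group (members
linked through shared membership that day) argues for counting both.

For a dyad, over all periods, `x` counts periods together, `y_AB` periods
both identified but never together, `y_A`/`y_B` periods only one
identified.  The half-weight index `HWI = x / (x + y_AB + (y_A + y_B)/2)`
down-weights the periods in which only one member was identified by half,
which makes it the least biased of the simple indices when individuals are
more likely to be missed than misidentified.  Dyads never co-sampled (all
four tallies zero) are assigned HWI 0 and flagged, rather than treated as
missing, because matrix algorithms downstream need a complete matrix.

Population summaries: social differentiation `S` is the coefficient of
variation (sample SD over mean) of the dyadic HWI values across **all**
dyads — a deliberately literal sample statistic, not a likelihood-based
estimate of the CV of the underlying association probabilities, which would
be larger.  Both the all-dyads mean and the nonzero-dyads mean are
reported; the all-dyads version is canonical.  `H` is the mean number of
observed associates per individual, where "associate" means a dyad with
`x ≥ 1`; whether such counts should instead include all nonzero-HWI dyads
is not settled usage, so the definition is recorded here rather than
asserted as the only one.  The preferred-association power rule rejects
"no preferred companions" when `S²·H > 5` (strict inequality).

## Permutation tests

The null model holds the sampling design fixed and permutes group
membership: each move exchanges two individuals between two groups, chosen
so neither is already present in the other group.  Group sizes and each
individual's total number of group memberships are conserved by every move
(within-period swaps additionally conserve per-period sighting counts).
The chain starts from the observed data, burns in 1,000 swaps, and records
one permutation every `flips_per_step` (default 100) further swaps; the
number of flips per recorded permutation is not fixed by convention, so it
is configurable.  The chain is single-threaded by contract so a seed fully
determines the output.

Statistics recomputed per permutation: mean, SD and CV of the dyadic HWI
and the proportion of nonzero dyads.  P-values use the +1 correction (the
observed arrangement counts as one member of its null set), so they are
never zero, and equal exactly 1 when no valid swap exists.  Dyad-level
p-values use mid-p tie handling (ties contribute half to each tail), so a
degenerate permuted distribution yields p ≈ 0.5 in both tails instead of
flagging every tied dyad.  A dyad is *preferred* when its upper-tail
p ≥ 0.975 **and** its HWI exceeds twice the overall mean (the magnitude
screen removes statistically extreme but biologically trivial dyads), and
*avoided* on the lower tail alone.

## Community structure

Clustering operates on the dissimilarity `d = 1 − HWI` (valid because
HWI ≤ 1); merge heights are mapped back to the association scale for
reporting.  "Ward's average linkage" is ambiguous terminology, so both
`average` (UPGMA) and `ward` linkage are implemented; the default is
average, the customary dendrogram for association matrices.  The cophenetic
correlation coefficient is the Pearson correlation between the dyadic
values and the levels at which dyads join the tree; CCC > 0.8 is the usual
bar for trusting the dendrogram, and agglomerative trees on noise matrices
sit well below it.

The flat partition is chosen by evaluating Newman's weighted modularity
`Q = Σ_c (e_cc − a_c²)` (weights = HWI, zero diagonal) at **every**
horizontal cut of the tree and keeping the maximum; ties resolve toward
fewer clusters.  Q of the single-cluster partition is exactly 0 and two
equal disconnected cliques score 0.5, which the tests pin down; Q > 0.3 is
the conventional bar for meaningful structure.  A mean-HWI cutpoint
partition (cut the tree at the overall mean association index) is also
provided for dendrogram display, but the modularity cut is canonical for
cluster counting.

The Mantel test correlates the HWI matrix with a same-cluster indicator
matrix under permutations of individual labels, reporting the Mantel `r`,
a permutation z-score `t`, and a two-tailed p.  The minimum-sightings scan
rebuilds matrix, tree, Q and CCC for each inclusion threshold `k`; its
purpose is to find the smallest `k` at which CCC clears 0.8.

One published companion statistic — the correlation between "true" and
permuted association indices (a maximum-likelihood social-differentiation
correlation) — has no closed formula in the sources available here and is
not implemented; the CV-based `S` covers the same construct.

## Standardized lagged association rates

For individual A with identified associate sets `S_A(t)` and `S_A(u)`
(both non-empty), the event for lag τ = |u − t| contributes
`|S_A(t) ∩ S_A(u)| / |S_A(u)|` to the numerator and 1 to the denominator,
summed over both time directions — the probability that a randomly chosen
*identified* associate of A at the later time was A's associate at the
earlier time.  Standardizing by the number identified makes the rate robust
to incomplete identification of groups; the estimator is exactly 1 for
permanent always-or-never detected companions and symmetric under time
reversal.  The null rate replaces the numerator's indicator with the
random-mixing expectation `deg_A(earlier) / (n − 1)` over the n catalogued
individuals; simulated random re-assortment sits on this null.

Lag bins are log-spaced by default (association persistence is judged over
spans two orders of magnitude longer than the sampling interval) and
configurable.  Four models are fit by maximizing a binomial
quasi-likelihood on the per-bin event sums: `a` (constant companions, CC),
`a·e^(−bτ)` (casual acquaintances, CA), `a + c·e^(−bτ)` (CC+CA) and
`a·e^(−bτ) + c·e^(−dτ)` (CA+CA).  These four forms are recorded explicitly
and are not claimed byte-identical to any particular software's internal
model list.  Overdispersion `ĉ` is the Pearson X²/df of the most general
converged model (floored at 1), and `QAIC = −2 log L / ĉ + 2k`; fits use
multi-start L-BFGS-B with parameters bounded in (0, 1] and decay rates in
(0, 5] per day.

Jackknife precision deletes one contiguous block of sampling periods at a
time (default 30-day blocks — "one observation" has no natural definition
for a rate built from period pairs, so a block of correlated periods is the
defensible resampling unit) and uses the delete-one-group SE
`sqrt((G−1)/G · Σ(θ₋ᵢ − θ̄)²)`.

## Closed-population abundance

The observed capture histories (pooled to one binary detection per survey
session) are augmented with all-zero pseudo-histories to `M = 4 ×`
the observed count by default; each row has inclusion `z_i ~ Bern(ψ)`,
detections `y_it ~ Bern(z_i p_it)`, and `N = Σ z_i`.  Detection structures:
M0 constant `p`; Mt session-specific `p_t` (independent Uniform(0,1)
priors); Mh `logit p_it = μ + ε_i` with `ε_i ~ N(0, σ²)`; Mth additive
fixed session effects plus the individual random effect.  ψ and all
detection probabilities get Uniform(0,1) priors (for μ the uniform sits on
the inverse-logit scale, i.e. a standard-logistic prior on μ); the
random-effect precision gets Gamma(5, 1), which concentrates σ² in a
plausible range while allowing broad values and stabilizes the
three-session heterogeneity models.

The sampler is a bespoke Gibbs scheme.  Under M0/Mt every update is
conjugate and the all-zero rows are exchangeable, so the sampler tracks
only the *number* of included pseudo-individuals (a Binomial draw), making
chains of hundreds of thousands of iterations essentially free.  Under
Mh/Mth the rows are explicit and the logit-scale parameters move by
random-walk Metropolis; excluded rows' random effects refresh from the
prior.  Defaults are 3 chains × 20,000 kept draws after 5,000–6,000
burn-in, which the Brooks–Gelman–Rubin statistic (computed via arviz)
shows is fully converged for M0/Mt on three-session data; a BGR above 1.1
on N attaches a warning rather than failing.  A posterior for ψ pressing
against 1 also warns, since it means the augmentation bound is restrictive.

DIC uses the deviance of the detections conditional on inclusion, with
effective parameters `p_D = var(deviance)/2` (the Gelman variant — stated
explicitly because DIC has several variants); ΔDIC is relative to the
best model on the same data, and comparisons across different data are
refused.  The marked-proportion correction divides: `N_total = N_marked /
θ`, drawwise; a marked proportion below 1 must *inflate* abundance, which
fixes division (not multiplication) as the direction of the correction.  θ has a Uniform(0,1) prior and a
binomial likelihood over pooled marked/total group counts, hence a
Beta(1 + marked, 1 + unmarked) posterior.  θ and N are estimated
separately and paired draw-by-draw rather than inside one joint model;
with a binomial θ likelihood the two posteriors are independent anyway, so
the pairing is exact up to Monte Carlo error, and this choice is
documented rather than asserted as the only one.  An independent
frequentist cross-check, the Schnabel estimator
`N̂ = Σ C_t·M_t / Σ R_t`, is provided and agrees with the Mt posterior
median within a few percent on three-session data.

## Synthetic data generator

Each simulated day assembles `groups_per_day` groups: a focal cluster is
drawn uniformly, group size is zero-truncated Poisson around
`mean_group_size` (simple and positive; real group sizes are more
overdispersed, which matters little for validating estimators), and
members are drawn without replacement with weight `within_propensity` for
the focal cluster and `between_propensity` otherwise.  Detection thins
group members independently (session-specific probabilities inside survey
sessions, optionally with logit-normal individual heterogeneity); marks
are permanent per-individual Bernoulli(θ) labels; habitat and stratum are
categorical labels assigned per cluster so stratum-versus-cluster
cross-tabulations can be exercised.  A single seed drives one generator
with a documented draw order (per-individual attributes first, then days,
groups, members, detection), so output is bit-reproducible.

Default magnitudes describe a three-cluster estuarine dolphin community:
cluster sizes 25/34/36 (95 individuals), 300 days, 2 groups/day, mean
group size 9, detection 0.45, between-propensity 0.05, marked proportion
0.7.  Under these defaults the realized within-cluster mean HWI is ≈ 0.11
and between-cluster ≈ 0.01, the modularity cut recovers the three clusters
exactly, and nearly every individual exceeds the 7-sighting inclusion
threshold.  What the generator does **not** emulate: spatial home ranges
and movement (cluster mixing is propensity-based, not geographic),
overdispersed group sizes, temporary emigration, mark change or
misidentification.  Passing tests therefore demonstrate estimator
correctness under the stated sampling model, not robustness to those
real-data complications.

## Problem sizes used in the test suite

Simulation-based checks run at deliberately modest sizes chosen to give
each property clear resolution: permutation and Mantel calibration use 200
replicate null datasets of ~10–12 individuals; SLAR model recovery uses 20
replicates of 40-pair populations over 30–40 periods; the Mt coverage
study uses 100 replicate surveys of N = 500 with detection (0.3, 0.2,
0.25); the worked three-session abundance fits use 3 chains × 10,000–20,000
kept draws, at which point the BGR statistic is indistinguishable from 1
and posterior medians are stable to well under 1%.

## Known limitations

* Mh and Mth with only three sessions are weakly identified — a known
  property of heterogeneity models at few occasions, not an implementation
  artifact; their estimates should be read as sensitivity checks.
* The SLAR null rate assumes random mixing over the whole catalog; for
  catalogs with strong temporal turnover in availability a
  gregariousness-stratified null would be more appropriate.
* The permutation engine implements group-membership swaps only; null
  models controlling for gregariousness or spatial overlap are out of
  scope.
* CSV is the only input format; SOCPROG or program-specific formats need
  to be mapped to the canonical columns first (a column mapping is
  supported).
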