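# socpod

Social-network and closed-population abundance analysis for
photo-identification sighting histories of group-living animals —
built around the workflow used for estuarine bottlenose dolphin
(*Tursiops truncatus*) catalogs, but applicable to any species observed
through repeated group encounters of individually identifiable animals.

## What it computes

Given a table of sightings (one row per identified individual per group
encounter per day), `socpod` provides:

* **Half-weight association indices (HWI).** For a dyad,
  `HWI = x / (x + y_AB + (y_A + y_B)/2)`, where `x` counts sampling periods
  (calendar days) the two were grouped together, `y_AB` periods both were
  identified apart, and `y_A`, `y_B` periods only one was identified.
  Per-individual summaries (mean, max, strength = Σ HWI, number of
  associates), social differentiation `S` (CV of dyadic HWI) and the power
  rule `S²·H > 5` for detecting preferred companionship.
* **Permutation null models.** Markov-chain swaps of individuals between
  groups that preserve group sizes and individual sighting counts, within or
  between sampling periods, with population-level tests (SD/CV of HWI higher
  than the null → preference; proportion of nonzero dyads lower → avoidance)
  and dyad-level preferred/avoided classification (one-sided p ≥ 0.975 and
  HWI > 2 × mean).
* **Community structure.** Hierarchical clustering of the HWI matrix
  (average or Ward linkage on 1 − HWI), cut selection by Newman's weighted
  modularity `Q = Σ_c (e_cc − a_c²)` (Q > 0.3 = meaningful structure),
  cophenetic correlation (CCC > 0.8 = the tree represents the matrix), a
  within/between-cluster Mantel test, and a minimum-sightings threshold scan.
* **Standardized lagged association rates (SLAR).** `g(τ)` = probability a
  companion is retained after lag τ, standardized for incomplete
  identification, with a random-mixing null rate, delete-one-block jackknife
  SEs, and QAIC-ranked exponential models (constant companions, casual
  acquaintances, and mixtures).
* **Bayesian closed-population capture-mark-recapture.** Models M0 / Mt /
  Mh / Mth via data augmentation (`z_i ~ Bern(ψ)`, `y_it ~ Bern(z_i p_it)`,
  `N = Σ z_i`), a bespoke Gibbs / Metropolis-within-Gibbs sampler, DIC model
  comparison, Brooks–Gelman–Rubin convergence diagnostics, and the
  marked-proportion correction `N_total = N_marked / θ` with a conjugate
  Beta posterior for θ.
* **A synthetic catalog generator** with known cluster labels, abundance,
  detection probabilities and marked proportion, so every stage can be
  validated against ground truth.

## Worked example

Reconstruct three-session capture histories from session totals
(269, 141, 174), pairwise resighting overlaps (41, 42, 46) and a triple
overlap of 21, then fit the session-specific detection model:

```python
from socpod import (AugmentedModelSpec, fit_closed_cmr,
                    histories_from_session_counts, schnabel_estimate)

table = histories_from_session_counts((269, 141, 174), (41, 42, 46), 21)
print(table.n_individuals)          # 476 unique individuals
print(round(schnabel_estimate(table)))  # 946  (closed-form cross-check)

spec = AugmentedModelSpec(model="Mt", n_chains=3, n_iter=20000,
                          burn_in=6000, seed=1)
fit = fit_closed_cmr(table, spec)
print(round(fit.median))            # 944
print([round(v) for v in fit.credible_interval()])  # [831, 1092]
```

The posterior median (~944 dolphins, 95% credible interval ~831–1092) is
the abundance of identifiable animals consistent with how quickly
individuals were resighted across the three survey sessions; the Schnabel
estimate provides an independent frequentist sanity check.

The `examples/` directory holds one short script per capability
(simulation, association network, permutation tests, clustering, SLAR,
abundance, full pipeline); each prints the numbers it computes and a line
on what they mean. The full pipeline is also scriptable:

```bash
socpod run-all --config config.yaml --seed 7
```

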