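# stsurv — Bayesian spatiotemporal surveillance of areal disease counts

`stsurv` is a toolkit for detecting areas with unusual risk trends in
non-communicable-disease surveillance data: panels of observed counts
`y_it` and expected counts `E_it` over administrative areas `i` and time
points `t` (e.g. monthly hospital admissions across the 211 Clinical
Commissioning Groups of England).  It is aimed at spatial epidemiologists
and public-health analysts who want model-based anomaly detection with
honest uncertainty, rather than scan-type hypothesis tests.

## Models

All models share the Poisson likelihood `y_it ~ Poisson(E_it ρ_it)` for the
relative risk `ρ_it`, and differ in the latent structure of `log ρ_it`:

* **Disease mapping (DM)** — the standard descriptive model
  `log ρ_it = α + θ_i + φ_i + γ_t + ψ_it`, with an intrinsic CAR (ICAR)
  prior on the structured spatial field `θ` (areas are neighbours when they
  share a boundary), exchangeable heterogeneity `φ`, a first-order
  random-walk (RW1) trend `γ`, and exchangeable space–time interactions
  `ψ`.  Areas are flagged informally when the posterior probability
  `P(ψ_it > 0 | y)` (equivalently, the interaction's risk ratio exceeding 1)
  passes a threshold — 0.8 by convention, 0.9 for a conservative variant.
* **STmix** — the same structure with the interaction prior replaced by a
  two-component zero-mean normal mixture `ψ_it ~ (1−p) N(0, σ₁²) +
  p N(0, σ₂²)`, `σ₁ ≤ σ₂`, so genuinely unusual units escape the global
  shrinkage.  Two classification rules are provided: at least one time
  point with exceedance probability above 0.8 (rule 1), or three time
  points averaging above 0.8 (rule 2).
* **FlexDetect** — per-area Bayesian model choice between a common-trend
  submodel `log ρ_it = α + θ_i + γ_t` and an area-specific-trend submodel
  `log ρ_it = α_i + γ̃_t + δ_it` in which every area owns a heavy-tailed
  departure walk `δ_i·`.  The per-area indicator `z_i` yields the posterior
  probability `p̃_i` that area i follows the common model; flags come from
  the Newton-style Bayesian false-discovery-rate rule, which flags the
  largest group of areas whose mean `p̃` stays within the FDR budget
  (α = 0.05 by default).

Inference is by Metropolis-within-Gibbs MCMC (vectorised single-site
updates, conjugate Gibbs steps for precisions, burn-in-only adaptation),
with potential-scale-reduction diagnostics built in.  A synthetic-scenario
generator reproduces the structure of the benchmark simulation — 211 areas,
15 months, 15 unusual areas whose risk doubles at time points 3 and 10 and
halves at 6, 12 and 15 — with ground-truth labels, and a study harness
scores every detector by sensitivity, specificity, FDR and false-omission
rate across replicates.

## Worked example

```python
import stsurv

# one synthetic monthly surveillance panel: 211 areas x 15 months,
# 15 areas with doubled risk at months 3 & 10 and halved at 6, 12, 15
panel, truth, graph = stsurv.make_scenario1(seed=7)

res = stsurv.FlexDetectModel(panel, graph).fit(fast=True, seed=7)
print(res.summary().round(3))

det = res.detect(alpha=0.05)
print(f"flagged {det.n_flagged} areas: {sorted(det.flagged_areas().tolist())}")
```

prints

```
                 mean      sd     q2.5    q97.5   rhat
param
alpha_common    0.005   0.003   -0.001    0.011  1.000
tau_theta      16.550   1.835   13.127   20.538  1.001
tau_gamma      64.673  23.475   27.217  114.734  1.000
tau_delta     728.719  50.215  626.772  824.455  1.005
pi              0.950   0.000    0.950    0.950  1.000

flagged 17 areas: [25, 27, 34, 69, 80, 86, 119, 120, 127, 136, 142, 146, 171, 181, 196, 202, 208]
```

`alpha_common` is the overall log relative risk (≈0 here, as simulated);
the `tau_*` rows are the latent-field precisions (`tau_delta ≈ 730` means
area-specific departures drift by only a few percent per month unless the
data insist otherwise); `rhat ≈ 1` indicates the two chains agree.  Of the
17 flagged areas, 15 are the truly unusual ones and 2 are false positives —
i.e. on this replicate the detector finds every planted area at an observed
false-discovery proportion of 2/17.

A command-line interface mirrors the library:

```bash
stsurv simulate --seed 1 --out sim/
stsurv fit --model stmix --counts sim/counts.csv --adjacency sim/adjacency.csv --fast --out fit/
stsurv detect --model flexdetect --counts sim/counts.csv --adjacency sim/adjacency.csv \
       --rule FlexDetect --fast --out flags.csv
stsurv benchmark --replicates 10 --seed 1 --out bench/
```

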