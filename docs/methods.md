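# Methods

## Data model

All three surveillance models condition on an areal count panel: observed
counts `y_it` and expected counts `E_it` (the offset, computed upstream by
indirect standardisation) for areas `i = 1..N` and time points `t = 1..T`,
plus an adjacency structure in which two areas are neighbours when they
share a boundary.  The likelihood is everywhere
`y_it ~ Poisson(E_it ρ_it)` with `ρ_it` the relative risk, so each model is
a prior on the latent surface `log ρ_it`.

Intrinsic Gaussian Markov random fields appear twice: the ICAR prior on
spatial fields, with density proportional to
`exp(−τ/2 Σ_{i~j} (θ_i − θ_j)²)`, and the first-order random-walk (RW1)
prior on temporal sequences, `exp(−τ/2 Σ_t (γ_t − γ_{t−1})²)`.  Both are
improper; identifiability comes from sum-to-zero constraints (one per graph
component for the ICAR; disconnected graphs are allowed with a warning) and
a flat prior on the intercept that absorbs the overall level.

## The three models

**Disease mapping (DM).**
`log ρ_it = α + θ_i + φ_i + γ_t + ψ_it` with θ ~ ICAR(τ_θ), φ ~ iid
N(0, 1/τ_φ), γ ~ RW1(τ_γ), ψ ~ iid N(0, 1/τ_ψ).  All four precisions carry
Gamma(1, 0.01) priors — vague but proper; shape/rate are constructor
arguments.  Detection thresholds the per-unit exceedance probability
`P(ψ_it > 0 | y)`: an area is flagged when at least one time point exceeds
the threshold (0.8 standard, 0.9 conservative).  A `component="risk"`
switch thresholds `P(ρ_it > 1 | y)` instead, which is the convention used
for descriptive risk atlases.

**STmix.**  As DM, but
`ψ_it ~ (1−p)·N(0, σ₁²) + p·N(0, σ₂²)` with σ₁ ≤ σ₂ and component
indicators `c_it` Gibbs-sampled from their Bernoulli full conditionals;
`p ~ Beta(1, 1)`.  Label switching is prevented by the ordering constraint,
enforced inside the precision Gibbs step by joint rejection (resample both
component precisions until ordered, keeping the previous pair after 100
failures — in practice rejection is rare because the components are
data-separated).  An alternative `label_switching="informative"` mode
replaces the hard constraint with asymmetric Gamma priors on the two
component precisions (defaults Gamma(2, 0.01) narrow / Gamma(2, 1) wide).
Rule 1 flags an area when any time point's interaction exceedance
probability is above 0.8.  Rule 2's "three time points with average
probability above 0.8" is read as the *three largest* per-time
probabilities (the most favourable triple); a `consecutive=True` variant
requires a window of three adjacent time points instead.

**FlexDetect.**  Per-area choice between two self-contained submodels,

* common trend: `log ρ_it = α + θ_i + γ_t` (θ ICAR, γ RW1) — no
  interaction term, so this submodel cannot absorb area-specific
  excursions;
* area-specific trend: `log ρ_it = α_i + γ̃_t + δ_it`, where `γ̃` is the
  area-specific submodel's own overall RW1 trend and `δ_i·` is area i's
  departure walk, an RW1 with base precision τ_δ and Student-t increments
  (ν = 4) implemented as a Gamma scale mixture: increment `d` has precision
  `τ_δ w`, `w ~ Gamma(ν/2, ν/2)`.

The hierarchical decomposition (shared trend + departure) rather than one
free-standing RW1 per area is deliberate: a single per-area walk must be
loose enough to track the population trend, which also lets it chase
Poisson noise in ordinary areas and erodes the model-choice contrast.
Decomposing lets the departure prior be stiff — τ_δ ~ Gamma(200, 0.25),
mean 800, i.e. month-to-month departures of ~3.5% unless the data insist —
while the heavy tails keep abrupt area-specific excursions (step changes,
isolated spikes: the patterns that motivate trend-based detection) cheap.
These hyperparameters were fixed once by a pilot simulation study on
scenario replicates, which is also the calibration procedure we recommend
before applying the detector to a new dataset.

The indicator `z_i` (1 = area-specific) is Gibbs-drawn each sweep from the
two submodels' current Poisson likelihoods for area i and the prior
inclusion probability π, with *no feedback* into the submodel parameters —
the "cut" construction used by model-choice detectors in this family.  Both
submodels therefore always condition on the full panel.  π is held at 0.95
(the mean of its Beta(19, 1) prior, encoding that unusual areas are rare);
`update_pi=True` enables the Beta–Bernoulli Gibbs update, but with hundreds
of areas that update is data-dominated and feedback can collapse π, so the
fixed default is recommended.  The detection score is
`p̃_i = P(z_i = common | y)`, estimated as the retained-draw frequency, and
flags come from the Newton-style Bayesian FDR rule below.

## Detection and multiple testing

`bayes_fdr_flags(p̃, α)` sorts areas by ascending `p̃` and flags the longest
prefix whose running mean stays ≤ α (ties at the cutoff are flagged
together, and a prefix may not split a tie group, which preserves the
budget guarantee `mean(p̃ flagged) ≤ α`).  Under the model's own posterior
this bounds the expected share of truly-common areas among the flags by α.
All rules use strict inequalities at thresholds, so boundary values do not
flag; all rules are permutation-equivariant in the areas.

## MCMC

Metropolis-within-Gibbs with vectorised random-walk Metropolis on the
latent Gaussian blocks:

* interaction cells (`ψ`, `δ`): all conditionally independent cells
  proposed and accepted elementwise in parallel;
* ICAR fields: chromatic updates — a greedy colouring partitions areas into
  independent sets whose full conditionals are mutually independent;
* RW1 sequences: even/odd time points alternately (two-colouring of the
  chain graph);
* intercepts and per-area levels: scalar/row Metropolis;
* precisions (and mixture indicators/weights): conjugate Gibbs.

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during
burn-in only, so the retained chain is Markovian.  Sum-to-zero constraints
are re-imposed every sweep by recentring, with the displaced mean absorbed
into the relevant intercept (pure projection when the intercept is held
fixed).  Initialisation: intercepts at `log(Σy/ΣE)`, latent fields at 0,
precisions at 10 (mixture components at ordered values).  A non-finite
log-posterior at initialisation raises immediately with a block-mean dump.
Default run length is 2 chains × 20 000 sweeps (10 000 burn-in, thin 10);
`McmcConfig.fast()` gives the desk-scale 2 × 5 000/2 500 (thin 5)
configuration used throughout the examples.  The FlexDetect sampler audits
itself every 100 sweeps: the mixture likelihood assembled from the
z-selected per-area submodels must equal the panel Poisson log-likelihood
of the assembled surface.

Convergence is summarised by a potential-scale-reduction variant
`R = sqrt(1 + B/(nW))` (W the mean within-chain variance, B/n the variance
of chain means), which is exactly 1 for identical chains and grows without
bound as chains separate; it tracks the classical split-R̂ closely on
well-mixed chains.

The sampler's joint correctness is audited by a successive-conditional
(Geweke-style) simulation in the test suite: on a 6-area × 4-time model
with proper priors, marginal moments of prior draws and of the
data-augmented transition chain agree within 4 standard errors across
20 000 sweeps.

## Synthetic scenarios

The generator emulates a monthly small-area admission panel.  Baseline:
θ from the ICAR model (conditional scale 0.2 — realised cross-area spread
≈0.12 on a 211-node planar graph; we use the plain conditional-scale
convention rather than marginal-variance rescaling), γ an RW1 with
increment sd 0.15, φ and ψ iid with sd 0.05, intercept 0.  Expected counts
are drawn once per area, uniform on [20, 60], and held constant over time —
plausible for monthly CCG-level admissions for a common condition.  The
default scenario plants 15 of 211 areas with log-risk shifts of +log 2 at
time points 3 and 10 and −log 2 at 6, 12 and 15 (time indices are 1-based
in configuration).  Unusual areas are drawn uniformly, with no spatial
pattern.  Since no public boundary file is bundled, the adjacency is a
Delaunay-based random planar graph with mean degree ≈5.8, typical of
administrative maps.  One master seed spawns independent substreams for
graph, baseline, signal placement, expected counts and count noise, so
every replicate is independently reproducible.

What the generator does *not* emulate: overdispersion beyond the latent
log-normal variation, age–sex standardisation structure in `E`, population
drift over time, spatially clustered anomalies, reporting artefacts, and
missing data.  Passing benchmarks here therefore demonstrate detector
behaviour under a clean, known signal structure, not performance on real
admission data.

## Benchmark

`run_study` generates R replicates, fits DM, STmix and FlexDetect on each,
applies DM1 (0.8), DM2 (0.9), STmix1, STmix2 and FlexDetect (FDR 0.05), and
scores flags against the truth at the *area* level (per-unit flags are
exported for diagnostics but not scored).  Metrics per replicate:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), FDR FP/(TP+FP), FOR
FN/(TN+FN), with any 0/0 set to 0 (no detections ⇒ no false discoveries).
Aggregation is the mean of per-replicate metrics with empirical 2.5/97.5
percentile intervals; the pooled-count aggregation is also written
(`*_pooled` columns) so either convention can be inspected.  A single
shared adjacency graph per study mirrors a fixed administrative map.
Failed replicate fits are logged, excluded and counted.

Problem sizes: the acceptance script runs 8 replicates of the full
211 × 15 scenario with 2 × 5 000-sweep chains (about four minutes on one
CPU); the test suite's benchmark checks use 5–6 replicates with single
3 000-sweep chains.  Tests assert coarse, stable features (orderings,
separations, calibration) at fixed seeds.

## Measured behaviour and limitations

On the default scenario the benchmark (as recomputed by
`scripts/acceptance.py`) shows: the DM exceedance rules detect essentially
all planted areas but at very high false-discovery rates (FDR ≈ 0.8–0.9 at
either threshold — the interaction field soaks up Poisson outliers once
planted signals have inflated its variance), STmix trades between its two
rules, and FlexDetect gives the best balance (sensitivity ≈ 0.78,
FDR ≈ 0.11).  Counts of 20–60 per cell carry limited information: a ±log 2
shift at one time point is a ~4σ event, while ~3σ Poisson fluctuations are
common among 3 000 cells, so a residual false-positive floor of one to two
areas per replicate persists for every detector at these count sizes and is
not removable by prior stiffness (we verified it survives even when the
generator's interaction noise is switched off).  Practitioners should
expect cleaner separation with larger expected counts, and should rerun the
scenario study with their own panel's `E` and noise scales — threshold
choices do not transfer across data regimes.

Other limitations: no Binomial likelihood; no shared-component or
multivariate outcomes; no forecasting; INLA-style approximations are out of
scope (mixture indicators are not Gaussian); the per-area trend model
assumes a single departure walk per area rather than seasonal structure.
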