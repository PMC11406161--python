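# Methods

## The model

`ewlphylo` fits a Bayesian phylogenetic longitudinal mixed model of body
mass in frogs held under crossed water-availability (standing water vs a
moist sponge) and temperature (26 / 36 °C) treatments. For observation
*i* on animal *j* of species *s*:

    ln m_i = x_i' β + u_frog(j) + u_housing(j) + u_date(j) + u_species(s) + ε_i

* `ln m_i` — body mass in natural-log grams.
* `x_i` — 19 fixed-effect covariates: intercept; time (min); water (0/1,
  no-water baseline); temperature (°C, centered at 26 so the intercept
  refers to the cooler treatment); ln snout–vent length (ln mm, centered at
  the within-species mean); species contrasts for *R. marina* and
  *P. terribilis* against the *X. tropicalis* baseline; and the
  species × {time, temperature, water} and water × {time, temperature}
  interactions, including the three-way species × water × {time,
  temperature} terms. The water × time interaction separates the uptake
  slope (in water, via the pelvic patch) from the dehydration slope
  (no water).
* Random effects: individual frog, housing tank, experiment date, and
  species. The species effects are jointly Gaussian with covariance
  `σ²_species · Φ`, where Φ is the phylogenetic correlation matrix.
* Residuals within an individual are correlated through a Gaussian kernel
  in the time lag: `corr(ε_a, ε_b) = ρ^((Δt/20)²)`, so ρ is the residual
  correlation at the nominal 20-min weighing interval. This handles the
  jittered, irregular weighing times directly.

All random effects are marginalized analytically into a single Gaussian
covariance, so the likelihood is an exact multivariate normal:

    y ~ N(Xβ, Σ),   Σ = σ²_f Z_f Z_f' + σ²_h Z_h Z_h' + σ²_d Z_d Z_d'
                        + σ²_s Z_s Φ Z_s' + σ²_e K∘S + 10⁻⁸ I

where `K` is the temporal kernel and `S` restricts it to within-individual
pairs ("nested" mode, the default). A "composite" mode instead applies
`σ²_e Φ[s_a,s_b] K(Δt)` across all pairs — the literal reading of a
composite error covariance. Residual correlation between different animals
is biologically implausible, so nested is the default and composite exists
for sensitivity analyses; both keep the same marginal variance per
observation. The 10⁻⁸ nugget keeps Σ invertible when two rows share a
timestamp.

## Phylogenetic correlation

Φ comes from a sample of ultrametric trees (Newick): topologies are
grouped by their clade sets, the strict-majority topology is kept, each
edge is set to its across-tree mean length, and the matrix entry for
species pair (s, u) is the shared root-to-MRCA path length divided by
√(depth_s · depth_u) — the Brownian-motion expectation. The tree scaling
model is a package choice (the covariance only needs a correlation, and
Brownian motion is the standard neutral default); no Pagel's λ or OU
transform is applied. For the three study species the synthetic tree
sample uses ((R. marina, P. terribilis), X. tropicalis) with node ages of
roughly 75 and 205 My, giving Φ(Rm, Pt) ≈ 0.64 and ≈ 0 against the pipid
outgroup.

## Priors

* Fixed effects: independent normals. The dehydration-slope prior mean is
  the pilot rate (−0.002 ln g/min by default); the uptake (water × time)
  prior mean is −2 × the loss mean, encoding that uptake can be up to
  double dehydration; the water × temperature means assume standing water
  shields 50% of the *X. tropicalis* surface and 25% for the terrestrial
  species, shrinking the temperature effect proportionally; the body-size
  prior mean is the ln midpoint of the baseline species' SVL range. Every
  sd is at least |mean|/2, so zero is always within two prior sd — the
  priors inform scale, not sign.
* Variances: inverse gamma — narrow IG(3, 0.05) for the error variance
  (pilot trajectories pin the measurement scale), wide IG(2, 1) for the
  four group variances. These hyperparameters are declared package
  constants, overridable through `PriorConfig`, and recorded in run
  metadata.
* ρ: uniform(0, 1) on the correlation at the 20-min reference lag. The
  raw bandwidth form `exp(−(Δt/ℓ)²)` is algebraically identical with
  `ℓ = 20/√(−ln ρ)`.

## Sampling

The sampler is a blocked scheme built on an in-package Hamiltonian Monte
Carlo engine (static HMC, jittered path length of 1..L leapfrog steps,
dual-averaging step-size adaptation to 0.8 acceptance, diagonal mass
matrix re-estimated mid-warmup):

1. The 19 fixed effects, being conditionally Gaussian, are marginalized
   under their normal priors into the covariance (`Σ + XΛX'`), and HMC runs
   on the six remaining parameters — the five log variances and logit ρ —
   with analytic gradients of the marginal likelihood. A
   Fisher-information-style preset (`var(log σ²) ≈ 2/k` for k levels)
   initializes the mass matrix so short warmups adapt reliably.
2. For every kept draw, β is drawn exactly from its Gaussian conditional.

With a user-fixed covariance the sampler instead runs HMC over β itself
(flat priors allowed). That path is deliberately independent of the
closed-form GLS solution, so the GLS-oracle test compares two genuinely
different routes to the same posterior.

Convergence is monitored with R-hat, bulk/tail ESS and MCSE (via arviz);
divergent transitions are counted and a fraction above 5% triggers a
warning in the run report rather than an exception. Desk-scale defaults
are 4 chains × 1000 warmup / 1000 samples; study-scale runs (tens of
thousands of iterations) are configuration options. Gradients use a
block-structured path (triangular inverse plus per-individual 4×4 blocks)
when rows are grouped by individual; a dense-inverse fallback covers
arbitrary row orders and composite mode. The two paths agree to machine
precision and both are exercised in tests.

An explicitly hierarchical (non-marginalized) sampler is not implemented;
instead the marginalization is cross-validated against brute-force
Gauss–Hermite integration over the latent effects on a two-frog fixture
(agreement to < 10⁻⁶ in log density).

## Synthetic experiments

The generator emulates the study design so every stage is testable without
any download: 3 species × 2 × 2 treatments, 8 animals per cell (one per
treatment per day over 8 shared dates; two housing tanks per species),
SVL uniform within each species' range, weighings at {0, 20, 40, 60} min
plus uniform ±3 min jitter (t = 0 exact). Trajectories follow the model
above: the linear predictor is evaluated through the same design-matrix
code the fitted model uses, group effects are drawn once per experiment
(species effects jointly under Φ), and residuals are drawn from the
Gaussian kernel at the actual jittered times. Starting masses are whatever
the truth coefficients imply, so SVL and mass are consistent by
construction.

The corruption stage overlays, in order: a single urination/defecation
event per affected animal (probability 0.08, shedding 0.5–3% of current
mass, recorded so preprocessing can add it back), truncation of all
weighings after cumulative loss exceeds 20% (the euthanasia rule), and
masking of interior weighings (probability 0.05, or an exact count for
bookkeeping tests). Missingness is therefore missing-completely-at-random;
the real experiment's missingness (measurement windows colliding with
endpoints) is plausibly also ignorable, but passing tests here do not
establish robustness to informative missingness. The generator likewise
omits behavior (climbing out of water), humidity, and any righting-response
process — dropout uses the 20% mass rule only.

Ground-truth presets: `table1` (the fitted model's posterior means as true
values, variances included, ρ = 0.7 — ρ is a generator choice since the
study does not report its posterior), `null` (all slopes zero), and
`fig1:O1`–`fig1:O5` (conceptual water × temperature outcome shapes).

## Preprocessing rules

* Excretion correction adds the recorded shed mass back to that weighing
  and all later ones (cumulative across events); first differences away
  from event times are unchanged.
* Exclusion removes animals losing > 20% of starting mass (or manually
  flagged); each removal is logged with a reason.
* Imputation: interior single gaps take the mean of the two adjacent
  weighings; all other gaps use a straight-line fit of mass on time.
  The regression is fit per individual — pooling across animals would
  blend species-specific slopes into an individual's prediction; a pooled
  option is not offered. Observed values are never altered, and imputed
  rows keep a provenance flag through to the model frame.
* Missing-value bookkeeping reports masked / total scheduled weighings
  exactly.

## Reported quantities

* Posterior summaries: mean, 2.5% and 97.5% quantiles, and an
  excludes-zero flag per term.
* Marginal temperature effects per species × water cell:
  `Temp + [species-Temp] + water·(Water-Temp + [species-Water-Temp])`
  applied draw-wise; direction probabilities count draws below zero (exact
  zeros half, for determinism on degenerate inputs).
* Rate conversions: `100(e^b − 1)` percent per unit, and
  `m·(e^b − 1)·1000` mg/min at a reference mass; the two are consistent by
  construction.
* Variance ratios of posterior means, with nearest-integer rendering.
* The conceptual outcome classifier consumes slope credible intervals
  (interval logic, not point slopes): overlapping water/no-water intervals
  → no marginal water effect (O2); otherwise a temperature contrast
  covering zero splits gain/loss into O1/O4; with a temperature
  interaction, water gain with credibly negative no-water slope is O3,
  in-water loss is O5; conflicting evidence returns "other".

## Problem sizes and test design

Tests run on reduced problems chosen to keep the whole suite desk-scale
while preserving the structure being tested: unit fixtures use 2–12
animals; sampler contracts use 48 animals (192 rows); the GLS-oracle check
uses 100 animals (400 rows) with 4 × 1000/1000 chains; the parameter-
recovery experiment uses the study scale itself — 95 animals (32 + 31 + 32),
four weighings each — for 20 replicates at reduced sampler settings
(2 chains × 150 warmup / 250 samples, exact conditional β draws). Recovery
simulates clean trajectories (no corruption stage) so it isolates
estimation calibration from preprocessing.

Under the null preset the package asserts only that no species × water
cell reaches a decisive direction probability. A tighter band around 0.5
is not a property a single replicate can be expected to satisfy: the
direction probability is approximately Φ(z) with z standard normal across
replicate datasets, i.e. close to uniform, so any narrow band fails most
seeds by construction.

## Known limitations

* Temperature enters at two levels only; the per-°C slope is the
  26→36 contrast divided by 10 and should not be extrapolated.
* Species-level inference rests on 3 species; the species variance and
  the fixed species contrasts are jointly weakly identified (both are in
  the model, as in the original analysis) and their posteriors are wide.
* The study's exact inverse-gamma hyperparameters are not public; the
  defaults here are package choices, so posterior numbers from the real
  data would not be expected to match the original analysis digit-for-digit.
* Two of the published marginal-effect cells are not reproducible as
  contrasts of the published coefficient means under any coding this
  package implements; the contrast algebra documented above is the one
  reported, and its self-consistent cells are the ones tested.
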