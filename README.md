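# ewlphylo

Bayesian phylogenetic longitudinal mixed models of evaporative water loss
(EWL) in frogs.

Amphibians exchange water rapidly across their skin, so their body mass
tracks the balance between evaporative loss and uptake through the pelvic
patch. This package models repeated body-mass weighings of frogs held
under crossed water-availability (standing water vs a moist sponge) and
temperature (26 / 36 °C) treatments, for three species spanning aquatic to
terrestrial lifestyles (*Xenopus tropicalis*, *Phyllobates terribilis*,
*Rhinella marina*). It is aimed at ecophysiologists who want a tested,
reusable version of this analysis — including a synthetic-data generator
that emulates the experimental design, so every stage runs and is
validated without any data download.

## The model

For observation *i* on frog *j* of species *s*:

```
ln m_i = x_i'β + u_frog(j) + u_housing(j) + u_date(j) + u_species(s) + ε_i

u_species ~ N(0, σ²_s Φ)            Φ = phylogenetic (Brownian) correlation
corr(ε_a, ε_b) = ρ^((Δt_ab / 20)²)   within an individual (Gaussian kernel)
```

with 19 fixed effects β: time (min), water (0/1), temperature (°C,
centered at 26), ln snout–vent length, species contrasts, and all
species × water × {time, temperature} interactions. The water × time term
separates water-uptake from dehydration slopes. Random effects are
marginalized analytically, so the likelihood is an exact multivariate
normal; sampling is Hamiltonian Monte Carlo on the covariance parameters
with exact conditional draws of β (see `docs/methods.md`). Posterior
reporting includes Table-style summaries with 95% credible intervals,
marginal temperature effects per species × water cell, direction
probabilities, and rate conversions (percent body mass per minute,
mg/min).

## Worked example

Simulate an experiment at half the study's size (48 frogs, 4 weighings
each), fit, and report:

```python
import ewlphylo as e
from ewlphylo.hmodel import summary_frame, summarize_posterior

phi = e.phylo_correlation(e.mean_branch_tree(e.sample_trees(100, seed=1)))
design = e.make_design(4, e.DEFAULT_PROFILES, seed=2)
sim = e.simulate_experiment(design, e.truth_parameters("table1"), seed=3, phylo=phi)
frame = e.build_model_frame(sim.series, design, coding=sim.coding)

est = e.PhyloGLMMRegressor(phylogeny=phi, chains=4, warmup=500,
                           samples=500, seed=4).fit(frame)
tab = summary_frame(summarize_posterior(est.draws_)).set_index("term")
print(tab.loc[["Time", "Water-Time", "R.marina-Time", "var_error", "rho"]].round(4))
```

prints

```
                 mean    Q2.5   Q97.5  excludes_zero
term
Time          -0.0023 -0.0040 -0.0007           True
Water-Time     0.0020 -0.0004  0.0043          False
R.marina-Time  0.0005 -0.0017  0.0028          False
var_error      0.0150  0.0103  0.0215           True
rho            0.7097  0.6436  0.7630           True
```

The baseline (*X. tropicalis*, no water) dehydration slope is recovered
near its true −0.0019 ln g/min with an interval excluding zero; the uptake
slope (+0.0023 true) and the *R. marina* contrast are near truth with
intervals reflecting half-size data; the error variance (0.0174 true) and
temporal correlation (0.7 true) are recovered. Contrasts and conversions:

```python
r = e.marginal_temperature_effect(est.draws_, "Phyllobates_terribilis", False)
# mean -0.0066  CI (-0.0341, 0.0202)  p_negative 0.677
e.percent_per_minute(tab.loc["Water-Time", "mean"])   # 0.20 (% body mass/min)
est.diagnostics_["rhat"].max()                        # 1.011
```

`PhyloGLMMRegressor` follows the scikit-learn estimator contract
(`get_params`/`set_params`, `fit`/`predict`, trailing-underscore fitted
attributes); `ewlphylo.fit_hmc`, `gls_fit`, `summarize_posterior` and the
`effects` functions are the functional interface over the same engine.

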