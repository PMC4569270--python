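# dielocc

Day/night hierarchical Bayesian occupancy models for camera-trap surveys
of carnivore guilds.

Camera traps record *when* an animal passes, not whether it truly uses a
site, and species that avoid people by day may use the same landscape
freely at night. `dielocc` is for ecologists who want to ask that
question quantitatively: it splits every photo into a diel period (day =
1 h before sunrise to 1 h after sunset, from solar geometry at the study
centroid), builds per-period detection histories, and fits a
single-season occupancy model separately for day and night while
correcting for imperfect detection.

## The model

For site *i* and period *j* (1 = day, 2 = night):

```
z_ij ~ Bernoulli(ψ_ij)                      presence
y_ij | z_ij ~ Binomial(k_i, z_ij · p_ij)    detections in k_i trap days

logit(ψ_ij) = α1_j + β_j′ X_i + γ_j ψD_ij + U_i + d_ij
logit(p_ij) = α2_j + δ_j′ X_i + S_i
ψ_i = 1 − (1 − ψ_i1)(1 − ψ_i2)              overall (24 h) occurrence
```

with standardized landscape/habitat covariates `X_i`, a plug-in
introduced-dog occurrence covariate `ψD` (the dog is fitted first from a
null occurrence model, two-stage), an intrinsic CAR spatial field `U` on
the Voronoi-tessellation neighbor graph of the stations, an unstructured
detection site effect `S`, and a site-level bivariate diel random effect
`d_i` whose correlation ρ measures day/night coupling of occurrence.
Every occurrence-side fixed effect carries a Bernoulli(0.5) inclusion
indicator, giving indicator-variable Bayesian model selection over a
2^20 model space for the full covariate roster, posterior model
probabilities, inclusion probabilities, and model-averaged coefficients.
The latent `z` is marginalized analytically; estimation is seeded,
reproducible Metropolis-within-Gibbs. See `docs/methods.md` for the full
account.

A synthetic-survey generator (`dielocc.simulate`) reproduces the survey
design the model assumes — ≥500 m station spacing, 37±12 trap days per
site, screened covariate fields, an eight-species guild with a dog whose
occurrence feeds the other species — so every stage is testable against
known ground truth.

## Worked example

```python
import numpy as np
from dielocc.simulate import STUDY_CENTER, generate_landscape, generate_guild
from dielocc.camtrap import build_history, naive_occurrence
from dielocc.solar import SolarProvider
from dielocc.model import ModelSpec, OccupancyData
from dielocc.inference import run_mcmc, day_night_correlation, psrf

sites = generate_landscape(n_sites=120, extent=15_000, seed=1)
photos, truth = generate_guild(sites, seed=2)
history = build_history(photos, sites, SolarProvider(**STUDY_CENTER))
naive = naive_occurrence(history)
print(naive[naive.species == "Kodkod"])

piv = history[history.species == "Kodkod"].pivot_table(
    index="site_id", columns="period", values="y").loc[list(sites.site_id)]
k = history.groupby("site_id")["k"].first().loc[list(sites.site_id)]
data = OccupancyData(y=piv[["day", "night"]].to_numpy(float),
                     k=k.to_numpy(float),
                     X_occ=np.zeros((len(sites), 0)),
                     X_det=np.zeros((len(sites), 0)))
fit = run_mcmc(data, ModelSpec(use_diel_re=True),
               n_chains=2, n_iter=4000, burn_in=1000, thin=5, seed=3)
print("psi (day, night):", fit.psi_mean.mean(axis=0).round(3))
print("p   (day, night):", fit.p_mean.mean(axis=0).round(3))
print("overall psi:     ", fit.psi_overall_mean.mean().round(3))
print("rho: %.2f" % day_night_correlation(fit)[0])
print("max PSRF: %.3f" % psrf(fit)["psrf"].max())
```

prints

```
   species period  naive_occurrence
10  Kodkod    day          0.733333
11  Kodkod  night          0.650000
psi (day, night): [0.734 0.649]
p   (day, night): [0.426 0.629]
overall psi:      0.884
rho: 0.47
max PSRF: 1.039
```

The naive occurrence (fraction of sites with ≥1 detection) and the
detection-corrected ψ nearly coincide here because ~37 trap days at
these detection rates make presence almost certain to be observed; with
sparser effort the corrected ψ rises above the naive value. `p` is the
per-occasion detection probability, `rho` the posterior mean day/night
occurrence correlation, and the overall ψ is the site-averaged union of
day and night occurrence. PSRF near 1 indicates the two chains agree.

The same pipeline is available from the shell:

```
dielocc --seed 1 simulate --n-sites 210 --out survey/
dielocc --seed 1 fit --out artifacts/        # simulate + screen + fit + report
dielocc report --artifacts artifacts/
```

which writes detection histories, the collinearity screen, the adjacency
edge list, per-species chains, model rankings, model-averaged coefficient
tables ("−" marks effects never included), occupancy summaries, ψ
surfaces and a PSRF report.

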