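# occaban

Hierarchical Bayesian analysis of how land abandonment reshapes species
communities, built around multi-species presence/absence surveys collected
in abandoned and inhabited settlements across climatic regions (the
motivating case is butterfly surveys in rural Japan).  The package is aimed
at ecologists who want to (1) estimate species-specific responses to
abandonment and their correlation with thermal niches, (2) relate those
responses to habitat preferences, and (3) project community-level loss and
gain maps over species range stacks.

## The model

Occupancy of species *i* at plot *j* is Bernoulli with a logistic
regression on abandonment, mean annual temperature, survey month and land
use, plus nested random effects for region, settlement and
settlement-by-land-use:

    logit(p_ij) = β0_i + β1_i·ABAN_j + β2_i·TEMP_j + β3_i·MONTH_j
                  + β4_i·I(dry field) + β5_i·I(built-up)
                  + ε_reg(j) + ε_set(j) + ε_lu(j)

Species slopes are random: (β1_i, β2_i) ~ MVN(μ, Σ) with Σ decomposed into
SDs and a correlation ρ — positive ρ means cold-niche species lose more
from abandonment.  Three variants share this core:

- **M1** — free slope means (estimates ρ);
- **M2** — slope means structured by one habitat type:
  μ_β1i = α0 + α1·H_ik, fitted per habitat type;
- **M3** — ridge-regularized multivariate habitat model over all 11 types,
  used to predict responses of species never seen in the survey.

Model variants of the abandonment covariate (binary "abandoned or not"
vs. "years since abandonment") are compared by WBIC, with the Bayes factor
exp(ΔWBIC).  Goodness of fit uses posterior predictive p-values of five
community statistics (presence proportions and Gini coefficients).  M3
predictions projected on a species-by-cell range stack give per-cell
cumulative loss (CL) and gain (CG): sums of negative/positive predicted
effects over species present in the cell, with full posterior mean and SD
maps.  Posterior sampling uses a No-U-Turn sampler with analytic gradients
implemented in the package; see `docs/methods.md` for priors, sampler
details and design decisions.

## Worked example

Simulate a survey with known truth (ρ = 0.5, mean abandonment effect
−0.5), fit the species-level model and compare the abandonment codings:

```python
from occaban import (DesignConfig, GenerativeHyper, McmcSettings,
                     build_design, fit, generate_survey, generate_truth,
                     significant_species)
from occaban.model_selection import compare_aban_codings

config = DesignConfig(n_regions=10, n_species=20,
                      settlements_per_region=(2, 4),
                      plots_per_settlement=(6, 12))
hyper = GenerativeHyper(mu_beta=(-0.5, 0.5, 0, 0, 0), rho=0.5)
truth = generate_truth(config, hyper, seed=11)
table = generate_survey(config, truth, seed=12)
design = build_design(table)

draws = fit("M1", table, design,
            settings=McmcSettings(n_chains=2, n_warmup=300,
                                  n_samples=300, seed=0))
rho = draws.stacked("rho")
print(f"max R-hat {draws.max_rhat():.3f}")
print(f"rho posterior mean {rho.mean():.2f}")
calls = significant_species(draws)
print(sum(v == 'negative' for v in calls.values()), "negative species,",
      sum(v == 'positive' for v in calls.values()), "positive")

report = compare_aban_codings(
    table, settings=McmcSettings(n_chains=2, n_warmup=200,
                                 n_samples=200, seed=1))
print(f"WBIC binary {report.wbic_binary:.1f}, years {report.wbic_years:.1f}"
      f" -> {report.selected}")
```

Output (this exact run):

```
max R-hat 1.021
rho posterior mean 0.52
6 negative species, 0 positive
WBIC binary 2716.9, years 2731.9 -> binary
```

The posterior mean of ρ lands near the generating value 0.5 with all
R-hat below the 1.1 convergence threshold; six species are called
significant losers (upper 95% CI bound of their abandonment coefficient
below zero) at this reduced survey size; and the binary coding — the one
the data were generated under — wins the WBIC comparison by ~15 units,
a Bayes factor of ~10^6.5 in its favour.

## Command line

Each analysis stage is also a subcommand:

```sh
occaban simulate --seed 1 --out run/          # synthetic survey + truth
occaban validate --survey run/survey.csv --habitats run/habitats.csv
occaban fit --model m1 --survey run/survey.csv --seed 1 --out run/
occaban compare --survey run/survey.csv --seed 1 --out run/
occaban check --survey run/survey.csv --seed 1 --out run/
occaban project --survey run/survey.csv --habitats run/habitats.csv \
    --range-stack run/range_stack.csv --seed 1 --out run/
occaban run-all --seed 1 --out run/           # the whole pipeline
```

Artifacts (draw tables, diagnostics, map CSVs) are plain text with JSON
manifests recording the config hash and per-stage seeds, so any stage can
be reproduced bit-for-bit.

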