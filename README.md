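# assemblage

Quantify the relative contribution of **selection** and **ecological drift**
in replicated, dispersal-limited microbial time series.

In a closed microcosm experiment sampled by 16S amplicon sequencing, the only
assembly processes that can restructure the communities are selection
(deterministic, driven by fitness differences) and drift (stochastic births
and deaths). The two leave opposite fingerprints on the *similarity between
replicate microcosms*: under homogeneous selection replicates converge on one
equilibrium, so their pairwise similarity rises over time and its spread
shrinks; under drift replicates wander apart, similarity falls and its spread
grows. `assemblage` implements the full analysis that reads this fingerprint,
plus a synthetic microcosm experiment to exercise it end to end:

1. **Simulate** a 2 × 2 factorial crossover design — disturbance (pulsed 1:50
   dilution every 2nd day, `D`) vs. continuous dilution at 1 day⁻¹ (`U`),
   crossed with a 5-fold carrying-capacity contrast (`H`/`L`), 3 replicate
   microcosms each, 17 sampling days over 50 days with the regime switched at
   day 28 — as stochastic logistic growth with demographic, environmental and
   episodic-bloom noise, sequenced by overdispersed multinomial sampling.
2. **Normalise** count tables by averaging many rarefactions to 10,000 reads
   (multivariate hypergeometric subsampling), with Hill diversities of order
   0–2 as the per-sample summary.
3. **Compare** replicate pairs with Bray–Curtis or Sørensen similarity at
   every sampling day (plus PCoA ordination and PERMANOVA R² effect sizes).
4. **Model** the replicate similarity y with a hierarchical Bayesian
   distributional regression,

   ```
   y_n        ~ Normal(mu_n, sigma_n)
   mu_n       = x_n' beta + b_pair(n),   b_pair ~ Normal(0, tau)
   log sigma_n = z_n' gamma
   ```

   with fixed effects of time × disturbance × capacity (3-way) on the mean
   and time × disturbance on the standard deviation, a random intercept per
   replicate pair, mean-centred time, and 4 MCMC chains × 4000 iterations
   (2000 warm-up) retaining 8000 draws.
5. **Classify** each group from the posterior daily slopes
   (Δμ/day, Δσ/day): *selection* iff Δμ ≥ 0 and Δσ < 0, *drift* iff Δμ < 0
   and Δσ > 0, *mixed* otherwise — with the posterior mass of each sign
   quadrant as an uncertainty-aware complement.

## Worked example

```python
import assemblage as A
from assemblage.model import (MCMCConfig, prepare_model_data,
                              fit_distributional_model, derive_group_slopes)
from assemblage.classify import make_assembly_calls, format_report

# a full synthetic experiment: neutral (drift-only) dynamics
taxa = A.neutral_community(seed=106)
counts, metadata = A.simulate_experiment(
    A.DesignSpec(), taxa, A.default_schedules(), seed=106)

norm = A.rarefy_mean(counts, depth=10_000, n_rep=250, seed=106)
metadata = metadata[metadata.sample_id.isin(norm.samples)].reset_index(drop=True)
norm, metadata = A.filter_samples(norm, metadata,
                                  "day == 2 and regime_code != 'inoculum'")

records = A.replicate_similarity_series(norm, metadata, "bray_curtis")
data = prepare_model_data(records, period=1)
fit = fit_distributional_model(
    data, config=MCMCConfig(chains=2, iterations_per_chain=1200,
                            warmup=400, seed=106), rhat_action="warn")
calls = make_assembly_calls(derive_group_slopes(fit))
print(format_report(calls))
```

prints

```
Community assembly calls
============================================================
bray_curtis period 1 group UL: d_mu = -0.0072 +/- 0.0011 /day, d_sigma = +0.0231 +/- 0.0136 /day -> DRIFT (P[selection] = 0.00, P[drift] = 0.96)
bray_curtis period 1 group UH: d_mu = -0.0060 +/- 0.0011 /day, d_sigma = +0.0231 +/- 0.0136 /day -> DRIFT (P[selection] = 0.00, P[drift] = 0.96)
bray_curtis period 1 group DL: d_mu = -0.0081 +/- 0.0014 /day, d_sigma = +0.0169 +/- 0.0149 /day -> DRIFT (P[selection] = 0.00, P[drift] = 0.87)
bray_curtis period 1 group DH: d_mu = -0.0066 +/- 0.0014 /day, d_sigma = +0.0169 +/- 0.0149 /day -> DRIFT (P[selection] = 0.00, P[drift] = 0.87)
```

Every group of this ecologically neutral community shows the drift
fingerprint: the mean Bray–Curtis similarity between replicate pairs falls
by 0.006–0.008 per day while its standard deviation grows, so the calls land
in the drift quadrant with ~90% posterior mass. The convenience wrapper
`assemblage.pipeline.run_scenario_benchmark("selection", seed=106)` runs the
same pipeline on the strong-selection scenario, where the disturbed groups
flip into the selection quadrant (Δμ ≈ +0.007/day with Δσ ≈ −0.10/day,
P[selection] = 1.00).

The same pipeline is scriptable from the shell:

```bash
assemblage all --config my_config.yaml --seed 7 --outdir run7
```

with subcommands `simulate`, `normalize`, `diversity`, `similarity`, `fit`,
`classify` and `report` for stage-wise runs; every artifact carries a
provenance header with the config hash and seed.

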