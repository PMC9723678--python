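# Methods

This note documents the models, the numerical choices, and the reasoning
behind the open design decisions in `assemblage`. It describes what the code
computes; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## The inference problem

In a dispersal-limited, closed culture system monitored by 16S amplicon
sequencing, community assembly can only be shaped by selection and by
ecological drift (dispersal is excluded by the closed vessels; diversification
is negligible on the experiment's timescale at 97% OTU resolution). The two
processes are separated by how the *similarity between replicate vessels*
evolves: homogeneous selection pulls replicates toward one equilibrium, so
their pairwise similarity rises and the spread of similarity values shrinks;
drift pushes replicates apart, so similarity falls and its spread grows. The
pipeline estimates the daily rate of change of both the mean and the standard
deviation of replicate similarity, and reads the pair of signs.

## Distributional regression model

For one similarity index and one cultivation period, every observation is the
similarity `y` of one replicate pair of one regime at one sampling day:

    y_n          ~ Normal(mu_n, sigma_n)
    mu_n         = x_n' beta + b_{p(n)}        b_p ~ Normal(0, tau)
    log sigma_n  = z_n' gamma

* `x_n`: intercept, mean-centred day, disturbance (D vs. U at sampling),
  capacity (H vs. L), and all interactions up to the 3-way term
  (treatment coding, reference levels U and L).
* `z_n`: intercept, centred day, disturbance, day × disturbance. Capacity is
  deliberately absent from the sigma model.
* `b_p`: a random intercept per replicate comparison (e.g. `UDH:r1-r2`),
  absorbing pair-level offsets.
* Time is mean-centred *within the fitted records* so slope and intercept
  estimates decorrelate; the centred-day column of each fit averages to 0 by
  construction.

Periods are fitted separately: the crossover at day 28 swaps the disturbance
label of every microcosm, so a joint fit would conflate the regime effect
with the period effect. Sigma is modelled on the log scale; the downstream
decision rule uses only the *sign* of the sigma slope, which is invariant
under any monotone link, so this choice does not affect the classification.

### Priors

Weakly informative and proper, resolved from the response scale:
mean intercept Student-t(3, median(y), 2.5·mad(y)); mean slopes
Normal(0, 2.5·sd(y)/sd(x)); sigma intercept Student-t(3, log sd(y), 2.5) on
the link scale; sigma slopes Normal(0, 2.5/sd(z)); random-intercept SD
half-Student-t(3, 0, 2.5·mad(y)). When the response is degenerate (mad = 0)
the scale falls back to sd(y), then to 1.

### Posterior computation

The model is conditionally Gaussian, which a blocked Gibbs sampler exploits:

1. `(beta, b)` jointly from the exact multivariate-normal full conditional
   given `gamma` and `tau` (one Cholesky solve per iteration; an escalating
   diagonal ridge guards near-singular precision matrices when sigma
   collapses on near-constant data). The Student-t prior on the mean
   intercept is represented as an inverse-gamma scale mixture, preserving
   conjugacy.
2. Each `gamma` coordinate and `log tau` by univariate slice sampling
   (stepping-out/shrinkage), which requires no step-size tuning. The linear
   predictor of log sigma is clipped to [-11, 25] to keep weights finite.
3. An ancillarity–sufficiency interweaving move re-draws `tau` in the
   non-centred parameterisation (`b = tau·b_raw`, with `tau` entering the
   likelihood); without it, the strong coupling between `tau` and `b` slows
   the centred chain when the number of comparisons is small (the move
   raises the effective sample size for `tau` about five-fold).

Defaults follow the analysis configuration of the study design: 4 chains ×
4000 iterations with 2000 warm-up, retaining exactly
`chains × (iterations − warmup) = 8000` draws. `target_acceptance` is kept in
`MCMCConfig` for interface compatibility but is not used: a Gibbs/slice
scheme has no accept–reject step and therefore no divergences (the
divergence count is reported as 0 by construction). Convergence is monitored
with split-R̂ and bulk/tail effective sample sizes (arviz); a fit raises
`ConvergenceError` when any R̂ exceeds 1.01 unless explicitly overridden.
Parameter recovery on data simulated from the model itself gives ~95%
coverage of the 95% credible intervals for both the mean-slope and the
sigma-slope (checked over 200 replicates in the acceptance tests).

### Group slopes and classification

Under treatment coding, the daily slope of group g is an exact linear
combination of coefficient draws (e.g. for (D, H):
`b_t + b_{t:D} + b_{t:K} + b_{t:D:K}`), evaluated draw by draw; sigma slopes
are per disturbance level. The verdict per group applies the quadrant rule to
the posterior means:

* **selection** iff Δμ ≥ 0 and Δσ < 0,
* **drift** iff Δμ < 0 and Δσ > 0,
* **mixed** otherwise.

The sigma criterion is implemented strictly (Δσ = 0 is mixed): the decision
rule's two formulations differ on the boundary ("non-positive" vs. "< 0"),
and the strict inequality is the conservative reading. Labels come from
posterior means — what a quadrant plot of point estimates shows — and the
posterior mass in each sign quadrant is reported alongside as an
uncertainty-aware complement.

Model comparison (`compare_models`) ranks fits on the identical observation
set by PSIS-LOO expected log predictive density, falling back to WAIC when
the Pareto-smoothing diagnostic flags unreliable importance weights.

## The synthetic microcosm experiment

The generator emulates the study design: 4 cultivation regimes (UDH, UDL,
DUH, DUL; first letter = period-1 disturbance, second = period-2, third =
capacity) × 3 replicates × 17 sampling days in [2, 50] (including the
crossover day 28 and day 50) + 2 inoculum samples = 206 samples. Disturbed
microcosms are diluted 1:50 every 2nd day (and once at inoculation);
undisturbed microcosms are diluted continuously at 1 day⁻¹. A 1:50 pulse
every 2 days corresponds to a continuous rate of ln(50)/2 ≈ 2 day⁻¹.
Sampling happens immediately before a pulse. Read depths are log-normal
(mean 63,460, SD 31,411, truncated below at 10,000).

### Dynamics

Per-taxon discrete-time logistic-with-washout skeleton (step 0.05 d, ≥40
steps per pulse interval keeps the skeleton within 1% of adaptive ODE
integration):

    n_i <- n_i · exp(step·[mu_i·(1 − N/K) − D_t] + noise)

with four stochastic components, each matching a documented feature of real
community time series:

1. **Demographic noise** — the realised abundance is Poisson with the
   skeleton mean, and pulse survivors are binomial. This makes drift
   density-dependent (variance ∝ 1/n), the defining property of ecological
   drift.
2. **Slow environmental noise** — an Ornstein–Uhlenbeck perturbation of each
   taxon's growth rate (stationary SD 0.02 day⁻¹, correlation time 14 d) per
   microcosm, emulating persistent micro-environmental differences between
   vessels. Purely demographic noise self-averages across hundreds of taxa
   and produces unrealistically synchronous replicates; the OU component
   restores abundance-independent, slowly-decorrelating fluctuations, and
   over windows shorter than a few correlation times it makes replicate
   pairs diverge roughly linearly in time.
3. **Episodic blooms/crashes** — at 0.01 events per taxon-day a persistent
   log-normal shock (log-SD 1.0) hits one taxon, emulating the sudden
   outbreaks and collapses characteristic of bacterial communities. Their
   random timing makes between-replicate spread *grow through the window*
   rather than fan out smoothly (a smooth linear fan is absorbed by pair
   intercepts plus a common slope and leaves no heteroscedasticity signal).
4. **Sampling overdispersion** — each taxon's sampling probability is
   jittered log-normally (SD 0.6) before the multinomial read draw, the
   extra-multinomial variation well documented for amplicon counts. Its
   effect on pairwise similarity is rectified while replicates are still
   identical and passes through linearly once they have diverged, so
   measurement-scale jitter grows with divergence — a second contributor to
   the drift-side variance growth.

The carrying capacity is K_low = 10⁶ individuals (K_high = 5·K_low,
mirroring the 5× nutrient contrast). The absolute scale is a free parameter
of the emulation; 10⁶ is chosen so that demographic drift is visible but
does not saturate replicate divergence within a 28-day period (at much
smaller K the mid-abundance taxa decorrelate within days and the similarity
decline is front-loaded, which a linear trend model misreads as shrinking
residual spread).

### Scenarios

* **Neutral** (`neutral_community`): all growth rates equal (2.5 day⁻¹);
  composition changes only through the stochastic components — the
  drift-dominated extreme.
* **Strong selection** (`selection_community`): growth rates follow a
  quantile-spaced log-normal spectrum (CV 0.2) so the gaps between the
  fastest growers are a reproducible design property rather than a draw, and
  fitness is rank-correlated (0.95) with inoculum abundance — an inoculum
  sampled into a culture environment is already enriched for pre-adapted
  taxa. Without this correlation the eventual winner is a bottleneck-survival
  lottery among ultra-rare fast growers and replicate outcomes are
  stochastic rather than selective. Bloom events are disabled in this
  scenario: the two scenarios are intentionally the extremes of the
  stochasticity–determinism axis, and episodic fitness excursions belong to
  the stochastic extreme.

Both scenarios draw the inoculum from a log-normal rank-abundance
distribution (log-SD 2.0, inverse-Simpson diversity ≈ 10 on 400 taxa,
typical of coastal seawater dominance). `TaxonProfile.niche_share` supports
a partially niche-structured variant (per-taxon self-limitation, making the
composition a stable attractor); no default scenario uses it, because it
pins the replicate-similarity trajectory to a flat equilibrium plateau where
the sign-based classification is undefined in practice.

Reproducibility: every stochastic call derives its generator from
(global seed, microcosm id, day, purpose), so single microcosms are
reproducible independent of iteration order, and identical seeds give
bit-identical tables.

### What the generator does and does not emulate

It reproduces the design geometry, depth distribution, overdispersion,
density-dependent drift, and the qualitative selection/drift fingerprints on
replicate similarity. It does not simulate sequences (no chimeras, no OTU
clustering), resource chemistry beyond a scalar capacity, taxon
interactions, or the day-1 adaptation transient of a fresh environmental
inoculum — the pipeline's default exclusion of the first sampling day
mirrors the practice of dropping that transient, not a property of the
generator. Passing tests on synthetic data therefore validate the
statistical machinery and its sign conventions, not any claim about a
particular real community.

## Normalisation and beta diversity

* `rarefy_mean` draws `n_rep` without-replacement subsamples (multivariate
  hypergeometric) of exactly `depth` reads per sample and averages them;
  every output column sums to exactly the depth, expected relative
  abundances are preserved, and samples below the depth are dropped with a
  warning. The averaged table is kept real-valued; re-rounding would break
  the column-sum invariant. Hill diversities of the rarefied vs. raw table
  regress with slope ≈ 1 on deep samples (orders 1–2; order 0 is
  depth-limited by construction).
* Bray–Curtis similarity `1 − Σ|x−y| / Σ(x+y)`; Sørensen is the same index
  on presence/absence. Both are symmetric and invariant to joint rescaling.
* PCoA is classical scaling of the double-centred Gower matrix; negative
  eigenvalues are reported but get no axis (no Cailliez correction by
  default). PERMANOVA computes R² = SS_between/SS_total from pairwise
  dissimilarities with the permutation p-value using the +1 correction
  (default 999 permutations); its type-I error is calibrated at the nominal
  5% under label exchangeability.
* Replicate similarities are computed on the averaged-rarefied table (the
  normalised table is the one carried forward by the analysis); pair labels
  are sorted lexicographically so `comparison_id` is stable across days.

## Benchmark problem sizes

The end-to-end scenario benchmark (`pipeline.run_scenario_benchmark`, used
by the acceptance tests and `scripts/acceptance.py`) runs the full design
with rarefaction `n_rep = 250` (the full analysis default is 1000; below
~100 the residual rarefaction noise measurably dilutes the sigma-slope
signal) and 2 chains × 1200 iterations (400 warm-up) per fit, with R̂
monitoring demoted to a warning inside batch runs. Parameter-recovery
calibration uses 2 × 750 (250 warm-up) chains.

## Known limitations

* The sigma-slope sign — half of the drift fingerprint — is intrinsically
  power-limited at the study's design size (3 replicate pairs × 9 period-1
  sampling days × 4 regimes): under the neutral scenario its true value is
  ≈ +0.012 day⁻¹ against a combined realisation-plus-posterior spread of
  ≈ 0.017, so roughly a quarter of neutral experiments yield a "mixed"
  rather than "drift" verdict even though the mean-similarity slope is
  negative in essentially every run. The quadrant probabilities make this
  uncertainty visible where the point-estimate label hides it.
* The classification is a knife edge for converged systems: once replicates
  have reached a common equilibrium, Δμ fluctuates around 0 and the
  selection/mixed boundary is decided by noise. This mirrors the rule
  itself, which assigns Δμ = 0 to selection only when the variance is also
  shrinking.
* The Gibbs sampler is specific to the Normal distributional model with a
  log (or identity) sigma link and a single random-intercept grouping; it is
  not a general-purpose regression engine.
* PERMANOVA implements free permutation only (no strata), matching the
  one-way use here.
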