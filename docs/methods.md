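# Methods

`leafstem` implements a comparative-phylogenetic analysis of evolutionary
allometry in a clade of epiphytic ant-plants (Hydnophytinae-like study
system): how the scaling of stem cross-sectional area with leaf area
changed as ant-housing domatia and different mutualistic strategies
evolved, and how leaf and stem size relate to climate. This note records
the models, the numerical choices, and what the synthetic data can and
cannot establish.

## Trees and covariances (`phylo_core`)

A rooted, dated tree (Newick input, parsed with dendropy) is held in flat
arrays (parent pointers, branch lengths, postorder). All continuous-trait
models are multivariate normal over tip values with covariance read off
the tree:

- **BM**: `V_ij = sigma^2 * t_ij`, the shared root-to-MRCA path length.
- **OU**, two forms. *Stationary*: `V_ij = v * exp(-alpha * d_ij)` with
  `d_ij` the patristic distance — the unit-variance version is the
  Martins–Hansen correlation used as the PGLS error structure, the
  standard choice for GLS on ultrametric trees. *Fixed-root*:
  `V_ij = sigma^2 * exp(-alpha*d_ij) * (1 - exp(-2*alpha*t_ij)) / (2*alpha)`,
  which tends to BM as `alpha -> 0`; the nine-model likelihood comparison
  uses this form so OU properly nests BM.
- **lambda/kappa/delta**: Pagel's transforms (off-diagonal scaling,
  per-branch-length power, node-depth power).
- **EB**: exponentially decaying rate, `V_ij = sigma^2 (e^{r t_ij}-1)/r`.
- **trend**: rate changing linearly in time; **drift**: a linear time
  trend in the mean with BM covariance. On an ultrametric tree the drift
  mean trend is collinear with the intercept, so its slope is fixed at 0
  and a warning is emitted; trend is warned about in the same situation.
- **white**: diagonal (star phylogeny).

Ancestral states under BM use the two-pass message-passing (GLS)
algorithm; the root estimate is the GLS mean. Ultrametricity is judged at
1e-6 relative tolerance on tip depths.

## Nine-model selection (`trait_models`)

For every model the root state and overall rate are profiled analytically,
leaving at most a one-dimensional structural parameter, optimized by
bounded search from five dispersed starts (OU attraction in log space over
[1e-7, 1e3]/tree-height — these surfaces are flat and multi-started on
purpose). Ranking is by AIC (`k` counts the root state and rate: BM/white
2, all others 3); ties break toward fewer parameters, then model name.

## PGLS allometry (`pgls_allometry`)

Specimens carry one stem diameter and ~10 leaf areas each. Stems are
assumed circular (`area = pi r^2`). Species values are the **mean of
log-transformed measurements** (natural log by default; the log base is
configurable and only intercepts depend on it). The regression of log stem
area on log leaf area is GLS with the OU correlation `exp(-alpha d_ij)`;
`alpha` is profiled by **REML** (ML available). REML was chosen because at
the study scale (n = 60 species) ML-profiled alpha gives slightly
anticonservative standard errors — measured 92.8% coverage of a nominal
95% slope interval over 500 simulated datasets, against 93.4% (slope) and
95.2% (intercept) under REML. The reported log-likelihood is the ML value
at the chosen alpha so model comparison stays on one scale. Per-coefficient
F statistics are `t^2` on (1, n-2) df. Residuals (observed minus fitted,
in tree order) are the species-specific allometry scores. Per-group fits
prune the tree to each group's species; groups under 4 species are skipped
with a warning.

## Phylogenetic ANOVA and OU shifts (`shift_inference`)

The ANOVA compares the classic one-way F of the residual scores against F
values from BM simulations on the tree (rate estimated from the data by
ML); `p = (#{F_sim >= F_obs} + 1)/(nsim + 1)`. Pairwise post-hoc t
statistics use the same simulated null and Holm correction. The default
simulation count follows the study setting of 10,000.

The shift search models the scores as a single-alpha, single-sigma^2 OU
process whose optimum `mu` changes on selected branches (Hansen weight
matrix; the ancestral optimum absorbs the stationary start). Forward
stepwise: every candidate branch (clade of >= 2 tips, not the whole tree)
is evaluated by refitting with one more optimum; the best candidate joins
the list, labelled S1..Smax in addition order with the AIC path reported
for 0..nmax shifts. **Stopping rule**: the default criterion is a
location-penalized BIC (BIC plus `2 ln(#candidate branches)` per shift).
Plain AIC cannot control false shifts here: under no-shift OU data the
best of ~2n candidate branches improves 2*lnL by ~7.5 on average (n = 60),
far above AIC's penalty of 2, so an unpenalized stepwise search adds a
spurious shift essentially always — the familiar selection effect that
motivated penalized criteria for OU shift detection. With the location
penalty the measured false-shift rate is ~5% at n = 60 while an 8-SD
planted shift is still recovered in ~100% of replicates. `criterion="AIC"`
and `"BIC"` remain available.

Phenograms place every node at (depth, value) with BM ancestral estimates
for internal nodes.

## Discrete characters (`discrete_evolution`)

Binary Mk with exact 2-state transition probabilities; flat root prior
(1/2, or 1/4 per joint state in Pagel models). ER (k=1) vs ARD (k=2) by
AIC. Stochastic maps: upward pruning, downward node-state sampling, branch
histories by uniformization (rejection-free, terminates at any rate).
Summaries report node state frequencies, expected state occupancy and
expected transition counts.

MCMC ancestral states run a Metropolis-Hastings chain over the ER rate
(log-scale proposals, exponential prior with mean 10/tree-height) and draw
a tree uniformly from the sample each iteration; at each thinned sample
the analytic marginal reconstruction is accumulated, so posteriors
integrate over rate and tree uncertainty. Nodes are identified across
trees by their subtended tip set; sets present in fewer than half the
trees are reported unreconstructable. Proposal scale is tuned in a 20%
burn-in toward 20-40% acceptance. The full reversible-jump-over-model
space used by some Bayesian packages is deliberately simplified to a
fixed-structure chain; ER/ARD comparison is done by AIC instead.

Pagel's test compares the 4-rate independent model (each trait's gain/loss
ignores the other trait; double transitions zero) with the 8-rate
dependent model over joint states, by stepping-stone marginal likelihoods:
`logBF = 2 (SS_dep - SS_indep)`. A fast ML variant (`pagel_test_ml`)
exists for screening.

## Stepping-stone engine (`bayes_correlation`)

Power posteriors `prior * lik^beta` along the quantiles of Beta(0.4, 1)
(stones crowd near the prior, where the integrand changes fastest). One
chain visits the ladder cold-to-hot, warm-starting each stone. Two
proposal kernels alternate: a componentwise Gaussian random walk whose
scales adapt during each stone's burn-in (30%, discarded) toward ~35%
acceptance, and an **independence proposal** fitted to the previous
stone's samples (diagonal Gaussian, 1.3x inflated, standard Hastings
correction). The independence kernel matters: adjacent power posteriors
nearly coincide, so it accepts often and repairs the slow componentwise
mixing that otherwise biases the marginal-likelihood sum downward at desk
settings. Each stone contributes `log mean exp((beta_{k+1}-beta_k) lnL)`
over its retained samples; a stone whose log-likelihood trace has ESS < 20
flags the run's diagnostics. On a conjugate normal-mean toy with analytic
evidence, 50 stones x 1,000 iterations recovers log Z within ~0.05 (max
over 10 seeds ~0.07).

The trait-climate model is a bivariate Brownian random walk: tip values of
(trait, climate) are MVN with covariance `kron(R, C)`; the likelihood is
evaluated through Cholesky factors of R and C separately. Priors: root
means normal around the trait mean with 10-SD spread; variances
half-normal scaled to 5x the empirical rate (sampled on the log scale with
Jacobian); `rho = tanh(z)` with a uniform(-1, 1) prior on rho. The
no-correlation model fixes `rho = 0`. Bayes factors are
`2 (SS_corr - SS_noncorr)`, classified at 2/5/10 (half-open intervals,
open-ended top class). The full grid is 3 traits x 19 bioclim variables x
3 species summaries = 171 pairs, 342 model runs; each run's seed is a hash
of its identity so execution order is irrelevant. Desk defaults are 20
stones x 500 iterations; the canonical print setting (100 x 1,000) is one
argument away.

## Climate summaries (`climate_summaries`)

Cleaning removes exact duplicate (species, lon, lat) rows, (0,0)
coordinates and unparseable/out-of-range coordinates, with a per-reason
report; no coordinate rounding or spatial thinning. Summaries are the
per-species mean and the type-7 (linear interpolation) 5%/95% quantiles of
each bioclim variable; single-occurrence species collapse all three with a
warning.

## Synthetic data (`synthetic_data`)

Generators are pure functions of (config, seed) using dedicated
`SeedSequence` substreams per purpose. Defaults mirror the study scale:

- pure-birth tree, 70 tips, unit height;
- log-log allometric line slope 0.60, intercept -4.58 (the whole-clade
  values), group intercepts overridable (e.g. -2.88 for specialized
  ant-plants); log leaf area from BM (root 7.0 ~ 1,100 mm^2, rate 2.0);
  residuals stationary OU with SD 1.0 and attraction 2.0 per tree height,
  optionally with optimum shifts painted on known branches;
- specimens: ~10 leaves per stem (Poisson), 15% lognormal measurement
  noise on areas and diameters (multiplicative error is the plausible
  regime for herbarium measurement);
- binary characters by exact CTMC simulation (independent or dependent
  4-state generators), group labels painted on sizeable non-nested clades
  to mimic phylogenetically clustered strategies;
- occurrences: per-species bioclim centres with within-species scatter, a
  chosen variable correlated with a trait at a set rho, optional planted
  duplicates and (0,0) rows for the cleaner.

What this does **not** emulate: real measurement covariance between leaves
of one specimen, non-Yule tree shape, spatial autocorrelation of climate,
gradual (non-shift) trends in allometry, missing data. Passing tests
establish internal correctness and calibration under the generating
models, not the field validity of the original measurements.

## Problem sizes and determinism

The acceptance checks run at: 50 whitening instances (10-60 tips), 500
coverage replicates (60 tips), 500 ANOVA null replicates (30 tips, 500
simulations each), 100 shift-recovery and 200 shift-specificity replicates
(60 tips), 2,000 stochastic maps per fixture, 10 stepping-stone seeds at
50 x 1,000, and 10 Pagel pairs at 200 tips with 10 stones x 300
iterations. These sizes give Monte-Carlo error well inside the asserted
bands while keeping a full run in minutes on one core. Every random draw
descends from an explicit seed; reruns are bit-reproducible.

## Known limitations

- The OU error structure for PGLS is the stationary correlation form;
  non-ultrametric trees are accepted but the form is best motivated for
  ultrametric ones.
- The shift search is greedy (forward stepwise with refits), not
  exhaustive; exhaustive enumeration is feasible only for toy trees.
- Pagel marginal likelihoods at small n are prior-sensitive: with the
  diffuse exponential rate priors, weakly-informative data can yield
  logBF near or below 0 even when ML prefers dependence — the Occam
  penalty of four extra rates is real and intended.
- `mcmc_ancestral_states` implements the ER chain only; ARD rates are fit
  by ML.
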