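# Methods

## Scope and model

`linkrisk` quantifies the risk that individual plant–animal links pose to
mutualistic communities, combining an empirical vulnerability index with a
dynamical measure of each link's contribution to community feasibility,
and testing whether both are taxonomically conserved. This note records
the model, the numerical choices, what the synthetic data generator does
and does not emulate, and the design decisions that were genuinely open.

### Link vulnerability

For each network, present-link weights are log10-transformed and min–max
rescaled to [0, 1] (`f_std`); link generalisation is the mean of the two
endpoint binary degrees (`D_raw`), min–max rescaled the same way
(`D_std`, no log transform). Vulnerability is V = (1 − f_std)(1 − D_std).
A column with no variation (all weights equal, or all generalisations
equal) is mapped to 0.5 for every link: ties carry no ranking
information, and the midpoint keeps V defined without dividing by zero.
Degrees are presence-based, not weighted.

### GLV feasibility

Community dynamics follow a generalized Lotka–Volterra mutualism model:
plants and animals grow at intrinsic rates r, compete within guilds
through a mean-field matrix (diagonal 1, off-diagonal ρ, with ρ ∈ {0,
0.01} in standard runs), and benefit across guilds through
γ_ij = γ₀·L_ij/d_i^δ. At equilibrium r = B·N with the block matrix
B = [[α, −γ_P], [−γ_A, α]], so the feasibility domain — growth-rate
vectors compatible with positive abundances for every species — is the
cone spanned by B's columns.

**Trade-off δ.** Estimated by a single least-squares fit on the stacked
two-guild design: each link contributes a plant-side and an animal-side
observation of log(f/(d_plant·d_animal)) against the log focal-species
degree, with guild-specific intercepts and one common slope; δ is minus
that slope. The fit is exact (machine precision) when link frequencies
follow the planted power law and every link joins equal-degree partners.

**Stability threshold and γ₀.** The model community is globally stable
when the symmetric part (B + Bᵀ)/2 is positive definite. Because the
smallest eigenvalue of the symmetric part is concave in γ₀ and positive
at γ₀ = 0, the stable set is an interval [0, γ₀max); γ₀max is found by
doubling-then-bisection to relative tolerance 1e-6 (Cholesky as the
definiteness test). Since the mean mutualistic strength scales linearly
in γ₀ at fixed topology and δ, "half the average strength at the
stability threshold" is implemented as γ₀ = γ₀max/2. γ₀ is calibrated
once per network on the original topology and held fixed across link
removals, so per-link contributions are comparable within a network;
degrees are recomputed after each removal, so the γ of the remaining
links changes as the model prescribes. At ρ = 0 the threshold has the
closed form 1/σmax of the scaled adjacency, which the tests use as an
independent oracle.

**Ω estimators.** Two are shipped, both invariant to positive rescaling
of B's columns (so the removal ratio is well defined under either):

- `solid_angle`: the fraction of isotropic random growth-rate directions
  r with B⁻¹r > 0; unbiased, with binomial standard error, and checkable
  against analytic values (identity B of size S gives exactly 2⁻ˢ).
  Because the cone's solid angle shrinks roughly geometrically with
  community size S, direction samples stop hitting the cone beyond
  S ≈ 12; this estimator is therefore reserved for small-community
  validation, where it anchors the implementation to closed forms.
- `center_deviation` (pipeline default): the analytic center of the cone
  is r_c ∝ Σ_k B_k/‖B_k‖ (normalised sum of normalised generators; it is
  strictly interior whenever B is invertible, since B⁻¹r_c is a positive
  combination of basis vectors). For each random great-circle direction,
  bisection to 1e-4 rad finds the critical arc angle θ* at which the
  rotated growth-rate vector leaves the cone (θ* = π if it never does);
  Ω is the mean θ*/π. This mirrors the center-plus-perturbation
  construction verbatim and remains informative at any S. The choice of
  the mean (rather than a quantile) as the summary of tolerated
  deviations is a design decision, flagged here.

In the plane the two definitions coincide (both equal cone angle / 2π)
and both match a dense angular-grid oracle. In higher dimensions they
measure different functionals of the cone — volume versus mean angular
radius — and their rank orders over systems agree closely (Spearman 0.98
over a random panel in the tests). They do **not** agree on the rank
order of per-link removal ratios: removing one link changes the cone's
shape as well as its size, and a cone can lose volume while the mean
angular radius measured from its own (shifted) center grows. The
cross-estimator robustness test therefore checks rank agreement of Ω
across systems and sign agreement of contributions, not per-link rank
agreement.

**Contribution and exclusion.** I = 100·Ω_O/Ω_R − 100, with both Ω's
estimated on the same direction sample (common random numbers), which
cancels most Monte Carlo noise in the ratio; positive I means removal
shrinks the safe operating space. A link whose removal would leave either
endpoint with no partners is flagged `excluded` and never scored; records
are retained so the exclusion count is reportable. Default direction
counts: 10,000 per network in the API, 2,000 in the standard pipeline
configuration (chosen as the point where ratio noise is well below
between-link differences on the default metaweb).

### Taxonomic consistency

Links are aggregated to genus, family and order interactions; singleton
interactions are dropped. Property values are made relative first:
vulnerability (and, for the supplementary analyses, frequency and
generalisation) is min–max rescaled within each network (tie rule 0.5);
feasibility contribution is already a relative percent and passes
through. For each interaction, the sample variance (n−1 denominator
throughout) of its links' values is compared with `n_null` same-size sets
drawn without replacement from all other links at that level; P is the
proportion of null sets with strictly lower variance, consistency is
mean(Var_null − Var_obs) > 0, and significance is declared at P < 0.05.
Ties between null and observed variance count as "not lower", per the
strict inequality; on data with point masses this makes the test
conservative, and a group of exactly equal values is automatically
significant (P = 0) — both behaviors follow from the definition, which is
why calibration checks need effectively continuous properties. The null
pool is drawn per aggregation level from the same level's links, and the
test is invariant to relabelling of network ids.

### Risk regression

The headline model is a linear mixed model (REML, via statsmodels) with
feasibility contribution as response, vulnerability as fixed effect and a
per-network random intercept. Reported: slope, its standard error, Wald
χ² = (slope/SE)² on 1 df, and the mixed-model R² decomposition
R²m = σ²_f/(σ²_f+σ²_α+σ²_ε) and R²c = (σ²_f+σ²_α)/(σ²_f+σ²_α+σ²_ε), with
σ²_f the sample variance of the fixed-effect linear predictor, σ²_α the
random-intercept variance and σ²_ε the residual variance. REML rather
than full ML is a deliberate choice (noted in the model report); a
zero-variance response returns a flagged singular result instead of
raising. Diagnostic fits with the same random-effect structure separate
the two vulnerability ingredients (contribution on generalisation, on
frequency, and log-generalisation on log-frequency, whose marginal R² is
the share of generalisation variance that frequency explains).

## Synthetic metaweb generator

The generator emulates the statistical structure the analyses assume:
shared plant/animal species pools with a nested genus→family→order
taxonomy; per-network sampling of those pools; heterogeneous, heavy-tailed
degrees; log-normal visitation rates following a degree power law with a
planted trade-off; and optional interaction-level consistency. Its
defaults (10 networks, 60/90-species pools, ~35 links per network at
connectance ≈ 0.2, δ = 0.339, log-normal noise σ = 0.3) are the standard
study conditions for tests and the acceptance script.

Structure comes from matched bipartite modules: each network's included
species are partitioned into complete bipartite blocks with equal plant
and animal counts, sizes drawn from a discretised log-normal calibrated
so the size-weighted mean hits the target connectance. On a pure module,
every link joins equal-degree partners, which is exactly the condition
under which the pooled two-guild regression identifies the planted
trade-off to machine precision — the generator's noise-free configuration
(frequency noise 0, cross links 0) is therefore an exact identifiability
fixture. On top of the modules, sparse cross-module links
(`cross_link_prob`, default 0.08) blur the degree classes the way
imperfect compartmentalisation does in field data; without them,
generalisation takes a handful of exact values per network and the
consistency test's strict-inequality P turns tied groups into automatic
positives. Link frequencies follow
ln f = a₀ + (1 − δ/2)(ln d_plant + ln d_animal) plus noise, which reduces
to the exact power law on pure modules. Because cross links join partners
of unequal degree, the default configuration attenuates the pooled slope
somewhat (δ̂ typically 0.23–0.33 for a planted 0.339, seed-dependent);
unbiasedness holds in the pure-module configurations, which is where the
identifiability checks run.

Networks include at most one species per genus per guild (each genus
enters with the inclusion probability and contributes one random
representative). This makes genus-level interactions recur only across
networks, so with `consistency_planted=False` the generator is a true
null for the consistency test: measured type-I error sits at the nominal
5% (slightly conservative, from residual discreteness ties). Planted
consistency attaches a latent offset per genus pair (SD
`between_interaction_sd`) realised per link (SD `within_interaction_sd`)
on the log-frequency scale; it propagates through the real pipeline into
frequency and vulnerability rather than being written into V directly.
Because generalisation is deliberately left unplanted (its module lottery
is independent across networks), frequency shows near-complete positive
consistency under strong planting (>0.95 in tests) while vulnerability
inherits a clear majority (~0.75).

What the generator does **not** emulate: same-network duplicate links of
one interaction (congeneric species sharing a partner in one community —
supported by the aggregation code and covered by hand-built fixtures, but
excluded from generated data to keep the null exchangeable); visitation
driven by abundance dynamics; spatial or phenological structure; sampling
effort gradients; and integer count data (weights are continuous positive
rates so the log-scale laws hold exactly). Passing tests on this
generator show the estimators and tests behave correctly under the
model's own assumptions, not that field data satisfy those assumptions.

## Numerical choices and degenerate inputs

- Stability bisection: relative tolerance 1e-6, bracket doubling capped
  at 2⁴⁰; arc bisection: 1e-4 rad; Ω matrices solved through one LU
  factorisation per topology; singular or ill-conditioned B (cond >
  1e12) raises instead of returning garbage.
- Min–max with zero range → 0.5 everywhere (frequency, generalisation,
  relative rescaling alike).
- All-zero rows/columns are pruned on ingestion with a warning; a network
  left with fewer than two species in either guild is rejected as
  degenerate.
- A trade-off design without degree variation raises an
  unidentifiability error; a star-only dataset therefore requires a fixed
  δ configuration, under which all links are excluded and the regression
  stage reports an empty-input flag rather than failing.
- Per-unit seeds derive from the master seed by hashing stage and network
  labels (all below 2³¹ and recorded in the run summary); identical
  configurations reproduce artifacts byte-for-byte.
- Sampling intensity is sqrt(total events / (n_plants·n_animals)); the
  literature formula behind this descriptor is not restated in most data
  sources, so the root-mean-events-per-cell form is documented here as
  the package's convention.

## Known limitations

- The center-deviation Ω summarises boundary distance by the mean arc;
  quantile summaries would weight narrow cone directions differently.
- γ₀ shared across removals (rather than re-calibrated per removed
  topology) is a comparability choice; re-calibration would mix
  threshold shifts into the contribution.
- The mixed model assumes a common slope across networks; no random
  slopes are fitted.
- Default problem sizes (10–20 networks, a few hundred links, 2,000
  directions, 200–1,000 null draws) are chosen so the full pipeline and
  its tests run in minutes on one core while keeping Monte Carlo error
  well below the effects of interest; field-scale runs simply raise the
  direction and null counts in the configuration.
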