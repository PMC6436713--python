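# Methods

`ordcar` implements a Bayesian hierarchical proportional-odds model for an
ordinal health-facility outcome observed on patients nested in facilities
nested in counties, with spatially structured county effects. This note
records the model, its priors, the sampler, the synthetic-data design used
for validation, and the numerical and design choices a maintainer would
want to know.

## The model

For patient *i* treated in facility *j(i)* located in county *c(i)*, the
outcome y ∈ {1, …, K} (K = 3 in the motivating design: no contraceptive
method, less-effective method, highly effective method) follows the
cumulative-logit (proportional-odds) law

    P(y_i ≤ k) = logit⁻¹(κ_k − η_i),        k = 1, …, K−1,
    η_i = x_i'β + f_{j(i)} + u_{c(i)} + φ_{c(i)},

with κ_0 = −∞, κ_K = +∞ and strictly increasing cutpoints κ. The design
matrix carries no intercept: a constant column is unidentifiable because
the cutpoints absorb the location of the latent scale (the likelihood is
exactly invariant under adding a constant to η and to every κ, a property
the test suite checks). Coefficients are reported as odds ratios exp(β):
OR > 1 means higher odds of a more effective outcome category.

Random-effect structures:

| structure      | county terms | interpretation |
|----------------|--------------|----------------|
| `none`         | —            | facility clustering only |
| `unstructured` | u            | exchangeable county heterogeneity |
| `structured`   | φ            | spatially smooth county field (intrinsic CAR) |
| `convolution`  | u + φ        | BYM-type sum of both |

Facility effects f are iid N(0, 1/τ_v) and are on by default in every
structure; they can be switched off.

The intrinsic CAR prior on φ is, with w_ij = 1 for neighbouring counties
and L the graph Laplacian,

    log p(φ | τ_c) = −(τ_c/2) Σ_{i~j} (φ_i − φ_j)² + const
                   = −(τ_c/2) φ'Lφ + const,

the pairwise sum running over unordered neighbour pairs once (the dense
Laplacian form is the testable statement of that convention). The prior is
invariant to a constant shift of φ; identification is by a sum-to-zero
constraint, imposed in the sampler by re-centring φ after every sweep, and
in the conjugate update by removing one degree of freedom per connected
component of the county graph.

## Priors

All normal distributions are parameterised by precision and all Gamma
distributions by shape and rate, matching the convention of the
hierarchical-modelling software the analysis design mirrors. Defaults:

| parameter | prior | note |
|---|---|---|
| β, patient block `b` | N(0, prec 0.001) | sd ≈ 31.6, effectively flat |
| β, blocks `s`, `q`, `m` | N(0, prec 1e-6) | facility/county blocks |
| g1 (= κ1) | N(0, prec 0.01) | |
| g2 (cutpoint increment) | Gamma(0.001, 0.001) | sampled on the log scale |
| τ_h (county u) | Gamma(0.5, 0.0005) | |
| τ_c (CAR) | Gamma(0.5, 0.0005) | |
| τ_v (facility f) | Gamma(0.001, 0.001) | near-improper; see limitations |

Cutpoints are stored as (g1, positive increments), κ_2 = g1 + g2, so the
ordering κ1 < κ2 holds by construction in every state the sampler can
reach. The implementation is generic in K ≥ 2 although the motivating
design fixes K = 3.

## Sampler

Metropolis-within-Gibbs, one full scan per iteration:

- **β and cutpoints** — single-site adaptive random-walk Metropolis per
  coefficient; g1 on its natural scale, each cutpoint increment on the log
  scale with the Jacobian folded into the acceptance ratio (in z = log g2
  the prior-plus-Jacobian term is shape·z − rate·eᶻ, evaluated in log
  space so the very diffuse default prior cannot overflow).
- **f and u** — all sites proposed at once with independent accept/reject
  per site. This is exact because facilities (and counties) partition the
  patients, so the likelihood factorises over sites and the iid prior adds
  no cross-terms.
- **φ** — updated by colour classes of a greedy colouring of the county
  graph: within a class no two counties are adjacent, so the CAR prior's
  neighbour sums are constant during the class update and the sites are
  conditionally independent. After the sweep φ is re-centred to mean zero
  (its mean is exactly zero in every retained draw).
- **precisions** — conjugate Gibbs: τ | θ ~ Gamma(a + m/2, b + Σθ²/2) for
  iid effects, and Gamma(a + (n−c)/2, b + ½Σ_{i~j}(φ_i−φ_j)²) for the CAR
  field with c connected components.

Proposal scales adapt during burn-in by Robbins–Monro toward 35%
acceptance (the middle of the usual 20–45% band for single-site random
walks) with step size min(0.3, 2/√t), and are frozen for all retained
draws so the post-burn-in kernel is fixed. One master seed drives a
`SeedSequence`; per-chain streams are spawned from it, and identical
configurations give bit-identical draws.

Default chain lengths follow the published analysis settings: screening
fits use 1,000 retained draws after 1,000 burn-in (`BIVARIATE_MCMC`), and
the preset for final multivariable fits is 10,000 draws with thinning 100
(`MULTIVARIABLE_MCMC`); most validation fits in this repository use
shorter chains (typically 1,500–2,500 retained draws after 500–1,500
burn-in), which profiling showed to be well past the mixing times of these
posteriors at the problem sizes used.

## Model comparison

DIC = D̄ + pD with pD = D̄ − D(θ̄), where D = −2·log-likelihood, D̄ is the
mean over retained draws of the stored per-draw deviance, and D(θ̄)
evaluates the deviance at the posterior means of *all* parameters,
random effects included (the "focused" plug-in that matches the BUGS
convention). Both components are stored so either reading of the DIC
definition is recoverable. Lower DIC is better. Note that pD is a Monte
Carlo estimate: its noise is a few units at typical chain lengths, which
is why single-parameter pD differences are not interpretable.

## Survey weights

The facility design weight is sw = 1/(ps·pr) with ps the sampling fraction
and pr the response rate; with the published ps = 0.1233 and pr = 0.94
this gives 8.6279 (at the print's truncation; the exact product gives
8.62798). Weights are normalised to mean one over the analysis sample by a
single global rescale, which preserves all within- and between-stratum
ratios and is idempotent. Weights enter descriptive tabulations only: the
posterior uses the unweighted likelihood (matching the modelling code the
design mirrors), with a weighted log-likelihood available as a diagnostic.

## Synthetic-data generator

Because the motivating study's microdata are not publicly deposited, all
validation runs on synthetic studies with the same architecture. The
default configuration (`study_config`) reproduces the study's dimensions —
47 counties, 281 facilities, 2,568 patients — on a random-planar county
graph (Delaunay triangulation of random points, which gives the irregular
bounded-degree adjacency of a real county map; a lattice generator is also
available). Facilities are allocated to counties by multinomial draw after
guaranteeing every county one facility (the study does not state an
allocation rule; county sizes are configurable), and patients to
facilities likewise.

The default covariate plan spans the structure of the real questionnaire
rather than its joint distribution: a three-level patient categorical
(age group), two binary patient covariates (previous abortion, prior
modern-method use), a three-level patient categorical with an 8% distinct
"missing" code (pregnancy wantedness, exercising the missing-as-category
path), a facility-level binary (public ownership) and continuous
(number of methods available, standardised), and a county-level continuous
covariate (skilled ANC coverage, standardised). True coefficients are the
published convolution-model odds ratios on the log scale. Default
precisions τ_h = 16, τ_v = 11, τ_c = 1.5 give county, facility and spatial
effect scales of roughly 0.25, 0.30 and 0.4 sd on the latent scale —
moderate clustering of the kind facility surveys show. Default cutpoints
(1.0, 3.5) offset the plan's mean linear predictor (≈ +1.2) so the
marginal outcome split lands near the surveyed 45/46/9 distribution.

CAR fields are drawn exactly on the sum-to-zero subspace by
eigendecomposition of the graph Laplacian (the intrinsic prior is improper
on the full space; the constrained subspace draw is the standard fix).
The generator records every realised random effect and the latent η in a
truth record, making recovery studies and clustering checks (one-way
ANOVA of η on county) possible.

What the generator does *not* emulate: the real covariate joint
distribution and its collinearity, informative facility sizes, item
nonresponse beyond the single missing-coded covariate, and any
patient-level spatial information below the county. Passing recovery tests
therefore show the estimator is correct under the model's own assumptions,
not that the published coefficient values are right.

## Validation design

- **Oracles.** The log-likelihood is checked to 1e-10 against per-row
  enumeration; the CAR density against a dense-Laplacian quadratic form on
  100 random graphs; conjugate updates against analytic Gamma moments; the
  no-random-effects likelihood against an independent ordinal MLE
  (statsmodels `OrderedModel`) through direct numerical maximisation.
- **Prior recovery.** With an empty dataset the chain targets the prior;
  KS distances at 10,000 retained draws are required below 0.06 for the
  coefficient blocks and 0.10 for the county precisions (thresholds set
  from effective-sample-size considerations for adapted random-walk and
  hierarchical-Gibbs chains). The facility precision's Gamma(0.001, 0.001)
  prior is excluded: its log-density is nearly flat over hundreds of log
  units, and no local chain can traverse that support in any realistic
  number of draws — a known property of such near-improper hyperpriors,
  not a sampler defect.
- **Parameter recovery.** Five replicate convolution studies at the full
  study dimensions; for each coefficient the replicate-averaged posterior
  mean must fall within 0.15 of truth, and pooled 95% intervals must cover
  at least 90% of true coefficients. The averaged-bias form is the
  standard recovery design: a per-replicate bound of 0.15 would sit at
  ~2σ of the sampling distribution of a dummy-covariate posterior mean at
  n = 2,568 and would fail occasionally for a perfectly correct sampler.
- **Structure selection.** Six scenario runs (two replicates generated
  under each structure) are each fitted under all three structures; DIC
  must rank the generating structure best in the majority of runs. The
  scenario design matters more than one might expect, because the three
  structures are *near-equivalent representations* of any county field:
  facility effects can absorb a county field outright, an iid county term
  can represent a smooth field (and a diffuse CAR a rough one) with only
  a hyperprior-efficiency penalty, and when the field scale is large
  relative to the per-county standard error no prior shrinks and the DIC
  gaps fall inside Monte-Carlo noise (observed gaps of a few units with
  random sign in data-rich designs). The selection study therefore turns
  facility effects off and places the county-field scale near the
  per-county standard error (15 patients per county, field sd ≈ 0.5–0.8),
  the regime where iid versus spatially-borrowing shrinkage genuinely
  changes the fit; the field-recovery RMSE of the matched structure is
  lowest in every scenario, confirming the machinery independently of
  DIC. Structured-versus-convolution remains a documented near-tie.
- **Screening calibration.** With near-flat coefficient priors the 85%
  credible interval behaves approximately like an 85% confidence interval,
  so a pure-noise covariate should pass the screen in ≈ 15% of replicates;
  over 40 replicates the hit count must stay within the binomial 3σ band.

Problem sizes in the routine test suite (a few hundred to ~2,600 patients,
chains of a few thousand iterations) were chosen as the smallest at which
the targeted effects clear Monte-Carlo noise.

## Numerical choices

- Category probabilities are differences of `scipy.special.expit`
  evaluations, clamped at 1e-300 before the log; the log-likelihood is
  finite for all finite η and cutpoints.
- Proposals that would push log g2 beyond ±600 are rejected outright
  (zero prior mass at the representable boundary).
- Chain initialisation: β = 0, effects 0, precisions 1, cutpoints from the
  empirical cumulative outcome frequencies (clipped to [0.02, 0.98] and
  spread by 0.1 if degenerate).
- Posterior-mean plug-ins for DIC average κ draw-wise (the mean of
  increasing vectors is increasing, so the plug-in cutpoints are valid).
- Adjacency JSON stores the flattened neighbour list, per-county counts
  and unit weights; symmetry, self-loops and index ranges are validated on
  construction, and disconnected graphs are reported with their
  components.

## Open design points and how they were resolved

- The mapped county quantity is exp(u + φ), labelled an **odds
  multiplier**: the model is an ordinal logit, so calling the surface a
  "risk ratio" (as choropleth conventions sometimes do) would misname the
  scale.
- Screening significance is operationalised on the OR scale — the
  equal-tailed 85% interval for exp(β) excluding 1 — which is equivalent
  to the coefficient interval excluding 0; a multi-level covariate is
  retained when any of its dummy coefficients is significant, and forced
  covariates are retained with an explicit "forced" reason.
- Facility effects default to on. The screening model is the unstructured
  variant with county and facility effects, one candidate per fit.
- The county precision is named τ_c throughout (the source modelling code
  reused one name for two different precisions; the likelihood-level
  naming here keeps u/τ_h, f/τ_v, φ/τ_c distinct).

## Known limitations

- Single-site random-walk updates mix slowly for strongly correlated
  coefficient blocks (e.g. collinear dummies); no blocked β proposal is
  implemented.
- Only the intrinsic CAR is available — no proper-CAR autocorrelation
  parameter and no Leroux prior.
- The DIC plug-in at posterior means of random effects makes pD sensitive
  to the random-effect parameterisation, as is well known for focused DIC.
- The sampler is pure NumPy; it handles the study's dimensions in seconds
  per thousand iterations but is not tuned for problems orders of
  magnitude larger.
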