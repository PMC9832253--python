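# Methods

## The setting

Respondents living near, or visiting, a water body with macrophyte mass
development are shown five stylised images of increasing plant growth
(levels 1–5) and tick every level they would consider a nuisance; not
ticking a level is read as "not a nuisance".  They also distribute exactly
100 importance points over the recreational activities possible at their
site (swimming, boating, angling, appreciation of biodiversity, appreciation
of landscape, birdwatching), answer New Environmental Paradigm (NEP) Likert
items on a 1–5 agreement scale, and may answer "I don't know" to the
nuisance question as a whole.  The package analyses such data and, because
the original survey microdata are not deposited anywhere, ships a generator
that reproduces the study conditions synthetically.

## Synthetic survey generator

Each respondent is a resident with probability `resident_fraction` and
carries a latent intercept `b ~ N(0, σ²)`.  Under the default `bernoulli`
tick model the tick at level `L` is

    Bernoulli( expit( β₀ + b + β₁·L + β_res·1[resident] + Σ_a (points_a/100)·δ_a ) )

so the downstream random-intercept logistic model is exactly correctly
specified.  The alternative `monotone-threshold` mode compares one shared
uniform draw per respondent against the same (monotone in `L`)
probabilities, which makes every respondent's ticks monotone non-decreasing
in level while leaving the marginal tick probabilities unchanged — a
plausible behaviour for real respondents that the binary-per-level model
does not assume.  Both are offered because the field data's within-respondent
tick pattern is unknown; the default follows the per-level binary model the
analysis fits.

Calibration of the five default site profiles: retained sample sizes
(292/172/304/299/167), resident/visitor splits, NEP latent means and the
activity sets (no swimming at Lake Kemnade or Lake Grand-Lieu, birdwatching
only at Grand-Lieu) follow the published respondent profiles.  The slope is
β₁ = 1.5 per growth level at every site — steep enough that the nuisance
probability rises from ~0.1 to ~0.9 across two levels, matching the shape of
the published probability curves — and the intercept is set to
β₀ = −β₁·ED50 so that the *true* median nuisance levels at the visitor
baseline are 3.1, 3.2, 3.6, 4.1, 4.3 (Ludwigia, P. crassipes, J. bulbosus,
E. nuttallii, S. sagittifolia).  Resident effects are positive on the logit
scale (residents mind the plants more), largest at the J. bulbosus site;
that site also carries zero-centred activity contrasts (swimmers most
bothered, landscape watchers least).  The random-intercept SD defaults to
σ = 1, a moderate between-respondent heterogeneity.

NEP items are drawn as round(clip(N(latent_r, 0.8), 1, 5)) with a
respondent-level latent mean `latent_r ~ N(site mean, 0.45)`; with 15 items
this yields cohort score means within ~0.03 of the configured latent mean
and a between-respondent SD of ≈ 0.5, matching the published profile table.
Activity points are Dirichlet-multinomial conditioned to sum to exactly 100.

Contamination is integer-exact rather than merely expected: rates are
interpreted as fractions of the *total collected*, and the generator appends
`round(n·r/(1−r))` contaminated records (willingness-to-pay incomplete, or
protest records that add a uniform 1–50 point surplus to one activity) on
top of `n` clean ones.  Quality control therefore recovers exactly the
configured retained counts, and the five defaults reproduce the published
totals (403/297/338/477/265) and retention arithmetic deterministically.
"I don't know" is a whole-question state applied at rate `dont_know_rate`;
such respondents are retained but contribute no nuisance observations.

The Ludwigia site uses the lowest-level question variant
(`lowest_tick_only`): only the lowest bothersome level is recorded, and the
QC monotone fill expands it upwards, mirroring the mistranslation correction
applied to the original French survey.

**What the generator does not emulate.**  Item non-response patterns,
reverse-coded NEP items (items are generated pre-oriented; a reverse-code
index list is accepted for real data), respondent covariate correlations
(age/gender are decorative context), site-specific "don't know" differences
between residents and visitors, and any real relationship between NEP and
ticking (the generator's NEP is independent of perception, consistent with
the published null effect).  Passing tests therefore demonstrate the
*pipeline's* correctness under its assumed data-generating process, not the
field validity of the published estimates.

## Quality control

Rules are applied in order — (1) willingness-to-pay section incomplete,
(2) protest (activity points > 100), (3) fully blank — each removal counted
against the first rule it violates.  Retention percentages are rounded half
up; note that two cells of the published profile table (72.5% printed as
73%, 57.9% printed as 42%) are internally inconsistent with their own
counts, so the pipeline always reports computed percentages.  NEP scores are
the arithmetic mean of answered items; a record with no answered items keeps
a missing score but is not dropped.  The long analysis table has one row per
respondent × level, or per respondent × level × activity with weight
points/100 (zero-weight rows dropped).

## Binomial random-intercept model

The marginal likelihood integrates each respondent's intercept out of a
weighted Bernoulli likelihood.  We use the Laplace approximation: an inner
per-respondent Newton optimisation (strictly concave objective, vectorised
across respondents) finds the conditional mode `b̂_i` and curvature `H_i`,
and the outer quasi-Newton (L-BFGS-B with 3-point numerical gradients,
gtol 1e−8, relative-likelihood tolerance 1e−12, log σ bounded in [−7, 3])
maximises

    Σ_i [ ℓ_i(b̂_i) − b̂_i²/(2σ²) − log σ − ½ log H_i ]

over (β, log σ).  Starting values are the σ = 0 GLM coefficients (IRLS via
statsmodels) and log σ = 0.  The covariance of (β, log σ) is the inverse
numerical Hessian at the optimum, projected to the nearest symmetric PSD
matrix.  AIC counts the fixed effects plus one variance parameter.
Observation weights multiply the log-likelihood terms, so duplicating every
row at half weight reproduces the fit exactly.

Accuracy: the implementation agrees with lme4's `glmer` (an independent
Laplace implementation) to ~1e−5 on coefficients, σ and log-likelihood, and
with 30-node adaptive Gauss–Hermite quadrature to ≈ 0.003 log-likelihood
units *per respondent* at σ ≈ 1 with five binary observations each — the
total Laplace error grows linearly with the number of respondents, which is
why the quadrature comparison is made on cohorts of ≈ 100.

Design choices where the published description was open:

* **Link.** The analysis is described as binomial "log-link", but the logit
  is used throughout: it is the canonical binomial link, the default of the
  lme4/dose.p toolchain that produced the published numbers, and keeps
  probabilities defined at all levels.
* **Conditional, not population-averaged.** Predictions and median nuisance
  levels are conditional on b = 0 (the median respondent), which is what
  `dose.p` applied to the fixed effects computes.
* **Term tests.** Wald chi-square per term, `W = β_t' V_t^{-1} β_t` with df
  = number of coefficients in the term; the published results table reports
  Chisq/Df/P without naming the statistic.
* **AIC rule.** The simplest candidate within 2 AIC units (inclusive) of the
  minimum is selected, candidates ordered simplest-first.
* **Per-site fitting.** Growth levels only correspond qualitatively across
  species, so models are fitted separately per site; the activity analysis
  weights each observation by the respondent's points for that activity
  divided by 100.

The median nuisance level generalises −β₀/β₁: with design row `x₀` at growth
level 0 under the chosen covariate context and per-level contrast `s`, the
level solves `x₀'β + L·s'β = 0`, and its delta-method variance is `g'Vg`
with `g = −x₀/(s'β) + (x₀'β)·s/(s'β)²`.  This handles level × type
interactions transparently.

## Decision network

Discrete nodes with CPTs; structure and tables live in editable files (JSON
structure + one TSV per node, row sums validated to 1e−9 on load).  The
engine never hard-codes probabilities: the shipped example network's tables
are synthetic stand-ins (labelled as such), and the Perception CPT can be
exported from the fitted models via `perception_cpt_from_fits`, which writes
P(nuisance | activity, respondent type, species, growth level) from the
conditional predictions.  Activities not offered at a species' site are an
error by default; an explicit `absent_activity="average"` option substitutes
the site's mean over its own activities.

Inference is exact variable elimination with a min-fill ordering
(deterministic name tie-break), validated against full joint enumeration
(≤ 10⁶ joint states) to 1e−10 on random networks, including evidence on
descendants of the query.  Evidence is hard only; soft likelihood evidence
is out of scope because the published scenarios set nodes to 100%.  CPT
learning uses pseudocount smoothing, `(count + α)/(total + α·k)` with α = 1
by default (uniform prior, NETICA-style case learning); α = 0 gives maximum
likelihood and raises on unseen parent combinations.  MAP decisions break
ties by declared state order and flag them.

## Simulation study sizes

Chosen to match the field study's scale: recovery runs use cohorts of 500
respondents (200 replicates; median absolute ED50 error ≈ 0.04–0.05, well
inside the published ±0.1 SDs) plus one 1000-respondent run; the Wald-test
type-I study uses 500 null cohorts of 300 respondents at σ = 1 (observed
rejection rate ≈ 0.045 at α = 0.05); the inference equivalence check uses
100 random networks of up to 8 nodes × 3 states.

## Known limitations

* The Ludwigia profile generates monotone-threshold ticks, whose
  within-respondent dependence is stronger than a Gaussian random intercept
  can represent; the fitted median nuisance level there carries a small
  upward bias (~ +0.15 levels) and extra variance relative to the other
  sites.  This is a property of the question variant, not a fitting defect.
* No crossed or nested random effects, no random slopes — one respondent
  intercept only, as in the published analysis.
* Wald tests rely on the asymptotic normality of the Laplace estimates;
  likelihood-ratio comparisons are available implicitly through the AIC
  ladder but no LRT p-values are exposed.
* The ecological consequence tables shipped with the example network are
  illustrative; real deployments must replace them with locally elicited
  CPTs, exactly as the decision-support design intends.
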