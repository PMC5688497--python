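# Methods

## Scope and units of analysis

`birthrisk` is an ecologic analysis: its units are surveys, not women.
Each survey contributes one observation per risk category — the percent
of births in the 36 months before the survey falling in that category —
together with the survey's modern contraceptive prevalence (mCPR, women
15–49 in union) and method-mix shares among modern users. Associations
estimated at this level need not hold for individual women.

## Classification rules

All category bounds are half-open `[lo, hi)`: an interval of exactly 18
months is `18-23mo`, exactly 24 is `24-35mo`, exactly 36 is `36+mo`; a
mother of completed age 35 is `35+`. This convention makes each
dimension's categories disjoint and exhaustive, which the compositional
renormalization downstream requires. First births carry no preceding
interval and are excluded from the spacing denominator, so spacing
percentages are shares of second-and-later births. Dates use the DHS
century-month code (integer months since January 1900) to avoid calendar
arithmetic. Optional per-woman sampling weights propagate through every
rate (births inherit their mother's weight); with equal weights the
unweighted results are reproduced exactly. The default is unweighted.

mCPR's denominator is women 15–49 currently in union; "modern" is every
enumerated method except `none` and `traditional`. Permanent =
female/male sterilization; LARC = IUD/implant; short-term = the
remaining modern methods. The method-mix denominators are modern users,
so `%permanent + %LARC ≤ 100` by construction.

## Period TFR

TFR = 5 × Σ over the seven 5-year age groups of (window births to
mothers in the group) / (woman-years of exposure in the group). Because
women's ages are known only in completed years at the survey, exposure
is reconstructed in 12-month blocks: the year before the survey at
`age`, the one before at `age − 1`, and so on. True birthdays fall
uniformly within the year, so this slicing misassigns a few months of
exposure between adjacent groups at group boundaries and around entry to
the reproductive span; in simulation this biases the period TFR downward
by roughly 2–5% relative. The estimator is kept as stated because the
input schema deliberately carries no exact birth dates for women; tests
of TFR recovery use a tolerance that covers Monte-Carlo error plus this
known discretization bias.

## The log-linear models

The response is the natural log of the category **percent** (0–100
scale); using proportions would only shift the intercept, and the
renormalization of predictions makes the choice invisible. A survey
observing zero births in a category takes the continuity substitute
`100 × 0.5 / n_births_window` before logging (half a birth out of the
window total); surveys with no window births are dropped for that
dimension. Each (dimension, category, variant) is fitted independently —
no cross-category covariance is modelled; coherence across categories is
restored by renormalizing predictions.

Models m1/m2 are ordinary least squares with σ̂² = RSS/(n−p), classical
covariance, and two-sided t p-values on n−p degrees of freedom. They do
not adjust standard errors for repeated surveys within a country; that
clustering is exactly what m3 absorbs.

Model m3 adds a country random intercept and is estimated by REML. The
restricted likelihood is profiled down to the variance ratio
λ = τ²/σ²: within a country of nᵢ surveys the marginal covariance is
σ²(I + λJ), whose inverse and determinant are closed-form, so each
criterion evaluation costs O(countries) from per-country sufficient
statistics. λ is maximised by bounded scalar search over log λ on
[1e−8, 1e3] (xatol 1e−10), with an exact λ = 0 candidate evaluated so
that data without country-level variation land precisely on the τ̂² = 0
boundary, where the GLS fit coincides with OLS. With true τ² = 0 the
estimate sits on that boundary about half the time — standard behaviour
for a variance component under its null. REML (not ML) is used because
with four fixed effects the ML variance estimates would be noticeably
biased at ~200 surveys.

Wald standard errors come from σ̂²(X'V⁻¹X)⁻¹. p-values use a t reference
with n − p − (countries − 1) degrees of freedom (floored at 1) for m3 —
a conservative between/within compromise; no authoritative convention
exists for this design and the choice only matters in small panels.
When fewer than two countries, or no country with two surveys, is
available, τ² is unidentifiable: the fit warns and fixes τ² = 0.

Country effects are empirical-Bayes BLUPs,
`b̂ᵢ = nᵢτ̂²/(nᵢτ̂² + σ̂²) · r̄ᵢ`, which for a random-intercept model is
the exact conditional mean given the fitted variance components. The
shrinkage factor is monotone in nᵢ and bounds |b̂ᵢ| by |r̄ᵢ|.

## Predictions and scenarios

Predicted category percents `exp(β̂₀ + β̂₁·mCPR + β̂₂·%perm + β̂₃·%LARC
+ b̂ᵢ)` are rescaled within each dimension to sum to 100. This makes the
predictions invariant to a constant added to every intercept of a
dimension (compositional identifiability) and guarantees nonnegative
shares. For countries without an estimated effect, the fallback is
`zero` (default) or `regional_average` (mean b̂ over the country's
region, from a country→region table); `country` insists on an observed
country and errors otherwise.

A scenario adds Δ percentage points of mCPR (default 10 — "+10%" is
read as +10 points, forced by the printed 33→43 and 67→77 transitions)
entirely to one method class. Existing users do not switch methods: in
user-shares of women, `u_class' = u_class + Δ` for the target class
only, and the mix shares are re-expressed against the new prevalence.
This is the minimal-change reading of "increasing mCPR with X methods";
reallocation of existing users is deliberately out of scope. Scenario
covariates must keep mCPR ≤ 100. TFR is held out of the scenario
machinery entirely; only the risk distribution is projected.

## Synthetic data

The panel generator draws the model exactly: covariates (mCPR uniform on
[5, 75]; method-mix from a Dirichlet(1.5, 2, 6.5), i.e. roughly 15%
permanent / 20% LARC / 65% short-term on average), country effects
N(0, τ²) shared within country, survey residuals N(0, σ²), and category
percent `exp(x'β + b + ε)`. Defaults mirror the study scale: 71
countries, 207 surveys (the first 65 countries get three surveys, the
rest two — a deterministic allocation), τ² = 0.04, σ² = 0.01. Default
slopes carry the signs and per-unit magnitudes of the hierarchical fit
reported for the real survey library (e.g. −0.0014 per percentage point
of mCPR for parity 5+), with method-mix slopes chosen so that a
permanent-heavy mix associates with relatively more high-parity births
and a short-term-heavy mix with longer intervals; intercepts anchor each
category near its cross-survey average at reference covariates
(mCPR 30, %perm 15, %LARC 20). Emitted percentages follow the model
exactly and therefore do **not** sum to 100 within a dimension unless
`renormalize=True` is set, which rescales them and thereby slightly
breaks the generating mean structure — the same tension real
compositional data would have.

The birth-history generator draws each woman's births as independent
monthly Bernoulli events with hazard `asfr[age group]/12` from her 15th
birthday to the survey month (birthday offset uniform within the year).
This makes two oracles exact: the period TFR is `5 × Σ asfr` in closed
form, and the expected distribution of window births over categories is
computable by dynamic programming over months
(`implied_category_distribution`): with independent monthly events, the
probability a birth in month *s* is first, or has preceding interval
*d*, factorises into hazards and survival products, and the birth-order
distribution is the Poisson-binomial count of earlier months. What the
generator deliberately omits: postpartum infecundability (so very short
intervals are over-represented relative to real populations),
union/contraception feedback on fertility (individual-level method use
is drawn independently of the birth process; the ecologic association
lives in the panel generator, not the microdata), twins (at most one
birth per month), and survey design effects (strata/clusters). Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not realism of the microdata.

`interval_months_override` replaces the hazard process with
deterministic renewal at a fixed interval — useful to force all
non-first births into a single spacing category when testing the
classifier.

All randomness descends from one integer seed through
`numpy.random.SeedSequence`, with an independent spawned stream per
survey, so outputs are byte-identical across runs and platforms for a
given seed.

## Numerical choices and degenerate inputs

- Rank-deficient designs are rejected with the collinear columns named.
- Zero modern users make the method-mix undefined (error), zero eligible
  women make mCPR undefined (error); empty surveys are rejected with the
  survey id in the message.
- Window filtering keeps births with `0 ≤ survey_cmc − birth_cmc <
  window`; the implied-distribution oracle uses the same convention.
- CSV serialization carries 6 decimal places; aggregate compositions are
  validated on read with tolerance 1e−3 to absorb that rounding, while
  in-memory pipelines enforce 1e−6.
- REML relabelling/row-order invariance holds to ~1e−6 (summation order
  perturbs the profiled criterion within the optimizer tolerance), not
  to machine precision.

## Problem sizes used in checks

Parameter-recovery checks run 200 replicated panels at the study scale
(207 surveys, 71 countries); classification agreement uses 10,000
randomized births including every boundary value; compositional
contracts use 1,000 random fit/covariate draws; TFR recovery averages
four surveys of 5,000 women. These sizes give Monte-Carlo standard
errors comfortably below the tolerances asserted.

## Known limitations

- Risk dimensions are modelled marginally; joint risk (e.g. young mother
  *and* short interval) is not represented.
- No uncertainty intervals accompany scenario predictions; they are
  point projections of the fitted mean structure.
- The mortality consequences of a shifted risk distribution are out of
  scope; the output is the distribution itself.
- Real survey microdata parsing (recode files), imputation of missing
  dates, and multiple-birth handling are out of scope.
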