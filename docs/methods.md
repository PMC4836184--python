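# Methods

## The problem being modelled

Health surveillance estimates (smoking, obesity, diabetes, asthma,
arthritis, mental-health conditions) are often produced by telephone
surveys whose frames are landline-based: random digit dialling (RDD) of
landline numbers, or directory-listed (EWP) numbers. A frame that cannot
reach part of the population biases prevalence estimates whenever the
unreachable part differs on the outcome. The package quantifies that
coverage bias with the relative coverage bias statistic

    RCB = (N_nc / N) · (p_c − p_nc) / P

with `f = N_nc/N` the non-covered population share, `p_c` / `p_nc` the
prevalence among covered / non-covered people, and `P` the overall
prevalence. RCB is dimensionless and scale-invariant as long as the three
prevalences share a scale.

Because the original face-to-face survey microdata this style of analysis
was built on are not publicly deposited, the package is organised around a
synthetic-data generator that reproduces the *published statistical
structure* — telephone-status mixtures by year, listing rates by device,
demographic gradients in mobile-only status, health-indicator gradients by
telephone status — so that every downstream stage (sampling, weighting,
estimation, bias) can be exercised and validated end-to-end.

## Synthetic population model

Persons aged 15+ are generated inside households; household size (eligible
members, 1–4) follows a configurable categorical distribution (default
0.27/0.40/0.17/0.16, a plausible adult-household-size profile). Households
are grouped into contiguous area clusters (default ~60 households per
cluster, echoing census collector districts); each cluster is assigned
metro/regional status so that area is a genuinely cluster-level variable.

**Telephone status** is a household attribute, drawn from a multinomial
logit over {mobile_only, landline_only, both, neither}. Baseline utilities
are the log of the configured mixture; the mobile-only utility is shifted
by additive log-odds offsets keyed to the household reference person's
demographics (age band, sex, area, optional covariates). With all offsets
zero the realized mixture converges to the configured one exactly; with
gradients on, the mixture parameter is the reference-person baseline and
the realized marginal sits somewhat below it (Jensen effects plus non-zero
mean offsets), which is why calibration checks run with gradients off.
Offsets rather than a joint model were chosen because the published
evidence is category-wise proportions, not a fitted joint distribution.

**Directory listing** is Bernoulli per household, conditional on owning the
device: P(landline listed) defaults to 0.627 in 2013 (declining backwards
to 0.770 in 2006, back-solved so the simulated directory-listed population
share tracks the published 73.8 % → 60.4 % → 49.6 % decline), P(mobile
listed) = 0.046 throughout.

**Health indicators** are person-level logistic draws: logit(baseline) +
telephone-status offset + optional demographic offsets. The default 2013
health spec puts baselines near published all-household prevalences and
gives current smoking a +0.65 log-odds mobile-only offset (mobile-only
smoking ≈ 27 % vs ≈ 16 % elsewhere, overall ≈ 19 %) and mental-health
conditions +0.45; obesity, arthritis, diabetes, asthma have small or zero
telephone gradients. This is the mechanism that produces negative RCB for
smoking and mental health and near-zero RCB for the rest.

**Year scenarios.** `scenario_for_year` encodes mixtures for 2006 and
2010–2013 derived from the published ownership series (mobile-only 5.2 /
17.1 / 21.7 / 23.9 / 27.6 %; total mobile ownership interpolated 89.7 →
96.3 %; landline ownership 94.4 → 71.7 %; the `neither` remainder 0.4–0.7 %).

What the generator deliberately does **not** emulate: real spatial
autocorrelation beyond cluster-level area, intra-household demographic
dependence (members are drawn i.i.d.), longitudinal household panels,
item nonresponse in indicators, and measurement error in self-report.
Passing tests therefore demonstrate correctness of the estimators and the
bias machinery under a known truth, not that any particular real survey is
unbiased.

## Survey design

Equal-probability simple random sampling of `n_clusters` clusters without
replacement (the real design's cluster selection probabilities are not
published; equal probability is assumed and flagged here). Within a
cluster, a systematic run of 10 households: uniform random start, fixed
skip `floor(H/10)` with wrap-around, which makes every household's
inclusion probability exactly `10/H` and keeps the 10 selections distinct.
One respondent per household, uniform among eligible members — the
last-birthday rule's statistical content — with selection probability
`1/household_size_eligible` recorded. Nonresponse is household-level
Bernoulli at the configured response rate (default 0.593, the published
median), optionally skewed by covariate log-odds offsets (MAR);
non-respondents are not replaced. The 10 households are treated as the
*issued* count, so expected respondents ≈ clusters × 10 × response rate
(300 clusters ≈ 1780 respondents; scenario configs scale `n_clusters` when
a different yield is wanted).

## Weighting

Design weights multiply the inverse stage probabilities (cluster ×
household × person) and are normalised to sum to the respondent count;
prevalence estimates are invariant to that normalisation, and
`normalize=False` exposes the Horvitz–Thompson scale for total estimation.
Post-stratification is full-cell age(5-year) × sex × area: within each
cell, weights scale by benchmark count / weighted sample count. Cells with
positive benchmark but zero sample weight are handled by collapsing
adjacent age bands within the sex × area stratum (standard practice; the
alternative raking is provided as `rake`, not the default, because the
design names one joint benchmark). Post-stratified weights sum to the
benchmark total (tolerance 1e-6 relative), are idempotent under repeated
post-stratification, and invariant to input-weight scale. Re-weighting a
frame subsample is post-stratification started from the original relative
design weights of the retained respondents.

## Estimation

Prevalence is the weighted ratio estimator. Variance by Taylor
linearization with clusters as with-replacement PSUs in a single stratum
(no stratification detail is assumed): for scores
`z_i = w_i(y_i − p̂)/Σw`, `V = m/(m−1) Σ_c Z_c²` over the m cluster totals.
With one respondent per PSU and equal weights this reduces exactly to the
SRS binomial variance with the n/(n−1) factor. Confidence intervals
default to the logit-transformed Wald interval with a t(m−1) reference
(guaranteed inside (0,100); plain Wald available, and used automatically
at p̂ ∈ {0,1}).

The chi-square test reports the design-based Pearson X² computed on
weighted cell proportions with unweighted n — identical to the classical
Pearson statistic in the SRS limit — and corrects the reference
distribution by the second-order Rao–Scott method: generalized design
effects are the eigenvalues of `V₀⁻¹V̂` on the (R−1)(C−1)-dimensional
space of independence contrasts (V̂ linearized, V₀ the SRS multinomial
covariance), and `F = X²/(d·δ̄)` is referred to
F(d/(1+a²), ν·d/(1+a²)) with ν = m−1 and a² the squared CV of the
eigenvalues. A pseudo-inverse guards degenerate tables (perfect
association makes the contrast null covariance singular; the correction
then falls back to unit design effect, leaving the extreme p-value
extreme). Under independence of two cluster-correlated variables the
empirical size is ≈ 0.05 where the uncorrected test rejects at ≈ 0.09
(see the acceptance suite).

Records from households with no telephone service (or undetermined
status) are excluded from telephone-status tabulations, mirroring the
analysis convention; they remain in the population and the face-to-face
sample, and they count as non-covered in *both* frames, since no
telephone method can reach them.

`relative_change` is ((new − old)/old)·100 with the reporting convention
of whole percent above magnitude 100 and one decimal below (430.8 → 431).

## Frames and RCB modes

`rdd_landline` covers telephone_status ∈ {landline_only, both};
`directory_listed` covers listed_landline ∨ listed_mobile. Coverage
fractions default to weighted shares (unweighted available).

Two RCB computation modes are provided deliberately. *Consistent* mode
(default) uses one weight vector for f, p_c, p_nc and P, so the
decomposition P = (1−f)p_c + f·p_nc holds and RCB ≡ (p_c − P)/P to
machine precision — an identity the test suite verifies and that makes
simulation studies interpretable. *Re-weighted* mode reproduces the
published workflow, in which the frame estimate is first re-calibrated to
population benchmarks: published frame-comparison tables mix re-weighted
frame estimates with the formula, so their printed RCBs do not satisfy
the consistent-mode identity against their printed prevalences. Which
weight vector produced the published non-covered prevalences is not
recoverable; re-weighted mode uses the full-sample post-stratified
weights for f, p_nc and P. The two modes agree closely when
post-stratification moves weights little.

## Numerical and design choices

* Degrees of freedom m−1 (PSUs minus one) for CI t references and the
  Rao–Scott F denominator.
* RCB reported to three decimals; prevalences and percentage-point
  differences to one decimal; full precision kept internally.
* Scale validation in `rcb`: inputs are auto-classified as percent if any
  exceeds 1; explicitly declaring `scale="proportion"` with a value > 1
  (or percent with > 100) raises, which catches mixed-scale calls.
* Seeds: one suite seed spawns per-stage child seeds via
  `numpy.random.SeedSequence` (recorded in the run manifest), so any
  stage can be reproduced independently.
* Degenerate inputs: empty mixture components get −inf utility (a
  degenerate mixture like "all both" is honoured exactly); indicators
  with baseline 0 or 1 are constant without logistic sampling; the final
  generated household is trimmed so the person count is exact.

## Simulation sizes

Chosen as the package's standard validation settings: simulator
calibration at 200 000 persons (≈ 90 000 households; 3 Monte-Carlo-SE
bands); RCB parameter recovery on a 120 000-person population with 500
replicate surveys of 300 clusters × 10 households at response 0.593
(≈ 1780 respondents each); CI coverage over 2000 replicate 100-cluster
surveys of a fixed 60 000-person population; chi-square size over 2000
replicates of 50 clusters × 30. The acceptance script uses the same
scales and finishes in well under a minute.

## Known limitations

* Cluster selection is equal-probability; size-proportional selection of
  real area frames is not modelled (design weights would absorb it via
  `prob_cluster` if supplied).
* The with-replacement PSU variance ignores finite-population corrections,
  slightly over-stating variance when many clusters are sampled.
* Household members share telephone status by construction; real
  households occasionally mix personal mobiles with differing listings.
* The multinomial-logit gradient structure shifts only the mobile-only
  utility; gradients for landline-only vs both are not separately
  configurable.
* Re-weighted-mode RCB depends on which weight vector is used for the
  non-covered prevalence; this is a genuine ambiguity of the published
  workflow, made explicit rather than resolved.
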