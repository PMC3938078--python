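# Methods

## Problem and model

`vaxcov` analyses childhood immunization coverage surveys of the kind run
under the Expanded Program on Immunization (EPI): children aged 12–59
months are sampled by a two-stage cluster design, their written
immunization histories are transcribed, and each dose and vaccine series is
classified by completeness and timeliness.

### Timeliness classification

A schedule assigns each dose a closed acceptable window in days: dose 1 of
a series carries an *age* window (day of birth = day 0, age computed as the
calendar-day difference between vaccination date and birth date); every
later dose carries an *interval* window measured from the immediately
preceding dose of the same antigen (dose *k* against dose *k*−1). For a
received dose with measurement *x* (age or gap) and window [*lo*, *hi*]:

* *x* < *lo* → **invalid** (age-invalid / interval-invalid): given too
  early to count as a valid immunization;
* *lo* ≤ *x* ≤ *hi* → **appropriate**;
* *x* > *hi* → **delayed**.

The bundled default schedule is the Chinese EPI primary series in force in
Guangdong in 2011 (1 BCG, 3 HepB, 3 OPV, 3 DPT, 1 MCV — the "1:3:3:3:1"
composite): BCG1 and HepB1 at 0–1 d of age, HepB2 28–61 d and HepB3
59–183 d after the previous HepB dose, OPV1 at 59–91 d, DPT1 at 89–122 d,
MCV1 at 242–274 d of age, and 28–61 d for the later OPV and DPT doses.
Whether HepB3's interval is anchored at HepB2 or elsewhere is not fixed by
the printed schedule; the dose-(k−1) convention is used uniformly and any
other anchoring can be expressed through a custom schedule file.

A series is **UTD** (up-to-date) when every required dose has a recorded
date, regardless of timing. Among UTD series, timeliness is
INVALID if any dose is invalid (invalid takes precedence over delay, since
an invalid dose is not a valid immunization), AGE_APPROPRIATE if dose 1 is
age-appropriate and every later dose interval-appropriate, and DELAYED
otherwise; non-UTD series are INCOMPLETE. The composite series is UTD iff
all five series are, with the same precedence rules lifted to series level.

Degenerate inputs: a dated dose whose predecessor is unreceived has an
undefined interval and is classified interval-invalid (and logged as a
data-quality anomaly); out-of-order dates produce a negative gap, which
falls below every interval minimum and is likewise interval-invalid.

### Record reconciliation

Two written sources may exist per child: the caregiver-held certificate and
the clinic-held card. The certificate is authoritative whenever present;
the card is used only in its absence; a child with neither document is
regarded as unvaccinated. A dose whose date is missing on the chosen
document is treated as unreceived. The document tally reports certificate/
card availability and discordance between paired documents, split into
pairs where one document records more doses and pairs with equal doses but
differing dates.

### Coverage tabulation

Coverage of a dose is the share of *all* surveyed children (including the
recordless) with a dated record of it, so per table row

    coverage = invalid + age-appropriate + delayed

holds exactly at full precision; percentages are rounded half-up to one
decimal only on export. Per-dose coverage is computed independently per
dose — monotone dropout is not assumed, a child may have dose 3 recorded
without dose 2.

### Survey design

The required sample size is the closed form ceil(deff·z²·p(1−p)/d²) — a
formula approximation to the WHO manual's lookup table; at the default
parameters (p = 0.75, d = 0.03, deff = 2, z = 1.96) it gives 1601 children,
spread as ceil over clusters (23 per cluster × 70 clusters = 1610).
Cluster selection is systematic PPS: cumulate the measures of size, take
sampling interval total/n, draw a uniform start in [0, interval), and
select the cluster containing each equally spaced point; clusters larger
than the interval are certainty selections returned with multiplicity.
Within a village the interview walk starts at a uniformly drawn household,
proceeds cyclically "to the right" through the fixed household ordering,
takes at most one eligible child per household — the youngest, when several
are eligible — and stops at the quota or after one full pass (shortfall
flagged). All randomness flows from one explicit `numpy` generator; there
is no global random state.

### Determinants model

Knowledge is a 0–34 count of correct questionnaire items, attitude a 0–13
graded-points total; the questionnaire item lists are configuration inputs,
not fixed by the package. Scores and household quantities are binned
deterministically (knowledge ≤9 / 10–19 / 20–34 — a printed "<9" bin read
as ≤9 to close the gap before 10; attitude 0–7 / 8–13; income <3000 /
3000–5000 / >5000 yuan per person-year with both boundary values in the
middle bin; child age 12–35 / 36–59 months). All covariates enter one
multivariable logistic regression of composite-series UTD status
simultaneously, dummy-coded against fixed reference levels (worker, mother,
male caregiver, age <25, high school and above, knowledge <9, attitude 0–7,
income <3000, child 36–59 months, male child, Hukou outside Guangdong,
renting house, county-level hospital birth). Odds ratios are
exp(coefficient) with Wald 95% intervals and p-values — profile-likelihood
intervals are not used, matching the standard output of the era's survey
software. Reference levels are reported as exactly 1.00 without an
interval. Degenerate fits (a single outcome class, an unobserved level,
complete or quasi-complete separation) raise a diagnostic error naming the
covariate rather than returning unstable estimates.

## Synthetic-data generator

No field microdata are available, so the generator emulates the surveyed
population with every default anchored to the published survey margins:

* covariate marginals = the published category counts divided by 1530;
* per-dose timing mixtures (invalid, appropriate, delayed) = the published
  per-dose decomposition conditioned on receipt;
* baseline UTD probability 0.649; true odds ratios default to 1 and can be
  configured per covariate level (UTD is drawn from
  logit p = logit(baseline) + Σ log OR over the child's levels);
* record model: no document 49/1530; the documented split approximates the
  published certificate/card counts; discordance 18/1437 among both-present
  pairs, realised as either dropping one card dose or shifting one card
  date by ±1–14 days;
* survey ages: the child-age band is drawn from its marginal and the exact
  age is uniform within the band (the two published age-band counts are far
  from uniform over 12–59 months, so band-level fidelity is preferred).

Dates are built from the drawn categories: appropriate draws are uniform
integers inside the window; invalid draws are uniform in the 30 days below
the window minimum (a mixture that demands invalid doses for a window
starting at day 0 is rejected as infeasible); delays add a geometric tail
with mean 30 days past the window maximum — the survey publishes no delay
distribution, so the magnitude distribution is a documented, pluggable
choice. For non-UTD children each series is truncated by a per-dose
dropout chain (default stop probability 0.5 before first doses, 0.3 before
later ones, reflecting that most non-UTD children lack entire series); a
non-UTD child whose chain happens to drop nothing has the final dose of one
randomly chosen series removed so the ground truth stays consistent.

The two-stage survey simulator draws village sizes from a lognormal
(default median 60 eligible children, σ = 0.6, 429 villages), selects
clusters by systematic PPS, generates populations only for selected
villages, groups children into households (10% of households hold a second
eligible child), and runs the household walk to the per-cluster quota.

### What the generator does and does not emulate

Covariates are drawn independently across variables (only marginals are
published; no copula is attempted) and per-dose timing categories are drawn
independently across doses. The second point matters when reading synthetic
composite rows: with ~1–2% invalid probability per dose independently, the
composite invalid share is ≈1 − Π(1 − pᵢ) ≈ 10%, and the composite
age-appropriate share is the product of per-dose appropriate shares —
both far from the published composite row, which reflects strong within-
child correlation of timing behaviour. Passing round-trip tests therefore
demonstrates that classification and estimation invert the generative
process correctly, not that the synthetic joint distribution matches the
field population. Dose dates are not censored at the survey date by
default (`censor_at_survey` enables it): censoring would distort the
configured timing mixtures, and the uncensored idealisation keeps
generator→classifier round trips exact. Household geography, migration
dynamics over time and free-text questionnaire content are out of scope.

## Numerical choices and problem sizes

Percentages are rounded half-up (ties away from zero) to one decimal for
display; all identities are asserted pre-rounding. p-values are displayed
to three decimals with values below 0.0005 rendered "0.000". The test
suite verifies the classifier against a brute-force window-lookup oracle
over every age 0–600 days and every gap 0–400 days for all 11 dose rules;
generator→classifier round trips use cohorts of 4,000–50,000 children
(3-standard-error Monte-Carlo bands); odds-ratio recovery uses 200
replicates of n = 20,000 through the generator's covariate/outcome stage;
PPS inclusion probabilities use 100,000 seeded replicates on a 10-cluster
frame. These sizes give Monte-Carlo error comfortably below the asserted
bands while keeping the default suite fast.

## Known limitations

* The published survey's odds ratios are not reproducible without its
  microdata; the determinants stage is validated by parameter recovery on
  synthetic cohorts instead.
* Cluster-robust variance estimation is deliberately absent: the model is a
  plain maximum-likelihood logistic regression, as in the analysis it
  mirrors; design-based standard errors would require the cluster structure
  to enter the model.
* The wide CSV dialect cannot distinguish "document lists no entry for this
  dose" from "entry present with a missing date"; both read back as a
  missing-date event, which is also how both are analysed.
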