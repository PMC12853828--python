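# Methods

This note documents the models and procedures implemented in `probpanel`,
the defaults they ship with, and what the synthetic study does and does not
establish about real recruitment fieldwork.

## 1. Synthetic register and ground-truth model

### Frame

The frame generator builds a miniature national register: municipalities
nested in districts (the first six digits of the 8-digit municipality code)
and 16 federal states, each municipality carrying a BIK size/commuter class
(10 official classes, collapsed deterministically to 4) and an age-structured
16+ population over the eight address-draw age groups (16–29, 30–39, 40–49,
50–59, 60–64, 65–79, 80–84, 85+).

* State 16+ totals are fixed by controlled rounding of the official state
  shares, so state margins hold exactly up to integer rounding.
* Age-group totals are multinomial draws from the configured age shares; the
  65–79 draw group samples ages 40/60 between 65–69 and 70–79 so the six
  analysis age groups (…, 60–69, 70+) reproduce the official margins.
* Municipality sizes are log-normal within BIK class. The default scale is
  ~1/50 of the real register: 200 municipalities, 350,000 persons 16+. At
  this scale the municipality-count mixture across collapsed BIK classes is
  30/34/24/12% — fewer, larger small-class municipalities than reality — so
  that a 600-address draw remains feasible after merging one or two
  neighbours. BIK-10 subclasses are assigned by size tercile within class,
  which keeps district neighbours mergeable under the same-district,
  same-class rule.

### Persons

Each register row carries official demographics (sex at birth, birth year
and month, citizenship), Casmin education, household type, an address status
(valid / business / moved / deceased / duplicate-of), and the health items of
the recruitment questionnaire. Demographic margins default to the official
benchmarks (51.0% female, 85.0% German citizenship, 24.9% single-person
households, education 33.6/46.3/20.1). Health items are drawn from simple
marginal distributions — only the chronic condition depends on age — because
no generative model for them is available; their only contract is matching
the questionnaire's item domains and giving the registration model realistic
covariate variation. Birth month is missing in 2% of rows (exercising the
12-month matching tolerance); 0.5% of rows duplicate another address; 8.1%
carry a business/moved/deceased defect, matching the removal fraction of the
real gross-sample cleaning.

### Ground truth

The `GroundTruthModel` holds two logistic coefficient sets applied through
the inverse-logit link:

* **participation** (recruitment-survey response) on the gross-frame
  covariates: seven age groups, sex, a sex×70+ interaction, region, BIK-4;
* **consent** (panel consent given participation) on the extended covariate
  set: the same demographics plus education, citizenship, household type and
  the health items.

`default_truth()` derives these coefficients in closed form from age-by-sex
anchor tables that encode the documented participation gradients of German
register-based mixed-mode recruitment: women above men, the youngest group
(16–19) strongest and 20–29 weakest, a reversal of the sex gap above age 70
(carried entirely by the single sex×70+ interaction — the one interaction
the evidence demands), an education gradient and a strong citizenship
barrier at registration, higher registration under chronic conditions but
lower under poor self-rated health. Small region and BIK effects (Northwest
highest; the 20–50k size class highest, the largest cities lowest) are added
on top, and the intercepts are centred against the reference covariate
margins so the anchors hold *marginally*. Consent anchors are the
validated-per-complete ratios inflated by the expected double-opt-in loss,
since only online registrations require e-mail confirmation (confirmation
probability 0.9483).

Because the female effect below 70 is a single common log-odds gap, female
cells can deviate from their anchors by up to ~6 pp in single age groups
(most visibly at 60–69); male cells and the interaction-carrying 70+ female
cell are matched to <1 pp. Headline rates, which average over cells, are
unaffected at the percent level.

## 2. Sampling design

* **Controlled rounding** is largest-remainder apportionment with a
  deterministic lower-index tie break — for one-dimensional totals this
  satisfies every controlled-rounding constraint (each value rounds to floor
  or ceiling; totals preserved). Fractional parts are quantised to 9
  decimals so equal printed decimals tie exactly despite binary floats.
* **State allocation** applies the guaranteed minimum iteratively: fix every
  state whose proportional target falls below the floor, rescale the rest,
  repeat. A single pass is not enough — rescaling can push a previously safe
  state under the floor, and with 359 points and a floor of 14 exactly that
  happens once (nine states end at the floor, not eight).
* **Stratification level.** The scaled pipeline stratifies states by the
  collapsed 4-class BIK level. With 72 sample points, the full 10-class
  subdivision leaves stratum targets around 0.04 of a point, which
  deterministic rounding sends to zero — small-municipality strata would
  never be selected. At full scale (359 points, every state ≥ 14) the
  10-class subdivision is meaningful; it remains available via
  `stratify_by="bik_class_10"`.
* **PSU selection** is systematic PPS within stratum. A municipality hit
  *m* times becomes one sample point with *m*×600 addresses (how multiple
  sample points in one big city are realised). First-stage inclusion
  probabilities are approximated by min(1, k·size/stratum size); joint
  probabilities for design-based variance estimation are out of scope (the
  weighting methodology is a separate exercise). The Horvitz–Thompson
  property — design-weighted invited totals estimate the frame population
  unbiasedly — is verified in the tests on a configuration without
  certainties or merging, where the probabilities are exact.
* **Synthetic sample points** merge a municipality whose address need
  exceeds 70% of its 16+ population with its nearest neighbours — hard
  filters: same district key and same BIK-10 class; distance
  |log(pop ratio)| (the named features, with the scalar metric made
  explicit). Exhaustion of candidates flags the point but never aborts.
* **Address draw.** Age-group counts ∝ share/expected-recruitment-rate,
  controlled-rounded, capped at group population with proportional
  re-apportionment of the shortfall. Default expected recruitment rates per
  draw age group range from 12% (85+) to 21% (40–49), chosen so the invited
  age mix over-represents older groups the way a recruitment-rate-compensating
  draw does. Berlin and Schleswig-Holstein carry an oversampling factor of
  1.5 (900 drawn / 600 invited per point).
* **Cleaning** removes business/moved/deceased addresses, collapses
  duplicate chains onto the canonical person, and assigns mailing batches
  10/50/40% by seeded draw.

## 3. Fieldwork simulation

The latent participation propensity *P* is an *overall* response
probability; the field simulation converts it to a constant per-contact
hazard q = 1 − (1−P)^(1/3) over the three contacts (invitation, reminder at
day 14, reminder at day 28). This keeps the selection models and the
calibration targets on the natural scale (a logistic model of overall
participation) while giving the event-level behaviour the design implies: a
propensity of one responds at the invitation, dropping a reminder can only
lose respondents, and responders spread ≈ 39/33/28% over the three contacts
at P ≈ 0.375.

Mode choice: the sequential arm (under 70) offers web only until the second
reminder adds paper; given both modes, the paper preference is 0.41 under 70
(chosen in closed form so the sequential arm realises 88.4% of completes
online: 0.28 × 0.41 ≈ 11.6% paper) and 0.767 at 70+, the simultaneous-arm
paper share. Batches start at days 0/57/72; paper returns lag log-normally
(median 10 days, σ = 0.5 — no empirical delay distribution is available) and
returns after day 142 (field end) are discarded. Partial interviews (consent
given, ≥ first two items) occur at rate 0.003 among respondents.
Never-responders split 3% undeliverable (unknown eligibility), then 30/70
refusal/noncontact — an assumption, as the true non-interview code
distribution is not published.

Double realizations are overlaid on 4.36% of respondents with a type mix of
86.0% web+paper, 13.4% paper+paper, 0.6% web+two-paper; the package's
resolution rules then retain exactly one record per person.

## 4. Case processing

The verification rules are exact matches with tolerances, applied per case
(hence order-independent):

1. all of sex/year/month agree → keep;
2. sex differs alone → keep, sex corrected from the questionnaire; sex plus
   *any* other deviation (read strictly: even a one-month difference) →
   exclude;
3. any year deviation → exclude;
4. month deviation ≤ 6 → keep with the questionnaire month; > 6 → exclude;
   register month missing → tolerance 12 months, i.e. any reported month is
   accepted and written back. A missing *questionnaire* month has no printed
   rule and is kept with a warning rather than guessed.

Month deviation is the absolute difference of month numbers; a year mismatch
already excludes, so no December/January wraparound case arises. The same
rule set re-runs between questionnaire and registration fields
(`registration_mismatch` on failure). Duplicate interview records resolve by
completion fraction (desc), then completion date (asc), then web before
paper — deterministic and idempotent. Validation: consented ∧ not excluded ∧
(web ⇒ double-opt-in confirmed); the deployment mode is the retained
record's mode and is frozen for later waves.

Outcome rates are computed on the *unadjusted* ledger (before verification),
as in the original study; exclusions only reduce the validated panel.

## 5. Outcome rates

RR1/RR2 use the AAPOR definitions with ineligibles (defective addresses)
removed from numerator and denominator during cleaning, so the denominator
is the cleaned gross. RECR divides validated panelists by the same
denominator. The web rate is computed after double-realization resolution;
the panel consent rate counts consenters (including unconfirmed web
consenters) over completes plus partials. Displayed rates are percent,
one decimal, half-up. Subgroup tables use cell-specific denominators, so the
overall rate is exactly the denominator-weighted mean of any partition's
rates (an identity the tests assert).

## 6. Selection models

The weighted logistic score equations Σ wᵢ(yᵢ − pᵢ)xᵢ = 0 are solved by
IRLS (tolerance 1e-8 on the step, ≤ 100 iterations; non-convergence is
flagged, separation raises naming the offending term). Variance is a
cluster-robust sandwich aggregating score contributions within sample
points, with a G/(G−1) correction — a pragmatic stand-in for fully
linearised design-based variance. AMEs for category c of predictor X are the
weighted mean of p̂(X:=c) − p̂(X:=reference) over all observations, ×100;
CIs use the delta method on that mean with the cluster-robust coefficient
covariance (chosen over the bootstrap for determinism). Reference
categories: youngest age group, male, Northeast, smallest BIK class, low
education, German citizenship, non-smoker, normal weight, never/none for
behaviour items. All predictors are categorical; no multiple-testing
correction is applied. The design-effect helper implements
deff = 1 + (m−1)·ICC and the implied SE inflation (√deff − 1)·100%.

## 7. Composition benchmark

Composition tables report (weighted) relative frequencies per recruitment
stage; education, citizenship and household size are marked absent at the
gross stage, where the register does not observe them. Deviation from the
benchmark is a one-sample chi-square goodness of fit, χ² = n·Σ(p−π)²/π
against the benchmark treated as a known population distribution (the
original appendix formula is unpublished; this choice is isolated behind
`gof_deviation`), with Cramér's V = √(χ²/(n(k−1))). Benchmarks ship as a
packaged CSV (population figures for sex/age/BIK/state; microcensus margins
for education, citizenship, household size). The low-education margin is
published both as 33.6 (tabulated) and 34.2 (text); the fixture records 33.6
and notes the variant.

## 8. Orchestration, seeds, problem sizes

One master seed drives every stage through named substreams
(`SeedSequence([seed, stream])`), so runs are bit-reproducible and stages
independently re-runnable. The default configuration — 200 municipalities,
350,000 persons, 72 sample points, 30,000 invited — runs the full pipeline
in ~10 s and keeps the whole test suite under a minute; the calibration
checks use this size (≈27,500 cleaned gross ≥ the 20,000 the stochastic
tolerances assume), and parameter-recovery studies use 20 cohorts of 50,000.
Recovery is judged per coefficient as |mean estimate − truth| ≤ 2× the SD of
the 20 replicate estimates: a bound on bias at the scale of a single
replicate's sampling noise. The stricter ±2·SD/√20 band around the mean is
not a calibrated joint test — with ~15 correlated terms it would flag a
correct implementation roughly half the time.

## 9. What the synthetic study does not show

* The generator reproduces the *directions and headline magnitudes* of the
  documented selection effects, not their exact coefficient values; real
  subgroup tables are not exactly reproducible from synthetic data.
* Participation depends only on register covariates; the real education bias
  *at the participation stage* (visible only against external benchmarks) is
  therefore not emulated — education selection enters at registration only.
* Address-defect, refusal/noncontact, paper-delay and double-realization
  parameters are assumptions where no empirical distribution is published.
* Inclusion probabilities ignore joint selection and the merging
  approximation described above; weighted estimates are design-consistent at
  the first order only.
* No incentive effects, hotline/contact-cost behaviour, reserve-sample
  activation, multi-language instruments, or poststratification weighting
  (deferred to a separate weighting exercise by design).
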