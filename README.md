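# probpanel

Probability-based panel recruitment, end to end: design a two-stage
stratified cluster sample from a (synthetic) population register, simulate
age-differentiated push-to-web mixed-mode fieldwork, apply deterministic case
verification, compute AAPOR-adapted outcome rates, and quantify selection
effects and sample-composition bias against official population benchmarks.

The package is aimed at survey methodologists and epidemiologists who want to
study — or teach — how a register-based recruitment design behaves: how the
minimum-allocation rule distorts state composition and how design weights
remove it again, how a push-to-web mode sequence splits respondents between
web (CAWI) and paper (PAPI), what the double-opt-in step costs in validated
panelists, and how nonresponse shifts the sample relative to microcensus
margins. Everything runs against a synthetic register, so no restricted
register extract is needed anywhere.

## The design in brief

**Sampling.** Sample points (PSUs) are allocated to the 16 federal states in
proportion to the 16+ population with a guaranteed minimum per state, applied
iteratively (fix states below the floor, rescale, repeat) and made integral
by controlled rounding (largest-remainder apportionment, the one-dimensional
Cox case). Within a state, points are spread over BIK size classes
proportionally to population and municipalities are selected by systematic
PPS. A municipality whose 600-address draw would cover more than 70% of its
eligible population is merged with its nearest neighbours (same district key,
same BIK class, ranked by |log population ratio|) into a *synthetic* sample
point. From each point, 600 addresses are drawn by age-stratified random
sampling with per-group counts ∝ (population share)/(expected recruitment
rate); 400 are invited and 200 held in reserve. Every record carries its
inclusion probability π and design weight 1/π.

**Fieldwork.** Invitees under 70 enter a sequential (push-to-web) arm — web
only at invitation and first reminder, paper added at the second reminder;
invitees 70+ get both modes from the start. A person with latent
participation propensity *P* responds at each of the three contacts with
hazard q = 1 − (1 − P)^(1/3); mode choice among offered modes follows an
age-dependent paper preference. Paper returns lag log-normally and are
dropped after the field-end horizon. Some respondents realise the interview
in more than one mode ("double realizations").

**Rates.** With I completes, P partials, R refusals, NC noncontacts, O other
non-interviews, U unknown-eligibility cases:

    RR1 = I / (I+P+R+NC+O+U)        RR2 = (I+P) / (I+P+R+NC+O+U)
    RECR = validated panelists / (I+P+R+NC+O+U)

plus the web rate (online share of interviews) and panel consent rate
(consenters / (I+P)).

**Case processing.** Register vs questionnaire verification on sex at birth,
birth year, birth month: sex-only mismatch is corrected from the
questionnaire; month deviations ≤ 6 months corrected, larger excluded (12
months' tolerance when the register month is missing); any year mismatch
excludes. Duplicate realizations resolve by completion > date > web-mode
precedence. A panelist is validated iff they consented, passed verification,
and — for web registrations — clicked the double-opt-in confirmation link.

**Selection models.** Design-weighted logistic regressions (IRLS, cluster-
robust sandwich variance over sample points) for participation and panel
registration, summarised as average marginal effects (AME) in percentage
points with delta-method 95% CIs. A design-effect helper gives
deff = 1 + (m−1)·ICC.

## Worked example

```python
from probpanel.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(), seed=1)   # ~1/50-scale nation, ~30k invited
print(result.funnel)
print(result.rates.to_dict())
```

prints (seed 1):

```
FunnelReport(drawn=45000, invited=30000, cleaned_gross=27492,
             completes=10348, partials=24, consenters=8121, validated=7773)
{'rr1': 37.6, 'rr2': 37.7, 'web_rate': 73.7,
 'panel_consent_rate': 78.3, 'recr': 28.3, ...}
```

Read: of 27,492 cleaned invited addresses, 37.6% completed the recruitment
interview (RR1), 73.7% of interviews were realised online, 78.3% of
respondents consented to recontact, and 28.3% of the cleaned gross ended as
validated (double-opt-in confirmed) panelists. The registration AME table in
`result.ame_registration` shows the expected selection pattern — e.g.
non-German citizenship −17.5 pp [−20.2, −14.8] and high vs low education
+9.4 pp [+7.5, +11.2] on the probability of registering.

The same run from the shell, persisting all stage artifacts (CSV/JSON plus
AME forest plots):

```bash
probpanel full-run --seed 1 --out runs/demo
probpanel rates --ledger runs/demo/ledger.csv
```

## Layout

| module | contents |
| --- | --- |
| `register_synthesis` | synthetic frame/register, ground-truth propensity model |
| `sampling_design` | controlled rounding, allocation, PPS selection, synthetic sample points, address draw, gross-sample cleaning |
| `fieldwork` | contact protocol, mixed-mode field simulation, double realizations |
| `case_processing` | verification rules, duplicate resolution, panel validation, BMI |
| `outcome_rates` | AAPOR-adapted rates and subgroup tables |
| `selection_models` | weighted logit + AME + design effect |
| `composition` | composition tables, chi-square / Cramér's V vs benchmarks |
| `pipeline` | end-to-end runner, config, funnel report |

See `docs/methods.md` for model assumptions, parameter defaults, and known
limitations.
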