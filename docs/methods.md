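# Methods

## Design

The package implements a within-cohort ("own-control") effectiveness design
for osteoporosis medications. Follow-up is **as-treated**: a patient
contributes person-time from the index prescription until the earliest of
treatment discontinuation, switch to another osteoporosis class, death,
disenrollment, or the administrative censor date (default 2018-12-31).
Person-time is cut at fixed day boundaries into an early-treatment window
(days 0–89) and four on-treatment windows (days 90–364, 365–729, 730–1094,
1095–1459); all intervals are closed-open and follow-up is capped at 1460
days. The early window is treated as a negative-control period — clinical
studies of anti-resorptives show no measurable effect on fracture outcomes
that soon after initiation — so its rate estimates the cohort's baseline
risk, cancelling time-stable confounding within patient. "Months" are mapped
to days deterministically (3 months = 90 days, 12 months = 365 days, etc.)
to avoid calendar-month ambiguity.

Effectiveness per window is the incidence rate ratio against the early
window. All fracture events are counted, including recurrences; CIs do not
adjust for within-person correlation of recurrent events (a documented
limitation: with multiple events per patient the intervals are mildly
anti-conservative).

## Cohort selection

Criteria are applied in a fixed order, each recorded in the attrition table:
(1) ≥ 1 qualifying osteoporosis prescription in the inclusion window
(2013-01-01..2017-12-31); (2) age ≥ 50 at index; (3) ≥ 24 months (730 days)
of enrollment before index; (4) no exclusion diagnosis — cancer, Paget's
disease, osteogenesis imperfecta — anywhere in the pre-index history (the
blanket reading; stricter and simpler than a windowed lookback); (5) no fill
of the index class in the 730 days before index (new-user washout, applied
at class level — a configurable choice, since molecule-level washout is an
equally defensible reading). Patients with under 183 days of observable
follow-up are flagged and excluded from the fracture analysis only; they
remain in treatment-pattern summaries.

Treatment groups follow a strict hierarchy (denosumab > intravenous
bisphosphonates > oral bisphosphonates > teriparatide > raloxifene > HRT).
The IV tier is reported as two cohorts, so within it the first-filled
sub-class wins and the index date is that sub-class's first in-window fill.
Oestrogen-only fills qualify as HRT only when a hysterectomy procedure code
precedes the fill. Age is computed from the birth date at the index date
(data with only a birth year should encode July 1).

## Episodes

The expected refill date after each fill is fill date + days supplied
(per-class days supplied are taken as the median of observed fills). The
episode continues while the next index-class fill arrives within 60 days
after the expected refill date. When the grace period lapses, a fill of a
different osteoporosis class inside the 60-day window after the expected
refill ends the episode as a *switch* at that fill's date; otherwise the
episode ends as *discontinued* at the expected refill date, i.e. at the end
of supplied coverage, so as-treated person-time contains no unexposed grace
days (`discontinuation_at: grace_end` selects the +60-day convention
instead). Within the grace window, precedence is chronological, with an
index refill winning a same-day tie. Supplies are not stockpiled: an early
refill resets the expected refill clock rather than accumulating coverage —
the plainest reading of "expected refill date", and the one a day-grid
brute-force oracle reproduces exactly in the tests. Death, disenrollment and
the administrative end truncate episodes regardless of fills (death takes
precedence on date ties).

## Fracture events

A diagnosis qualifies if it is inpatient, or outpatient with a
fracture-related procedure within ±30 days (the claims convention for
"diagnosis in combination with a procedure"; the window is configurable
because no canonical value exists). Qualified same-site diagnoses of one
person are chained: each diagnosis at most 90 days after the previous one in
the chain is the same event (a rolling, transitive merge — "within 3 months
*of each other*" — rather than a fixed window from the first diagnosis), the
event taking the date and source of its first diagnosis. Different sites
never merge. Sites come from an ordered prefix code map; the first matching
prefix wins, so specific codes (S32.0 vertebral) must precede broader ones
(S32 pelvis). The shipped map is a synthetic placeholder and is part of the
configuration, not the code.

## Estimation

Rates are events per 1000 person-years per window. IRRs use two interval
methods, both reported in output metadata: Wald on the log rate ratio
(default when both counts are ≥ 5) and exact-conditional — conditioning on
the total event count makes the on-treatment share binomial with odds
proportional to the person-time-weighted rate ratio, and a Clopper–Pearson
interval on that share maps to the rate-ratio scale. Zero on-treatment
events yield a point estimate of 0 with an exact upper bound; zero early
events make the IRR undefined and the result is flagged with exact bounds
rather than raised. Display rounding follows field convention (rates to one
decimal, IRRs and CIs to two).

The trend analysis is weighted least squares of the four on-treatment rates
on window index 1–4; weights default to window person-years (precision
weighting — the window totals differ by an order of magnitude) with an
equal-weights option, and the choice is echoed in output. The slope is the
rate change per on-treatment period.

The age sensitivity analysis is a conditional Poisson regression: counts per
(person, window) with log person-years offsets, stratified by person, so the
per-person baseline rate is conditioned out and only within-person contrasts
remain. The solver is an in-package Newton iteration on the multinomial form
of the conditional likelihood (statsmodels' conditional model drops
informative persons whose counts happen to be equal across windows, so it is
used as a cross-check, not the implementation). Age enters as the age at the
midpoint of the person's exposed interval in each window. Note an inherent
identification limit: within person, age advances in lockstep with the
window clock, so the age-only model's coefficient is the within-person time
slope interpreted on the age scale, and adding window indicators leaves age
identified only through person-specific truncation — those intervals can be
arbitrarily wide and are reported as such. Persons with no events or a
single observed window drop out of the likelihood by construction; a panel
with fewer than two informative persons returns a flagged, estimate-free
result.

## Synthetic claims generator

The generator emulates the structure of a German statutory-claims extract
for women initiating osteoporosis treatment, 2011–2018, indexed 2013–2017.
Per patient it draws a treatment class (default mix ≈ 8% denosumab, 31% oral
bisphosphonates, 4% IV ibandronate, 1% IV zoledronate, 55% HRT, small
teriparatide/raloxifene shares), an index date, an age at index (class-
specific means, ~72 years for anti-resorptives, ~56 for HRT, SD 9), an
enrollment span, and censoring times (death 3%/year, disenrollment 1%/year).
Index-class fills recur at supply + Exp(gap) days with a per-refill stopping
probability; supplies (180 d denosumab, 30 d oral BP, 90 d IV ibandronate,
365 d zoledronate, 28 d teriparatide, 90 d HRT) and stopping probabilities
were set so that uncensored median persistence approximates real-world
orderings (denosumab ≈ 580 d ≫ oral bisphosphonates ≈ 260 d); administrative
censoring shortens realised medians below these, as it does in real data.

Fracture events are an inhomogeneous Poisson process with piecewise-constant
rate on the analysis windows, anchored at the generator's index date:
baseline hazard (default 87.6 per 1000 PY across seven sites, vertebral
dominant) before day 90 and baseline × r_w inside window w (beyond day 1460
the last window's ratio persists). Sampling uses per-segment Poisson counts
with uniform times, which realises the same process as exponential
inter-arrivals and keeps the draw sequence deterministic. Each event emits
an inpatient diagnosis with probability 0.6, otherwise an outpatient
diagnosis plus a same-day procedure, exercising both arms of the case
definition; a fraction of events emit a duplicate same-site diagnosis within
80 days to exercise merging. The funnel is populated deliberately: 16% of
patients carry an exclusion diagnosis, 8% have short pre-index enrollment,
and 40% are prevalent users given an index-class refill chain reaching back
more than 24 months before the inclusion window (long-enrolled, so the
washout — not the history criterion — removes them, mirroring the shape of
real attrition funnels). Prior-treatment history is drawn from
lower-hierarchy classes (pre-window dates for HRT) so that it sets the
prior-treatment flag without stealing the hierarchical assignment or
shifting the index clock. Optional knobs create a prior-fracture subgroup
with multiplied hazard (for stratified scenarios) and a per-year-of-age rate
ratio applied at window midpoints.

What the generator does **not** emulate: German billing semantics (quarterly
outpatient aggregation, EBM catalogues), morbidity-based sampling weights,
coding noise and misclassification, seasonality, secular trends, or
informative censoring (death is independent of fracture risk). Passing tests
therefore demonstrate that the pipeline's algorithms are correct and that
estimation is calibrated under the stated generating model — not that any
particular real-world estimate is unbiased in the presence of those
unmodelled features.

## Numerical and scale choices

Determinism: one `numpy` Generator seeds every draw; identical config + seed
give byte-identical tables and outputs. Episode and merge algorithms are
verified exactly against brute-force oracles on 1,000 random cases each.
Monte-Carlo checks run at sizes chosen to put simulation error well inside
the asserted tolerances: window-ratio recovery uses 100 replicates of 5,000
patients (per-replicate SD of the sparsest window's estimate ≈ 0.16, so the
mean carries ≈ 0.016 MC error against a 0.05 tolerance); the null
(type-I-error) check uses 200 replicates of 5,000 patients; Wald coverage is
assessed over 500 count-level replicates at the person-time scale of the
recovery scenario. The acceptance script pools event counts and person-time
over 30 replicates of 20,000 patients.

## Limitations

Beyond the generator gaps above: no between-treatment comparative estimates
(baseline risks differ by design); no adjustment for time-varying
comorbidity or differential censoring; no post-discontinuation analysis
(only the index episode is built); no Charlson index (baseline flags stand
in for descriptive comorbidity); the conditional Poisson age effect is
identified from the window clock as described. The attrition funnel's
prevalences and the hazard presets are scenario parameters, not estimates of
any real population.
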