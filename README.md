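# osteoepi

Own-control (within-cohort) analysis of osteoporosis-treatment effectiveness
from administrative claims data, plus a synthetic claims generator with known
ground truth.

## The problem

Randomised trials established that anti-resorptive drugs (denosumab,
bisphosphonates), teriparatide, raloxifene and hormone replacement therapy
reduce fracture risk, but routine-care effectiveness has to be estimated from
observational claims data, where treated and untreated patients differ
systematically. The own-control design sidesteps between-patient confounding:
each patient's fracture rate in the **early-treatment window** (the first 3
months after the index prescription, assumed to carry no measurable treatment
effect) serves as her own baseline, and effectiveness is the change in rate
over subsequent **on-treatment windows** (months 4–12, 13–24, 25–36, 37–48),
with follow-up censored as-treated at discontinuation, switch, death,
disenrollment or the administrative study end.

For a window $w$ with $N_w$ fractures over $T_w$ person-years and an early
window with $N_0$ fractures over $T_0$ person-years, the incidence rate ratio
is

$$\mathrm{IRR}_w = \frac{N_w / T_w}{N_0 / T_0},\qquad
95\%\ \mathrm{CI} = \exp\!\Big(\ln \mathrm{IRR}_w \pm 1.96\sqrt{\tfrac1{N_w}+\tfrac1{N_0}}\Big),$$

with an exact-conditional interval (binomial split of $N_w$ given
$N_w + N_0$) substituted when either count is small. Secondary analyses fit a
person-years-weighted linear trend of the on-treatment rates and a
person-stratified (conditional) Poisson model of fracture counts with a log
person-years offset and age as a time-varying covariate.

## What the package does

From four claims-style tables — enrollment, prescriptions, diagnoses,
procedures — the pipeline:

1. **cohort**: selects new users (women ≥ 50 at index, ≥ 24 months pre-index
   enrollment, no cancer/Paget's/osteogenesis-imperfecta history, no
   index-class fill in the 24-month washout), assigns one treatment group per
   patient by a fixed hierarchy (denosumab > IV bisphosphonates > oral
   bisphosphonates > teriparatide > raloxifene > HRT), and emits an attrition
   funnel;
2. **episodes**: builds index-treatment episodes with the 60-day refill-gap
   rule and classifies discontinuation vs switch;
3. **fractures**: identifies fracture events (inpatient diagnosis, or
   outpatient diagnosis plus fracture-related procedure) and merges same-site
   diagnoses within 90 days into single events;
4. **incidence**: splits as-treated person-time into the analysis windows and
   estimates rates per 1000 person-years and own-control IRRs, overall and
   stratified by prior fracture or prior treatment;
5. **models**: weighted rate trend and the age-adjusted conditional Poisson
   sensitivity analysis.

Because real claims databases are proprietary, `osteoepi.simulate` generates
synthetic bundles whose fracture process is a piecewise-constant Poisson
process anchored at each patient's index date: a configurable baseline hazard
in the early window and baseline × $r_w$ in each on-treatment window. The
$r_w$ are generator inputs, so every downstream estimate has a testable truth.

## Worked example

`examples/demo.yaml` simulates 20,000 denosumab initiators whose true
on-treatment rate ratios are 0.62, 0.50, 0.44 and 0.33:

```bash
osteoepi all -c examples/demo.yaml -o demo_run --seed 1
```

`demo_run/rates.csv` (all fractures):

```
window  events  person_years  rate_per_1000py
 early     202       2203.86            91.66
 m4_12     301       5453.03            55.20
m13_24     147       3619.43            40.61
m25_36      55       1470.36            37.41
m37_48      17        523.15            32.50
```

and `demo_run/irr_display.csv`:

```
window   N         irr_95ci
 m4_12 301 0.60 (0.50-0.72)
m13_24 147 0.44 (0.36-0.55)
m25_36  55 0.41 (0.30-0.55)
m37_48  17 0.35 (0.22-0.58)
```

Reading: the early-window rate of 91.7 per 1000 PY is the cohort's own
baseline risk; the on-treatment rates fall progressively, and every window's
IRR confidence interval covers the generating truth. The run directory also
contains the attrition funnel, episodes, duration summaries, stratified
tables, the trend fit, the age model and a JSON manifest (config echo, seed,
versions, row counts) that makes the run byte-reproducible.

## Scope notes

The shipped code map (ICD-10-GM-like fracture-site prefixes, exclusion codes,
procedure codes) is a synthetic placeholder for non-public study code lists;
supply your own YAML map for real data. Between-treatment comparisons are out
of scope by design: baseline risks differ across cohorts, so each cohort's
IRRs are interpretable only against its own early window. See
`docs/methods.md` for model assumptions, parameter defaults and limitations.
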