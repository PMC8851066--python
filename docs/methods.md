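# Methods

## Data model

The package operates on a linked suite of per-patient, date-stamped CSV
tables emulating regional healthcare-utilisation databases: a registry
(`patients.csv`), mental-health contacts with setting and intervention type,
hospital/residential admissions with ward and dates, drug dispensings with
ATC code and amount, lab tests, deaths, and three reference tables (DDD per
ATC code; general-population mortality rates per sex × 5-year age band;
standard-population weights). Dates are calendar dates; internally every
computation runs on integer day offsets with half-open `[start, end)`
intervals. Linkage is by `patient_id`; because event rows carry no region
column, ids must be globally unique across regions in one table suite (the
validator enforces this, slightly stronger than per-region uniqueness).

Age is `floor((date − birth_date)/365.2425)` — a pure day-arithmetic
convention that vectorises cleanly and is applied identically by the
generator and the cohort builder. On exact-anniversary dates it can differ
from calendar age by a day's worth of rounding; the generator keeps birth
dates ≥10 days away from anniversaries so planted ages are unambiguous.

Diagnosis code sets are configurable prefixes accepting both ICD-9-CM
(295\*, 297\*, 298\*) and ICD-10 (F20–F29) dialects at once; antipsychotics
are ATC prefix N05A minus lithium (N05AN01). Both are overridable via
`CodeConfig` / YAML, since locally used code lists vary.

## Cohorts

**Prevalent**: ages 18–65 at index with ≥1 diagnosis-qualifying mental-health
event (contact, or GHPW/CRF admission) in the recruitment window (default
calendar 2015); index = earliest such event; follow-up = 365 days. Members
not observable for the full year are excluded, with one carve-out: patients
who die during follow-up are retained with person-years censored at death.
They feed the mortality indicator only — without the carve-out the SMR would
be undefined — and are excluded from all proportion/mean denominators
(`full_follow_up = False`).

**Newly taken-in-care**: prevalent members aged 18–40 passing three
exclusions — (i) no qualifying diagnosis at any time before index (lifetime),
(ii) no GHPW admission and (iii) no two *consecutive* antipsychotic
dispensings (episode gap < 90 days, both dispensings dated) within the
lookback window (default 2 years, configurable). The upper age bound reflects
the unreliability of first-contact detection at older ages in administrative
data. Whether exclusion (ii) should be lifetime is genuinely open; we bind
"within the two years" to both (ii) and (iii) and expose `lookback_years`.

## Temporal rules

* Supply duration = `ceil(amount/DDD)` days; stockpiling appends (new supply
  starts when the previous ends). Consecutive iff gap < 90 days (a 90-day gap
  interrupts — the boundary is strict and tested).
* Drug persistence is evaluated on the union of supply across antipsychotic
  substances, so switching is not an interruption; an uncovered run of ≥ 90
  days between therapy start and follow-up end — including a trailing run
  before day 365 — means discontinuation. Requiring coverage through the
  window end is a choice (treatment "carried through the year"); the
  alternative (ignore trailing gaps) would count a 30-day supply as
  persistence.
* Community persistence: no uncovered run ≥ 90 days in the 365 days after the
  first community contact; CMHC and day-care contacts count as 1-day
  coverage, inpatient (GHPW/CRF) stay days count as covered (continuity of
  care); home visits are outreach and do not count.
* "Within k days" after discharge means days 1..k inclusive; a same-day
  admission is a transfer, not a readmission. The admission is the
  statistical unit; stay lengths are counted in full for admissions starting
  within follow-up (clipping at day 365 would bound mean residential stays
  at impossible values given means near half a year), and readmissions or
  post-discharge contacts may be observed past the follow-up end, which
  keeps per-discharge probabilities unbiased for late discharges.

## Indicator catalogue

~30 indicators over three domains, each an aggregation of one feature column
computed per member (or per GHPW admission): proportions with binomial SE;
cohort-wide means per person-year (total events / total person-years, SE from
the per-patient rate spread); intervention-specific session means *among
users* (patients with ≥1 such event) — the only reading under which typical
published values (e.g. psychosocial intensity well above the overall contact
mean times access) are mutually consistent; admission-level proportions and
means; and the SMR. Empty denominators yield NaN, never zero. The catalogue
is a list of declarative `IndicatorDefinition`s (feature column + statistic +
optional denominator restriction) and is user-extensible.

## Pooling, heterogeneity, SMR

Pooled estimate = summed numerators over summed denominators. Homogeneity:
for proportions, the k-sample χ² on the 2×k table (no continuity correction),
Q = χ², df = k−1; for means, one-way ANOVA reconstructed from per-region
(n, mean, sd) summaries — algebraically identical to raw-data ANOVA, verified
against `scipy.stats.f_oneway` in the tests. *I*² = max(0, (Q−df)/Q)·100,
with Q for means taken as the inverse-variance-weighted sum of squared
deviations (meta-analytic Q); an ANOVA-based variant max(0,(F−1)/F)·100 is
exposed as an option since the convention for mean-type indicators is not
standardised. Fewer than two defined regional estimates → pooled value with
heterogeneity fields undefined.

SMR = observed/expected, expected = Σ members per (sex, 5-year band) × annual
general-population rate (patient counts, not person-years, matching the
one-year window). Exact 95% CI from χ² quantiles of the Poisson observed
count (Garwood): `[χ²(.025, 2O)/2E, χ²(.975, 2O+2)/2E]`, lower bound 0 when
O = 0. Coverage is verified ≥ 93% over 2,000 Poisson replicates.

## Synthetic-data generator

The generator emulates multi-region HCU streams with every indicator's true
value planted, so the pipeline is testable by parameter recovery. Defaults
are the overall prevalent-cohort values the system is designed to reproduce
(39.2/10k treated prevalence, 27.7 contacts/py, 54% psychosocial access,
171 residential days among admitted, SMR multiplier 1.70, ...).

Planting is constructive, not by rejection:

* **Registry**: uniform sex, uniform ages in range, birth dates back-computed
  so floor-age at index equals the drawn age; coverage 2008–2019 so late
  stays close before coverage end. Case status Bernoulli at prevalence;
  new-case status a conditional Bernoulli among cases aged 18–40 (planted
  incidence ≤ prevalence). New cases have empty histories; other young cases
  receive a pre-recruitment diagnosis contact so the lookback exclusions
  identify exactly the planted new set.
* **Contacts**: the index psychiatric visit at day 0 plus Poisson component
  counts (psychiatric visits, "other professional" remainder, psychosocial
  sessions split into psychotherapy/psychoeducation/rehabilitation with
  conditional access so marginal access probabilities are exact, family
  interventions, structured assessment). The "other" mean absorbs the
  difference so the overall contacts-per-year mean is exact; the parameter
  validator rejects inconsistent combinations. Conditional session means are
  planted as `1 + Poisson(mean − 1)`, hence must be ≥ 1.
* **Admissions**: Bernoulli access; stay lengths geometric with the planted
  mean; readmission chains place the next admission 1–7 or 8–30 days after
  discharge with the planted per-discharge probabilities.
* **Timeliness and persistence**: per-discharge 14-day contact and home-care
  flags either *require* a contact in the window (repositioning one drawn
  contact, so counts stay exact; windows beyond day 365 get an appended
  contact instead, invisible to in-window indicators) or *block* the window.
  Community persistence flags are satisfied by repositioning contacts to
  close ≥90-day coverage gaps, or by reserving one 90-day contact-free window
  disjoint from admissions and required windows; when long stays make
  non-persistence infeasible, flags are swapped with an admission-free
  persistent patient, preserving the planted count exactly. Rare collisions
  (a required window fully blocked) resolve in favour of the required
  contact; the induced bias is orders of magnitude below Monte-Carlo noise at
  realistic rates.
* **Dispensings**: persistent patients get refill chains (25–35 days supply,
  gaps < 46 days) covering the year; non-persistent patients one supply
  ending ≥ 91 days before the window end. Polytherapy-flagged patients get a
  second substance overlapping > 30 days; others stay on one substance, so
  the planted proportion is exact.
* **Deaths**: Bernoulli at sex/age-band reference rate × SMR multiplier;
  events after death are truncated, coverage ends at death. Decedents are
  excluded from proportion/mean denominators (protecting their planted
  values) and drive the SMR, whose expectation matches the multiplier
  exactly under the patient-count expected-death convention.

Fixed seed ⇒ byte-identical output (one PCG64 stream per region keyed on
(seed, region index)).

**What the generator does not emulate** — and therefore what passing recovery
tests do *not* show about real data: realistic age pyramids (ages are
uniform), comorbidity and correlated utilisation (features are independent
given the planted flags), seasonal patterns, private-sector care, coding
errors and incomplete linkage, regional case-mix differences. Recovery tests
demonstrate that the pipeline measures what the rules define, on data where
the truth is known; they are not a validation of the indicator definitions
against clinical reality.

## Problem sizes and numerical choices

The recovery suite runs one 4-region simulation with ~20,000 cases
(prevalence scaled to 400/10k so that a 500,000-person registry yields that
cohort; every indicator parameter is planted at its default) and requires
each recovered indicator to fall within 3 Monte-Carlo SEs of its planted
value, in both cohorts. The acceptance script sizes each run from the same SE
arithmetic: 2.6M inhabitants for the prevalence rate (3 SE ≈ 1.2 on 39.2),
3M aged 18–40 for incidence (3 SE ≈ 0.3 on 3.1), 2M members for the SMR,
~10,000 prevalent cases for contact/stay means, ~5,700 new cases for
psychotherapy access. Ties and degenerate inputs: empty denominators → NaN;
single-region pooling returns the estimate with heterogeneity undefined;
DDD durations round up to whole days; all thresholds (90/30/14/7 days)
carry their defaults as explicit, overridable parameters.

## Known limitations

* The indicator catalogue is reconstructed from published summary
  descriptions; local deployments will want to adjust definitions (the
  catalogue is declarative) and real code lists for diagnoses, interventions
  and ATC groups.
* Means among users are sensitive to the denominator convention; both the
  convention and its rationale are stated above rather than hidden.
* The ANOVA-based homogeneity test from summary statistics assumes
  within-region SDs are well estimated; with very small regional cohorts the
  meta-analytic Q (default) is the more stable choice.
* No risk adjustment or case-mix standardisation beyond age/sex; no
  random-effects pooling; no small-sample Q corrections.
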