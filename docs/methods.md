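# Methods

## The phenotype and its premise

The method classifies patients as likely marijuana users or non-users from
bare term presence in clinical note text. Its premise: clinicians mention a
specific psychoactive substance in a progress note chiefly when use is
current or former, so a mention is positive evidence and its assertion
status (affirmed, negated, historical) is deliberately ignored. This is a
high-recall, modest-precision screen intended for cohort *recruitment*, not
a diagnostic instrument — definitive exposure comes from the follow-up
interview. The package keeps that division of labor: the classifier never
weighs mention counts, recency, or context, and the validation layer reports
how well bare mention-presence predicts interview self-report.

## Matching rules

Matching is whole-word and case-insensitive over NFC-normalized text. A hit
requires the characters immediately before and after the match to be absent
or non-alphanumeric; digits count as word characters, so `mjx2` does not
contain `mjx` and `TMJ` does not contain `mj` (underscore is treated as a
boundary). Hyphenation or line breaks inside a term are not bridged:
`mari-\njuana` is not a match, consistent with a literal string-search
facility. Mentions are non-overlapping, longest-first at each position, and
sorted by offset. The default lexicon enables `marijuana`, `cannabis`,
`mjx`; `mj` is present but disabled, togglable in a config copy, so the
discard decision stays auditable.

## Cohort, window, sampling

* **Cohort filter** (all conjunctive, pure, order-preserving): any diagnosis
  code with a 410–414 ICD-9 root (the conventional coronary-artery-disease
  range; the exact code list used operationally is configurable because no
  canonical list exists), age 65–67 inclusive at the index date, and at
  least one visit inside the index-year window (both ends inclusive).
* **Lookback window**: "past 12 months" is the 365 calendar days ending at
  and including the study-level index date, i.e. `[index − 364 d, index]`.
  The edges are tested explicitly: a mention at index − 364 counts, at
  index − 365 it does not. A single study-level index date is used rather
  than per-patient anchoring; it is a configuration value.
* **Arm sampling**: uniform without replacement via
  `numpy.random.default_rng(seed)`, n = 51 per arm by default. Exclusions
  follow the recruitment narrative's order — sample first, then remove
  deceased patients, then set aside those without contact information — so
  the accounting chain (51+51 → 99 → 97) is reproducible from the seed,
  which is recorded in the sample object and every run manifest.

## Validation statistics

The concordance table cross-tabulates the two arms against overlapping
self-report categories: past-30-day, past-year, lifetime-ever (nested), and
non-use. Non-use is the complement of ever-use within the interviewed arm
(`ever + nonuse = arm total`), which is what the arithmetic of the standard
presentation implies; "no use in the past year" would be a different, larger
count. Because the rows overlap, the table stores separate counters rather
than forcing a partition.

Predictive values are `100 · cell / arm_total`, rounded half-up to one
decimal (banker's rounding would differ at exact halves); the recruitment
rate is displayed as a whole-number percent. Enrichment returns the
(negative-arm, positive-arm) pair in the presentation order "increased from
X% to Y%".

The headline association test is the two-sided Fisher exact test, computed
by direct hypergeometric enumeration (sum of all tables at the fixed margins
whose point probability does not exceed the observed, with the standard
1 + 1e-7 near-tie tolerance); it is cross-checked in the tests against both
an exact-integer enumeration oracle and `scipy.stats.fisher_exact`,
exhaustively for every 2×2 table with positive margins and n ≤ 40. Pearson
chi-square variants (with and without Yates continuity correction) delegate
to `scipy.stats.chi2_contingency`. On the ever-use table [[33, 2], [23, 11]]
this package's Fisher p is 0.0057 (chi-square 0.0047, Yates 0.0117); group
summaries are descriptive only (means for numeric covariates, percentages
for binary/categorical), with no attached tests.

## Exposure

Joint-years: `jy = joints_per_day × days_used / 365`, linear in each
argument, with `jy(1, 365) = 1` as the unit definition. Only smoked exposure
contributes; vaping, topical, and edible use are recorded as modes without a
joint equivalent. Frequency categories (daily; weekly but not daily; 2–3 per
month; less often; none) map to representative days/year for simulation —
365, 104, 30, 12, 0 — as overridable defaults on the simulation config.

## The synthetic study generator

No real chart corpus can ship, so the generator emulates one with a known
latent truth. Notes are short template sentences (a packaged YAML file) with
slots for terms, negation cues, and boundary-confuser tokens (`TMJ`,
`cannabinoid`, `MJX2`) that a correct whole-word matcher must not hit.

**Probabilistic mode.** Each patient draws nested use flags
(ever ⊇ past-year ⊇ past-30-day) and a documentation flag: a past-year
user's chart carries an in-window mention with probability
`p_documented_given_past_year_use`, anyone else's with
`p_term_given_no_past_year_use`. Planted mentions are phrased as negations
at `negated_mention_rate` — still detected, by design; the tests assert the
negated contribution to false positives rises monotonically with that rate,
documenting the method's known limitation. Patients may also carry
out-of-window historical mentions that the classifier must ignore. Default
parameters (n = 210; P(ever) = 0.75; P(past-year | ever) = 0.30;
P(past-30d | past-year) = 0.83; documentation probabilities 0.63 / 0.20) are
back-derived from the validation cross-tabulation of the target population,
so the defaults reproduce, in expectation, a ~30% term-positive rate with
past-year PPV near 48%. Under this model the measured PPV converges to the
Bayes-rule value P(past-year | mention); the suite verifies convergence
within 3 Monte-Carlo standard errors at n = 20,000.

**Exact-count mode.** Cohort size (210 qualifying patients plus a few
registry decoys that must fail the filters), the 62/148 term split, 5
historical-mention-only patients, the 51 + 51 sample, 1 + 2 deceased, 2
without contact, the 35/34 completed-interview arm totals, the concordance
cells (15, 17, 2, 33 and 3, 4, 11, 23), the 1/20/7 refusal/unreachable
disposition, and the 16-of-18 predominantly-smoking exposure pattern
(7 daily, 2 weekly, 1 at 2–3/month) are planted as exact counts. Deceased
and no-contact flags are planted on ids drawn by the same seeded sampler the
pipeline re-runs, which is why every narrative count is recovered at any
seed. Realized counts are asserted equal to requested counts.

A single global seed drives named sub-streams (registry, truth, notes,
sampling, interviews, exposures) via `numpy.random.SeedSequence.spawn`, so
adding one stage does not perturb the others; fixed-seed runs are
byte-identical.

**What the simulation does not model.** Real clinical language (section
structure, misspellings, templated smart-text), per-patient documentation
propensity, correlation between documentation and visit frequency, and
interview measurement error beyond independent per-flag misreporting. A
green suite therefore shows the machinery is correct under the stated
generative assumptions, not that the phenotype attains these predictive
values in another health system.

## Numerical and design choices

* Percentage rounding is half-up via `decimal`, matching display convention;
  all comparisons in tests use the displayed precision.
* Degenerate inputs raise typed errors rather than returning sentinels:
  zero-margin 2×2 tables, empty arms, zero contacted, empty exposure sets.
* Readers report malformed rows with file and line; an empty input file is a
  warning, not an error.
* The interview schema is a minimal structured response (three nested
  booleans plus completion and disposition); the survey instruments behind
  it are out of scope.
* Mean joint-years among current smokers depends on simulated per-person
  amounts, so it varies with seed; the other narrative quantities are planted
  counts and do not. Published per-person amounts do not exist to plant.
* Problem sizes in the suite: exhaustive Fisher check at n ≤ 40 (~10⁵
  tables), 1,000 random texts for the matcher oracle, n = 20,000 patients
  for parameter recovery — sizes at which each check is exhaustive or the
  Monte-Carlo error is far below the tolerance, while the full suite stays
  under a minute.

## Known limitations

Negation blindness inflates the term-positive arm with patients whose charts
explicitly deny use; the measured past-month PPV of ~43% is the cost of that
simplicity. The word-boundary rule cannot rescue terms split across line
breaks. The cohort filter's code list and the index-date convention are
configuration, not validated truth. None of the validation statistics carry
confidence intervals; arm sizes near 35 make the percentage granularity
about 3 points.
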