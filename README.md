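# cannaphen

Lexicon-based computable phenotyping of marijuana use from the free text of
electronic medical records, with the chart-review validation statistics and
exposure quantification that go with it, and a synthetic study generator so
the whole pipeline runs without protected health data.

## The problem

Prospective cohorts for studying the cardiovascular effects of marijuana are
hard to assemble: screening by mail or telephone is costly and yields little
exposure. Within a large health system, clinical notes already carry the
signal — when a clinician writes a specific psychoactive substance into a
progress note, the mention itself suggests current or former use. `cannaphen`
implements that idea as a deliberately simple computable phenotype:

* **Lexicon.** Whole-word, case-insensitive search for `marijuana`,
  `cannabis`, and the chart shorthand `mjx`. The abbreviation `mj` ships
  disabled (it collides with temporomandibular-joint abbreviations such as
  TMJ). No negation detection, by design: "denies marijuana use" counts.
* **Classification.** A cohort patient (aged 65–67, coronary artery disease
  by ICD-9, ≥ 1 primary-care visit in the index year) is a *preliminary
  user* if any enabled term appears in any note dated in the 365 days ending
  at the index date, else a *preliminary non-user*.
* **Sampling & validation.** Equal arms are drawn with a seeded generator,
  deceased and contact-less patients are excluded after sampling, and the
  classification is validated against telephone-interview self-report: a
  concordance table over nested recall windows (past 30 days ⊂ past year ⊂
  lifetime), positive predictive values PPV = 100 · n(arm ∩ category) /
  n(arm), enrichment contrasts between arms, and a Fisher exact test on
  ever-use.
* **Exposure.** Self-reported amount is summarized in joint-years, the
  marijuana analogue of pack-years: jy = joints/day × days used / 365, so
  one joint per day for 365 days is exactly 1.0.

## Worked example

Generate the packaged exact-count synthetic study and run the pipeline:

```bash
cannaphen simulate --seed 1 --out-dir fixtures/
cannaphen run --notes fixtures/notes.jsonl --patients fixtures/patients.csv \
    --interviews fixtures/interviews.csv --exposures fixtures/exposures.csv \
    --seed 1 --out-dir out/
```

The report printed (and written to `out/report.txt`) reads:

```
== Cohort and classification ==
Cohort patients passing filters: 210
Preliminary users (term in notes, past 365 days): 62
Preliminary non-users (no term): 148

== Arm sampling ==
Drawn per arm: 51
Deceased excluded after sampling: 3
Retained: 50 potential users + 49 potential non-users = 99
Without contact information: 2
Contactable: 97

== Recruitment ==
Contacted: 97
Refused by message: 1; refused on call: 20; unreachable: 7
Completed interviews: 69  (recruitment rate 71%)

== Concordance (arm totals: 35 term-positive, 34 term-negative) ==
Use in past month       15 (42.9%)     3 (8.8%)
Use in past year        17 (48.6%)     4 (11.8%)
Non-use (never)          2 (5.7%)    11 (32.4%)
Ever use                33 (94.3%)    23 (67.6%)
Probability of past-month use increased from 8.8% to 42.9% in patients with a term in their notes.
Probability of lifetime ever use increased from 67.6% to 94.3% in patients with a term in their notes.
Ever-use association (Fisher exact, two-sided): OR=7.89, p=0.0057
```

Reading it: of 210 cohort patients, the text search flags 62; after seeded
51 + 51 sampling and exclusions, 97 are contactable and 69 complete the
interview. Among the 35 interviewed term-positive patients, 15 report use in
the past month (PPV 42.9% against the current-use standard), 17 in the past
year (48.6%), and 33 ever (94.3%); a term in the chart raises the
probability of past-month use from 8.8% to 42.9%. In the exposure section,
16 of the 18 current users predominantly smoke (88.9%).

Library use mirrors the CLI: `classify_cohort`, `sample_arms`,
`build_concordance`, `predictive_value`, `enrichment`, `association_test`,
`joint_years` are all importable from `cannaphen`.

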