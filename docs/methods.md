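# Methods

## The index

The engine implements a 36-deficit electronic frailty index under the
cumulative deficit model. Each factor f ∈ {1..36} is a binary slot; the
score is k/36 where k is the number of slots with evidence. The model's
assumptions are inherited from deficit-accumulation frailty indices
generally: deficits are exchangeable (each contributes 1/36 regardless of
severity), and a single documented mention is sufficient evidence of
presence. The score is therefore a *case-finding* signal — a prompt for
clinical assessment — not a diagnosis; no severity weighting or predictive
calibration against outcomes is attempted here.

Presence is decided per factor by the **any-one-entry rule** over a
superset terminology dictionary. The superset design is deliberate: coding
practice is heterogeneous, and restricting to any single vocabulary
(billing codes only, or free text only) systematically under-captures
factors — functional and social deficits in particular are carried almost
entirely by free text. The dictionary analytics quantify this per factor
(`capture_category`).

## Dictionary semantics

- **One factor per entry.** A (system, normalized code) pair or a phrase
  mapped under two factors would let one record raise the score twice;
  validation makes this a hard error. The published constraint covers
  codes; we extend it to phrases for the same double-counting reason (a
  deliberate design extension, configurable nowhere — it is load-bearing).
- **ICD9 vs ICD9-CM.** Every ICD9 code exists within ICD9-CM, so both
  systems share one normalized code space; matching is exact equality
  after normalization (trim, uppercase, dots removed), with *no prefix
  expansion* — the dictionary is already maximally inclusive, so expansion
  would only add unvetted codes.
- **Free-text matching** is token-based: text is lowercased, diacritics
  folded, punctuation mapped to spaces (`#` excepted — it is clinician
  shorthand for "fracture" and must remain matchable), whitespace
  collapsed; a phrase fires iff its token sequence occurs contiguously.
  This prevents substring artifacts ("flutter" inside "butterflutter").
  Spelling variants and acronyms are *dictionary entries*, not fuzzy
  logic: the method is enumerated term presence.
- **Exclusions** veto at the level of the whole text field: if any
  exclusion phrase of an entry occurs anywhere in the field, that entry
  cannot fire there. Field scope (rather than adjacency) matches the
  "excluded from the search" behavior the term lists describe and is the
  conservative choice — it can only suppress matches.
- **Subsumption** attaches longer phrases to a parent entry; either the
  parent or a subsumed phrase firing emits exactly one result for the
  factor. In analytics, subsumed phrases are counted as separate unique
  terms (so "disability" + "disability form" contribute 2 to the factor's
  free-text count), which is how the published per-factor tallies count.
- **Lab entries** fire on presence of the LOINC-coded result by default.
  Where mere presence of a test is not diagnostic, an entry can carry a
  numeric threshold (direction + cutoff) that the result value must
  satisfy. The default is presence because the dictionary's inclusion rule
  already restricts labs to definitively diagnostic ones.
- **Negation is not handled** ("no falls" matches "falls"): term presence
  is the method. This is a known limitation, stated rather than patched.

## Polypharmacy

The one rule-based factor: flag = (number of **distinct** medications
prescribed in the half-open window (index − 12 months, index] ≥ 5),
distinct by ATC code with fallback to normalized drug name. Distinct
medications, not prescription events, is the standard polypharmacy
definition; an event-count mode exists (`distinct=False`) for sites that
prefer it. The anchor date is the scoring index date. A medication that is
also factor evidence (e.g. levothyroxine) counts toward both its factor
and the medication tally — no exclusion rule is documented, and removing
it would silently weaken the tally.

## Cohort handling

Input tables are CPCSSN-style flat CSVs with fixed headers and ISO-8601
dates. Rows violating a table invariant (missing patient id, unparseable
date, diagnosis with neither code nor text, lab without LOINC, medication
with neither ATC nor name) are dropped but counted and logged; files with
missing columns fail hard. Eligibility is age ≥ 65 in completed years at
the index date (a birthday on the index date counts as attained). The
observation window defaults to 2017-07-01..2022-06-30 inclusive, index
2022-06-30; whether lifetime history outside an extraction window should
still count as deficits is an open clinical question, so the window is
configuration, not policy.

## Severity bands

Cut points are not part of the index definition here; `CategoryConfig`
defaults to the UK convention (fit ≤ 0.12 < mild ≤ 0.24 < moderate ≤ 0.36
< severe), boundary values falling in the lower band. Bands are reported
only when requested.

## Synthetic cohorts

The generator emulates the documentation heterogeneity the superset
dictionary exists for. Per patient: true deficits are independent
Bernoulli draws (default flat prevalence 0.15 per factor — a plausible
order of magnitude for individual deficits in a 65+ primary-care
population); each true deficit is charted at all with probability
`documentation_prob` (default 1.0), and if charted, documented as a code
row (probability `q_code` = 0.45), a free-text phrase (`q_text` = 0.35), or
both (`q_both` = 0.20) — codes route to the table their system implies,
phrases are embedded in neutral encounter templates. Polypharmacy truth is
realized directly in the medication table (≥5 distinct in-window
medications when true, ≤4 when false, counting any dictionary-medication
evidence already emitted). Two adversarial channels are planted:
distractor encounter texts from a vocabulary verified disjoint from every
dictionary phrase, and exclusion traps (an entry's exclusion phrase
prepended to its own phrase, e.g. "ventricular flutter") emitted only for
patients without that factor. Traps make the exclusion logic falsifiable:
tests show zero trap false positives with exclusions on and strictly
positive counts with them off.

What the generator does **not** model: disease co-occurrence (deficits are
independent, unlike real multimorbidity), longitudinal progression,
clinician-specific style, multi-provider notes, or realistic text beyond
short encounter-reason fields. Passing recovery tests therefore shows the
*mechanics* — matching, exclusion, subsumption, windowing, the
polypharmacy rule, scoring — are correct, not that real-world sensitivity
will equal the configured documentation probability.

Typo noise (single-character edits at `typo_rate`, default 0) exists for
robustness experiments together with an opt-in fuzzy matcher (edit
distance 1, single-token phrases of length ≥4); both are off by default
because the method is exact enumerated terms.

## Full-scale synthetic dictionary

The complete published term list is distributed as journal supplementary
material and is not redistributable here. Scale-dependent analytics are
therefore exercised against `fullscale_synthetic()`, a generated stand-in
whose entry contents are placeholders but whose structure is constrained to
the published marginals: 2987 ICD9/ICD9-CM + 31 LOINC + 3 ATC = 3021
codes, 747 free-text terms (3768 entries), per-factor splits including
housebound (1 code, 14 terms) and social vulnerability (22, 66), capture
categories 24 mostly-codes / 7 mostly-free-text / 4 equal with
polypharmacy rule-based, and a 16-code automatic-mapping delta
(`fullscale_synthetic_split()`) whose merge adds ≈0.5%. All totals the
tests assert are recomputed from the constructed object by
`dictionary_stats`, never hard-coded in the analytics.

## Numerical and procedural choices

- The "approximately equal" capture rule needs a denominator; we use the
  relative difference |c − t| / (c + t) < 0.10, configurable via
  `equal_threshold`.
- Merge percentage is n_added / total codes after merge, to match how an
  addition share is naturally reported.
- Scores are exact rationals k/36 in floating point (k ≤ 36, so exact);
  display is rounded to two decimals.
- Determinism: scoring is pure; generation is driven by one
  `numpy.random.Generator` seeded from the config, and repeated runs are
  byte-identical including CSV serialization.
- Test problem sizes (500–2000 simulated patients, 1000-field matcher
  oracle corpora) were chosen to give 3-standard-error resolution on the
  statistical checks while keeping the suite fast.

## Known limitations

Physician-entered encounter fields only (no multidisciplinary notes); no
negation or context detection; no NLP/concept extraction; no predictive
validation of scores against outcomes (mortality, hospitalization) — the
scores are screening signals pending clinical assessment; the packaged
seed dictionary is a small anchor set, not the full production list.
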