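# efrailty

A case-finding engine for the Canadian-adapted 36-factor **electronic
frailty index (eFI)**, aimed at primary-care EMR data.

Frailty in older adults is quantified here under the cumulative deficit
model: a fixed list of 36 deficits (conditions, symptoms, and social or
functional circumstances — heart failure, falls, housebound, social
vulnerability, ...) is screened for in a patient's record, and the frailty
score is

```
score = n_deficits_present / 36
```

so a patient with 8 documented factors scores 8/36 ≈ 0.22. A factor counts
as present when **any one** dictionary entry for it fires. Because Canadian
primary-care EMRs document the same deficit heterogeneously — an ICD9 or
ICD9-CM billing code from one clinician, a free-text acronym or misspelling
from another — the engine matches a *superset* terminology dictionary per
factor:

- **codes**: ICD9/ICD9-CM diagnoses (one normalized code space), LOINC labs
  definitively diagnostic of a factor, and ATC medication codes explicitly
  indicating one (insulin → diabetes, levothyroxine → thyroid disease,
  levodopa-carbidopa → parkinsonism);
- **semi-structured free-text terms** with word-boundary phrase matching,
  field-level *exclusions* (capture "flutter" for atrial fibrillation, veto
  "ventricular flutter") and *subsumption* ("disability" already captures
  "disability form");
- **polypharmacy**, the one rule-based factor: 5+ distinct medications
  prescribed in the 12 months before the index date.

Every (system, code) pair and every phrase maps to exactly one factor, so
no record can be double-counted across deficits. Input is CPCSSN-style flat
CSV tables (patient, diagnosis, lab, medication); output is a per-patient
score table plus an auditable run report.

The packaged seed dictionary carries documented anchor entries plus
synthetic representative ones (see its `_note`); production use expects a
site's full dictionary via `--dict` (JSON or CSV, schema in
`efrailty.dictionary`).

## Worked example

Generate a synthetic cohort with known ground truth, score it, and check
recovery:

```
$ efi simulate --seed 42 --n-patients 100 --out demo/
wrote 100 patients to demo (781 diagnoses, 22 labs, 271 medications)

$ efi score --patients demo/patient.csv --diagnoses demo/diagnosis.csv \
            --labs demo/lab.csv --meds demo/medication.csv --out scores/
scored 100 eligible patients -> scores/scores.csv

$ head -4 scores/scores.csv
patient_id,n_deficits,score,score_display,category,evidence_codes,evidence_freetext
P00001,5,0.1388888888888889,0.14,,3,1
P00002,5,0.1388888888888889,0.14,,1,4
P00003,5,0.1388888888888889,0.14,,4,1

$ efi evaluate --scores-dir demo/
exact-match rate 1.000; mean sensitivity 1.0; false positives 0
```

Patient `P00001` has 5 of 36 deficits (score 5/36, displayed 0.14), three
found through codes and one through free text (the fifth is the rule-based
polypharmacy factor, which has no match rows). Under perfect documentation
the pipeline recovers every generated deficit vector exactly, with zero
false positives from distractor or exclusion-trap texts.

Dictionary analytics (`efi dict-stats`) report per-factor code/free-text
counts and each factor's capture category: *mostly codes*, *mostly free
text*, or *equal* when the relative difference |c − t| / (c + t) is under
10%.

The same functionality is available as a library:

```python
import efrailty as ef

d = ef.seed_dictionary()
cohort, truth = ef.generate_cohort(ef.SyntheticConfig(n_patients=100, seed=42), d)
table, vectors, report = ef.score_cohort(cohort, d, ef.ObservationWindow())
print(ef.evaluate_recovery(vectors, truth).exact_match_rate)  # 1.0
```

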