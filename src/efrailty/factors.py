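"""The 36 frailty factors of the electronic frailty index (eFI).

The eFI operationalizes the cumulative deficit model of frailty: each factor
is a health deficit (condition, symptom, or circumstance) and a patient's
frailty score is the proportion of the 36 deficits with any supporting
evidence in their EMR.  Factor ids are stable 1-based integers; polypharmacy
is special-cased throughout because its presence is decided by a medication
count rule rather than by dictionary terms.
"""

from __future__ import annotations

from dataclasses import dataclass

N_FACTORS = 36

POLYPHARMACY = "Polypharmacy"

#: Canonical factor labels, in id order (id = index + 1).
FACTOR_NAMES: tuple[str, ...] = (
    "Activity limitation",
    "Anaemia and haematinic deficiency",
    "Arthritis",
    "Atrial fibrillation",
    "Cerebrovascular disease",
    "Chronic kidney disease",
    "Diabetes",
    "Dizziness",
    "Dyspnoea",
    "Falls",
    "Foot problems",
    "Fragility fracture",
    "Hearing impairment",
    "Heart failure",
    "Heart valve disease",
    "Housebound",
    "Hypertension",
    "Hypotension or syncope",
    "Ischaemic heart disease",
    "Memory and cognitive problems",
    "Mobility and transfer problems",
    "Osteoporosis",
    "Parkinsonism and tremor",
    "Peptic ulcer",
    "Peripheral vascular disease",
    POLYPHARMACY,
    "Requirement for care",
    "Respiratory disease",
    "Skin ulcer",
    "Sleep disturbance",
    "Social vulnerability",
    "Thyroid disease",
    "Urinary incontinence",
    "Urinary system disease",
    "Visual impairment",
    "Weight loss",
)

assert len(FACTOR_NAMES) == N_FACTORS
assert len(set(FACTOR_NAMES)) == N_FACTORS

POLYPHARMACY_ID = FACTOR_NAMES.index(POLYPHARMACY) + 1


@dataclass(frozen=True)
class FrailtyFactor:
    """One deficit of the 36-factor eFI.

    ``rule_based`` marks factors whose presence is computed by a rule
    instead of dictionary matching (only polypharmacy).
    """

    id: int
    name: str

    @property
    def rule_based(self) -> bool:
        return self.name == POLYPHARMACY


FACTORS: tuple[FrailtyFactor, ...] = tuple(
    FrailtyFactor(i + 1, name) for i, name in enumerate(FACTOR_NAMES)
)

FACTOR_BY_NAME: dict[str, FrailtyFactor] = {f.name: f for f in FACTORS}
FACTOR_BY_ID: dict[int, FrailtyFactor] = {f.id: f for f in FACTORS}


def factor_id(name: str) -> int:
    """Resolve a canonical factor label to its id; raises KeyError if unknown."""
    return FACTOR_BY_NAME[name].id
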