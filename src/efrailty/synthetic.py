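"""Synthetic CPCSSN-style cohorts with known ground truth.

Real EMR extracts cannot ship with the package, so every pipeline stage is
exercised against generated cohorts whose true deficit vectors are known.
The generator emulates the documentation heterogeneity that motivates the
superset dictionary: the same true deficit may be recorded as a
standardized code by one clinician (diagnosis, lab, or medication row,
depending on the code's system) and as a free-text phrase — full name,
acronym, or misspelling — by another.  It also plants the two failure
modes the matcher must resist:

* **distractors** — irrelevant encounter texts drawn from a vocabulary
  verified disjoint from every dictionary phrase;
* **traps** — texts pairing a dictionary phrase with its exclusion phrase
  (e.g. "ventricular flutter"), which a correct matcher must *not* count.

Polypharmacy truth is generated directly through the medication table:
polypharmacy-true patients receive ≥5 distinct in-window medications from
a filler vocabulary (ATC-like codes disjoint from the dictionary's),
polypharmacy-false patients at most 4.

Everything is reproducible from the seed; two runs with the same config
produce byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dictionary import TerminologyDictionary
from .emr import (
    DEFAULT_WINDOW_END,
    DEFAULT_WINDOW_START,
    EmrCohort,
    ObservationWindow,
)
from .factors import FACTORS, N_FACTORS, POLYPHARMACY_ID
from .matching import _TextIndex
from .scoring import DeficitVector

logger = logging.getLogger(__name__)

#: filler medication codes; 'Z' is not an ATC anatomical group, so these can
#: never collide with real dictionary ATC entries.
_FILLER_ATC = tuple(f"Z{i:02d}AA01" for i in range(1, 21))
_FILLER_DRUGS = tuple(f"fillerdrug{i}" for i in range(1, 21))

_DISTRACTOR_TEXTS = (
    "annual checkup",
    "vaccination visit",
    "travel advice",
    "prescription renewal",
    "lab requisition",
    "telephone consult",
    "wellness review",
    "driver exam",
    "sick note request",
    "routine bloodwork",
)

_TEXT_TEMPLATES = ("{p}", "{p} reviewed", "pt with {p}", "{p} stable today")

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class SyntheticConfig:
    """Study conditions for a generated cohort.

    ``prevalence`` is the per-factor Bernoulli probability of truly having
    each deficit (flat 0.15 by default — a plausible order of magnitude for
    single deficits in a 65+ primary-care population).  ``q_code`` /
    ``q_text`` / ``q_both`` split documented deficits between coded,
    free-text, and dual documentation and must sum to 1.
    ``documentation_prob`` is the chance a true deficit leaves *any* record
    at all; detection sensitivity converges to it.  Noise (``typo_rate``)
    and traps are off by default, matching an exact-term matching method.
    """

    n_patients: int = 500
    seed: int = 0
    prevalence: float | dict[int, float] = 0.15
    q_code: float = 0.45
    q_text: float = 0.35
    q_both: float = 0.20
    documentation_prob: float = 1.0
    typo_rate: float = 0.0
    distractor_rate: float = 2.0
    trap_rate: float = 0.0
    age_min: int = 65
    age_max: int = 95
    window_start: dt.date = DEFAULT_WINDOW_START
    window_end: dt.date = DEFAULT_WINDOW_END

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = [self.q_code, self.q_text, self.q_both, self.documentation_prob,
                 self.typo_rate, self.trap_rate]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.q_code + self.q_text + self.q_both - 1.0) > 1e-9:
            raise ValueError("q_code + q_text + q_both must sum to 1")
        if not (0 < self.age_min <= self.age_max):
            raise ValueError("invalid age bounds")

    def prevalence_of(self, factor_id: int) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence.get(factor_id, 0.0)
        return self.prevalence

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(self.window_start, self.window_end)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort.

    ``deficits`` maps patient id to the sorted list of truly-present factor
    ids; ``events`` records every emitted documentation row (channel, value,
    table) plus distractor and trap rows, so any detection can be traced to
    its cause.
    """

    deficits: dict[str, list[int]]
    events: list[dict] = field(default_factory=list)

    def vector_of(self, patient_id: str) -> list[bool]:
        present = [False] * N_FACTORS
        for fid in self.deficits[patient_id]:
            present[fid - 1] = True
        return present

    def to_json(self) -> str:
        return json.dumps({"deficits": self.deficits, "events": self.events}, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _typo(word: str, rng: np.random.Generator) -> str:
    """One random single-character edit (substitute/delete/insert)."""
    if len(word) < 4:
        return word
    op = rng.integers(0, 3)
    i = int(rng.integers(0, len(word)))
    ch = _ALPHABET[int(rng.integers(0, 26))]
    if op == 0:
        return word[:i] + ch + word[i + 1 :]
    if op == 1:
        return word[:i] + word[i + 1 :]
    return word[:i] + ch + word[i:]


def _random_date(rng: np.random.Generator, window: ObservationWindow) -> dt.date:
    span = (window.end_date - window.start_date).days
    return window.start_date + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _dotted(code: str, rng: np.random.Generator) -> str:
    # clinicians enter "428.0" as often as "4280"; exercise normalization
    if len(code) > 3 and rng.random() < 0.5:
        return code[:3] + "." + code[3:]
    return code


def generate_cohort(
    config: SyntheticConfig, dictionary: TerminologyDictionary
) -> tuple[EmrCohort, SyntheticTruth]:
    """Generate a cohort plus its ground truth from the study conditions.

    For each patient, true deficits are drawn per factor; each documented
    deficit emits evidence through its dictionary entries — a code row in
    the table its system implies, a free-text phrase embedded in a neutral
    encounter template, or both.  Factors with only one entry kind fall
    back to the kind they have.  Raises if polypharmacy can be true but the
    filler medication vocabulary collides with dictionary ATC codes, or if
    ``trap_rate`` > 0 while no dictionary term carries exclusions.
    """
    rng = np.random.default_rng(config.seed)
    window = config.window
    index_date = window.index_date

    dict_atc = {c.code for c in dictionary.codes if c.system == "ATC"}
    if config.prevalence_of(POLYPHARMACY_ID) > 0:
        if not _FILLER_ATC:
            raise ValueError("polypharmacy prevalence > 0 requires a medication vocabulary")
        if dict_atc & set(_FILLER_ATC):
            raise ValueError("filler medication vocabulary collides with dictionary ATC codes")

    text_index = _TextIndex(dictionary)
    for text in _DISTRACTOR_TEXTS:
        if text_index.scan(text, apply_exclusions=False):
            raise ValueError(f"distractor text {text!r} collides with a dictionary phrase")
    trap_terms = [t for t in dictionary.terms if t.exclusions]
    if config.trap_rate > 0 and not trap_terms:
        raise ValueError("trap_rate > 0 but no dictionary term has exclusions")

    patients, diagnoses, labs, medications = [], [], [], []
    deficits: dict[str, list[int]] = {}
    events: list[dict] = []

    def log_event(pid: str, fid: int | None, channel: str, value: str, table: str) -> None:
        events.append(
            {"patient": pid, "factor": fid, "channel": channel, "value": value, "table": table}
        )

    def emit_code(pid: str, fid: int) -> int:
        """Emit one coded row; returns 1 if it was a medication row."""
        entries = dictionary.codes_for(fid)
        entry = entries[int(rng.integers(0, len(entries)))]
        if entry.system in ("ICD9", "ICD9CM"):
            when = _random_date(rng, window)
            diagnoses.append((pid, when, entry.system, _dotted(entry.code, rng), ""))
            log_event(pid, fid, "code", entry.code, "diagnosis")
        elif entry.system == "LOINC":
            labs.append((pid, _random_date(rng, window), entry.code, "", ""))
            log_event(pid, fid, "lab", entry.code, "lab")
        else:  # ATC — prescriptions are dated inside the 12-month polypharmacy
            # lookback so their contribution to the medication tally is known
            when = index_date - dt.timedelta(days=int(rng.integers(0, 300)))
            medications.append((pid, when, entry.code, ""))
            log_event(pid, fid, "medication", entry.code, "medication")
            return 1
        return 0

    def emit_text(pid: str, fid: int) -> None:
        terms = dictionary.terms_for(fid)
        term = terms[int(rng.integers(0, len(terms)))]
        phrase = term.all_phrases[int(rng.integers(0, len(term.all_phrases)))]
        if config.typo_rate > 0 and rng.random() < config.typo_rate:
            words = phrase.split()
            j = int(rng.integers(0, len(words)))
            words[j] = _typo(words[j], rng)
            phrase = " ".join(words)
        template = _TEXT_TEMPLATES[int(rng.integers(0, len(_TEXT_TEMPLATES)))]
        diagnoses.append((pid, _random_date(rng, window), "", "", template.format(p=phrase)))
        log_event(pid, fid, "freetext", phrase, "diagnosis")

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        age_years = int(rng.integers(config.age_min, config.age_max + 1))
        birth = index_date.replace(year=index_date.year - age_years)
        birth -= dt.timedelta(days=int(rng.integers(0, 300)))
        sex = "F" if rng.random() < 0.55 else "M"
        patients.append((pid, birth, sex))

        true_factors = [
            f.id for f in FACTORS if rng.random() < config.prevalence_of(f.id)
        ]
        deficits[pid] = true_factors

        n_dict_meds = 0
        for fid in true_factors:
            if fid == POLYPHARMACY_ID:
                continue
            if rng.random() >= config.documentation_prob:
                continue  # truly present but never charted
            has_codes = bool(dictionary.codes_for(fid))
            has_terms = bool(dictionary.terms_for(fid))
            u = rng.random()
            mode = "code" if u < config.q_code else ("text" if u < config.q_code + config.q_text else "both")
            if mode in ("code", "both") and has_codes:
                n_dict_meds += emit_code(pid, fid)
            elif mode == "code" and has_terms:
                emit_text(pid, fid)
            if mode in ("text", "both") and has_terms:
                emit_text(pid, fid)
            elif mode == "text" and has_codes:
                n_dict_meds += emit_code(pid, fid)

        # plan filler medications so the in-window distinct count lands on the
        # intended side of 5, including any dictionary medications just emitted
        poly_true = POLYPHARMACY_ID in true_factors
        documented_poly = poly_true and rng.random() < config.documentation_prob
        if documented_poly:
            n_fillers = max(0, 5 + int(rng.integers(0, 4)) - n_dict_meds)
        else:
            n_fillers = int(rng.integers(0, max(1, 5 - n_dict_meds)))
        med_idx = rng.permutation(len(_FILLER_ATC))[:n_fillers]
        for k in med_idx:
            when = index_date - dt.timedelta(days=int(rng.integers(0, 300)))
            medications.append((pid, when, _FILLER_ATC[k], _FILLER_DRUGS[k]))
            log_event(
                pid,
                POLYPHARMACY_ID if poly_true else None,
                "filler_med",
                _FILLER_ATC[k],
                "medication",
            )

        for _ in range(rng.poisson(config.distractor_rate)):
            text = _DISTRACTOR_TEXTS[int(rng.integers(0, len(_DISTRACTOR_TEXTS)))]
            diagnoses.append((pid, _random_date(rng, window), "", "", text))
            log_event(pid, None, "distractor", text, "diagnosis")

        if trap_terms and rng.random() < config.trap_rate:
            candidates = [t for t in trap_terms if t.factor_id not in true_factors]
            if candidates:
                term = candidates[int(rng.integers(0, len(candidates)))]
                excl = term.exclusions[int(rng.integers(0, len(term.exclusions)))]
                trap_text = f"{excl} {term.phrase}"
                diagnoses.append((pid, _random_date(rng, window), "", "", trap_text))
                log_event(pid, term.factor_id, "trap", trap_text, "diagnosis")

    cohort = EmrCohort(
        patients=pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex"]),
        diagnoses=pd.DataFrame(
            diagnoses, columns=["patient_id", "encounter_date", "code_system", "code", "text"]
        ),
        labs=pd.DataFrame(labs, columns=["patient_id", "date", "loinc_code", "value", "unit"]),
        medications=pd.DataFrame(
            medications, columns=["patient_id", "prescribed_date", "atc_code", "drug_name"]
        ),
    )
    truth = SyntheticTruth(deficits=deficits, events=events)
    logger.info(
        "generated %d patients: %d diagnoses, %d labs, %d medications",
        config.n_patients, len(cohort.diagnoses), len(cohort.labs), len(cohort.medications),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryReport:
    """How faithfully scoring recovered the generated ground truth."""

    n_patients: int
    exact_match_rate: float
    sensitivity_by_factor: dict[int, float | None]
    mean_sensitivity: float | None
    n_true_deficits: int
    n_detected_true: int
    n_false_positives: int
    false_positive_rate: float

    def to_json(self) -> str:
        payload = asdict(self)
        payload["sensitivity_by_factor"] = {
            str(k): v for k, v in self.sensitivity_by_factor.items()
        }
        return json.dumps(payload, indent=2)


def evaluate_recovery(
    vectors: list[DeficitVector], truth: SyntheticTruth
) -> RecoveryReport:
    """Compare recovered deficit vectors against the generated truth.

    Per-factor sensitivity is detected-true / true (None where a factor was
    never true); the false-positive rate is detections of factors that are
    not true, over all patient-factor negatives.  Patient ids must match
    the truth exactly.
    """
    ids_scored = {v.patient_id for v in vectors}
    if ids_scored != set(truth.deficits):
        raise ValueError(
            f"patient ids differ between scores and truth "
            f"(only-scored={sorted(ids_scored - set(truth.deficits))[:3]}, "
            f"only-truth={sorted(set(truth.deficits) - ids_scored)[:3]})"
        )
    tp = {f.id: 0 for f in FACTORS}
    pos = {f.id: 0 for f in FACTORS}
    n_fp = 0
    n_neg = 0
    n_exact = 0
    for v in vectors:
        true_vec = truth.vector_of(v.patient_id)
        if true_vec == v.present:
            n_exact += 1
        for fid in range(1, N_FACTORS + 1):
            t, d = true_vec[fid - 1], v.present[fid - 1]
            if t:
                pos[fid] += 1
                tp[fid] += d
            else:
                n_neg += 1
                n_fp += d
    sens = {fid: (tp[fid] / pos[fid] if pos[fid] else None) for fid in pos}
    observed = [s for s in sens.values() if s is not None]
    return RecoveryReport(
        n_patients=len(vectors),
        exact_match_rate=n_exact / len(vectors) if vectors else 0.0,
        sensitivity_by_factor=sens,
        mean_sensitivity=sum(observed) / len(observed) if observed else None,
        n_true_deficits=sum(pos.values()),
        n_detected_true=sum(tp.values()),
        n_false_positives=n_fp,
        false_positive_rate=n_fp / n_neg if n_neg else 0.0,
    )
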