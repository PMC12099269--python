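"""Deficit vectors and frailty scores (cumulative deficit model).

A patient's deficit vector has one boolean slot per eFI factor: a slot is
present when at least one dictionary match supports it — any single code or
free-text hit suffices.  Polypharmacy is the exception: its slot is set by
a medication-count rule (5 or more distinct medications prescribed in the
12 months before the index date), never by dictionary matches.

The frailty score is n_deficits / 36, exactly quantized to k/36; e.g. a
patient with 8 documented factors scores 8/36 ≈ 0.22.  Severity banding is
not part of the index itself — cut points are configurable, with defaults
following the UK convention (0.12 / 0.24 / 0.36 for mild / moderate /
severe) and reported only when requested.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._normalize import normalize_text
from .dictionary import TerminologyDictionary
from .emr import DATE_COLUMN, EmrCohort, ObservationWindow, eligible_patients, window_records
from .factors import FACTOR_BY_ID, N_FACTORS, POLYPHARMACY_ID
from .matching import MatchResult, detect_factor_evidence

logger = logging.getLogger(__name__)

POLYPHARMACY_MIN_MEDS = 5
DEFAULT_CUTPOINTS = (0.12, 0.24, 0.36)
DEFAULT_CATEGORY_LABELS = ("fit", "mild", "moderate", "severe")


@dataclass
class PolypharmacyResult:
    """Outcome of the distinct-medication count rule for one patient."""

    flag: bool
    count: int
    n_undated: int = 0


def polypharmacy_flag(
    medications: pd.DataFrame,
    as_of: dt.date,
    *,
    min_meds: int = POLYPHARMACY_MIN_MEDS,
    distinct: bool = True,
) -> PolypharmacyResult:
    """Apply the polypharmacy rule to one patient's medication records.

    Counts *distinct* medications (by ATC code, falling back to normalized
    drug name) prescribed in the half-open year (as_of − 12 months, as_of];
    the flag is count ≥ ``min_meds`` (default 5).  ``distinct=False``
    switches to counting prescription events instead.  Records without a
    parseable date are excluded from the count and logged.
    """
    lower = as_of - pd.DateOffset(months=12)
    lower = lower.date() if hasattr(lower, "date") else lower
    identities: list[str] = []
    n_undated = 0
    for row in medications.itertuples(index=False):
        when = row.prescribed_date
        if not isinstance(when, dt.date):
            n_undated += 1
            continue
        if not (lower < when <= as_of):
            continue
        ident = normalize_text(row.atc_code) or normalize_text(row.drug_name)
        if ident:
            identities.append(ident)
    if n_undated:
        logger.warning("polypharmacy: %d undated medication rows excluded", n_undated)
    count = len(set(identities)) if distinct else len(identities)
    return PolypharmacyResult(flag=count >= min_meds, count=count, n_undated=n_undated)


@dataclass
class DeficitVector:
    """Per-patient 36-slot presence vector with per-factor evidence counts."""

    patient_id: str
    present: list[bool]
    evidence_counts: list[int]

    def __post_init__(self) -> None:
        assert len(self.present) == N_FACTORS and len(self.evidence_counts) == N_FACTORS

    @property
    def n_deficits(self) -> int:
        return sum(self.present)

    def factors_present(self) -> list[int]:
        return [i + 1 for i, p in enumerate(self.present) if p]


@dataclass(frozen=True)
class FrailtyScore:
    patient_id: str
    n_deficits: int
    score: float
    category: str | None = None

    @property
    def display(self) -> str:
        """Two-decimal display form of the score."""
        return f"{self.score:.2f}"


def build_deficit_vector(
    matches: Iterable[MatchResult],
    poly: PolypharmacyResult,
    patient_id: str,
) -> DeficitVector:
    """Collapse one patient's matches to the 36-slot presence vector.

    A slot is present iff it has ≥1 supporting match; the polypharmacy slot
    comes only from the rule result (dictionary matches cannot set it — a
    valid dictionary carries no polypharmacy entries, and a match claiming
    that factor indicates an engine/dictionary inconsistency).
    """
    present = [False] * N_FACTORS
    counts = [0] * N_FACTORS
    for m in matches:
        if m.patient_id != patient_id:
            raise ValueError(f"match for {m.patient_id!r} passed to vector of {patient_id!r}")
        if m.factor_id not in FACTOR_BY_ID:
            raise ValueError(f"match carries invalid factor_id {m.factor_id}")
        if m.factor_id == POLYPHARMACY_ID:
            raise ValueError("dictionary match claims the rule-based polypharmacy factor")
        counts[m.factor_id - 1] += 1
        present[m.factor_id - 1] = True
    present[POLYPHARMACY_ID - 1] = poly.flag
    counts[POLYPHARMACY_ID - 1] = poly.count if poly.flag else 0
    return DeficitVector(patient_id=patient_id, present=present, evidence_counts=counts)


def frailty_score(vector: DeficitVector, category_config: "CategoryConfig | None" = None) -> FrailtyScore:
    """Score = n_deficits / 36, exactly; optional severity label."""
    n = vector.n_deficits
    score = n / N_FACTORS
    category = category_config.label(score) if category_config else None
    return FrailtyScore(patient_id=vector.patient_id, n_deficits=n, score=score, category=category)


@dataclass(frozen=True)
class CategoryConfig:
    """Severity banding by half-open intervals over the score.

    A score exactly at a cut point belongs to the lower band.  Labels must
    number one more than cut points; cut points strictly increase in (0,1).
    """

    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS
    labels: Sequence[str] = DEFAULT_CATEGORY_LABELS

    def __post_init__(self) -> None:
        cps = list(self.cutpoints)
        if any(not (0 < c < 1) for c in cps) or any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError(f"cutpoints must be strictly increasing within (0,1): {cps}")
        if len(self.labels) != len(cps) + 1:
            raise ValueError("need exactly one more label than cutpoints")

    def label(self, score: float) -> str:
        for i, cp in enumerate(self.cutpoints):
            if score <= cp:
                return self.labels[i]
        return self.labels[-1]


def categorize_score(score: FrailtyScore, config: CategoryConfig | None = None) -> str:
    """Severity label for a score under the given (or default) cut points."""
    return (config or CategoryConfig()).label(score.score)


# ---------------------------------------------------------------------------
# cohort-level scoring


@dataclass
class RunReport:
    """Auditable summary of one scoring run."""

    dictionary_version: str
    window_start: str
    window_end: str
    index_date: str
    n_patients: int
    n_eligible: int
    n_matches: int
    factor_prevalence: dict[str, float]
    evidence_by_kind: dict[str, int]
    rejections: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def score_cohort(
    cohort: EmrCohort,
    dictionary: TerminologyDictionary,
    window: ObservationWindow,
    *,
    category_config: CategoryConfig | None = None,
    min_age: int = 65,
    apply_exclusions: bool = True,
    fuzzy: bool = False,
) -> tuple[pd.DataFrame, list[DeficitVector], RunReport]:
    """Score every eligible patient in the cohort.

    Returns the score table (one row per eligible patient, sorted by id),
    the underlying deficit vectors, and a run report with counts at every
    stage.  Deterministic: identical inputs give identical output tables.
    """
    eligible = eligible_patients(cohort, window, min_age=min_age)
    warnings: list[str] = []
    if not eligible:
        warnings.append("no eligible patients")
        logger.warning("score_cohort: empty eligible set")
    matches = detect_factor_evidence(
        cohort,
        dictionary,
        window,
        eligible=eligible,
        apply_exclusions=apply_exclusions,
        fuzzy=fuzzy,
    )
    by_patient: dict[str, list[MatchResult]] = defaultdict(list)
    for m in matches:
        by_patient[m.patient_id].append(m)

    meds = window_records(cohort.medications, DATE_COLUMN["medication"], window)
    rows = []
    vectors: list[DeficitVector] = []
    for pid in sorted(eligible):
        poly = polypharmacy_flag(meds.loc[meds["patient_id"] == pid], window.index_date)
        vector = build_deficit_vector(by_patient.get(pid, []), poly, pid)
        vectors.append(vector)
        fs = frailty_score(vector, category_config)
        patient_matches = by_patient.get(pid, [])
        rows.append(
            {
                "patient_id": pid,
                "n_deficits": fs.n_deficits,
                "score": fs.score,
                "score_display": fs.display,
                "category": fs.category or "",
                "evidence_codes": sum(
                    1 for m in patient_matches if m.entry_kind in ("code", "lab", "medication")
                ),
                "evidence_freetext": sum(
                    1 for m in patient_matches if m.entry_kind == "freetext"
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "n_deficits",
            "score",
            "score_display",
            "category",
            "evidence_codes",
            "evidence_freetext",
        ],
    )

    n_eligible = len(eligible)
    prevalence = {
        FACTOR_BY_ID[fid].name: (
            sum(v.present[fid - 1] for v in vectors) / n_eligible if n_eligible else 0.0
        )
        for fid in range(1, N_FACTORS + 1)
    }
    by_kind: dict[str, int] = defaultdict(int)
    for m in matches:
        by_kind[m.entry_kind] += 1
    report = RunReport(
        dictionary_version=dictionary.version,
        window_start=window.start_date.isoformat(),
        window_end=window.end_date.isoformat(),
        index_date=window.index_date.isoformat(),
        n_patients=len(cohort.patients),
        n_eligible=n_eligible,
        n_matches=len(matches),
        factor_prevalence=prevalence,
        evidence_by_kind=dict(by_kind),
        rejections=dict(cohort.rejections),
        warnings=warnings,
    )
    logger.info(
        "scored %d eligible of %d patients, %d matches", n_eligible, len(cohort.patients), len(matches)
    )
    return table, vectors, report
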