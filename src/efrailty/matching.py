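"""Detection of frailty-factor evidence in EMR records.

Two detection routes feed the same result type:

* **code matching** — exact equality of normalized codes, per system
  family.  ICD9 and ICD9-CM share one normalized code space (every ICD9
  code exists within ICD9-CM), so a dictionary entry in either system
  matches a record coded in either.  LOINC entries match lab rows, ATC
  entries match medication rows.  No prefix expansion: the dictionary is
  already the maximally inclusive superset.
* **free-text matching** — a dictionary phrase fires when it occurs as a
  contiguous, token-aligned phrase in the normalized text ("flutter" does
  not fire inside "butterflutter"), *unless* any of the entry's exclusion
  phrases occurs anywhere in the same text field (capture "flutter", veto
  "ventricular flutter").  When a parent term and a phrase it subsumes both
  occur ("disability" / "disability form"), exactly one result is emitted
  for that factor.

Negation ("no falls") is deliberately not handled: the method is term
presence.  Fuzzy matching (edit distance 1 on single-token phrases) exists
only as an opt-in for robustness experiments and is off by default.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from ._normalize import normalize_code, normalize_text, tokens_of
from .dictionary import CodeEntry, FreeTextTerm, TerminologyDictionary
from .emr import DATE_COLUMN, EmrCohort, ObservationWindow, window_records

__all__ = [
    "MatchResult",
    "normalize_code",
    "normalize_text",
    "match_codes",
    "match_freetext",
    "detect_factor_evidence",
]

logger = logging.getLogger(__name__)

#: evidence channel labels, by source table
_TABLE_KIND = {"diagnosis": "code", "lab": "lab", "medication": "medication"}
_TABLE_SYSTEM = {"diagnosis": "ICD9", "lab": "LOINC", "medication": "ATC"}


@dataclass(frozen=True)
class MatchResult:
    """One record-level hit linking an EMR row to a frailty factor."""

    patient_id: str
    factor_id: int
    entry_kind: str  # code | freetext | medication | lab
    matched_value: str
    record_ref: str
    date: dt.date | None


def _within_one_edit(a: str, b: str) -> bool:
    """True iff Levenshtein distance between a and b is at most 1."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la > lb:
        a, b, la, lb = b, a, lb, la
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    if la == lb:  # substitution
        return a[i + 1 :] == b[i + 1 :]
    return a[i:] == b[i + 1 :]  # insertion into the shorter


class _TextIndex:
    """Pre-tokenized dictionary phrases for repeated field scans."""

    def __init__(self, dictionary: TerminologyDictionary):
        # (entry, parent-first phrase token tuples, exclusion token tuples)
        self.entries: list[tuple[FreeTextTerm, list[tuple[str, ...]], list[tuple[str, ...]]]] = [
            (
                term,
                [tuple(tokens_of(p)) for p in term.all_phrases],
                [tuple(tokens_of(x)) for x in term.exclusions],
            )
            for term in dictionary.terms
        ]

    def scan(
        self, text: str, *, apply_exclusions: bool = True, fuzzy: bool = False
    ) -> list[tuple[int, str]]:
        """(factor_id, matched phrase) per firing factor, one hit per factor."""
        tokens = tokens_of(normalize_text(text))
        if not tokens:
            return []
        hits: dict[int, str] = {}
        for term, phrases, exclusions in self.entries:
            if term.factor_id in hits:
                continue
            if apply_exclusions and any(
                _contains(tokens, excl, fuzzy=False) for excl in exclusions
            ):
                continue
            for phrase in phrases:
                if _contains(tokens, phrase, fuzzy=fuzzy):
                    hits[term.factor_id] = " ".join(phrase)
                    break
        return sorted(hits.items())


def _contains(tokens: list[str], phrase: tuple[str, ...], *, fuzzy: bool) -> bool:
    """Contiguous token-aligned occurrence of ``phrase`` in ``tokens``."""
    n, m = len(tokens), len(phrase)
    if m == 0 or m > n:
        return False
    if fuzzy and m == 1 and len(phrase[0]) >= 4:
        return any(_within_one_edit(tok, phrase[0]) for tok in tokens)
    for i in range(n - m + 1):
        if tokens[i : i + m] == list(phrase):
            return True
    return False


def match_freetext(
    text: str,
    dictionary: TerminologyDictionary,
    *,
    apply_exclusions: bool = True,
    fuzzy: bool = False,
    patient_id: str = "",
    record_ref: str = "",
    date: dt.date | None = None,
) -> list[MatchResult]:
    """Match one free-text field against every dictionary term.

    ``apply_exclusions=False`` disables the veto logic; it exists so tests
    can demonstrate that exclusions are load-bearing, and must stay on in
    production use.
    """
    index = _TextIndex(dictionary)
    return [
        MatchResult(patient_id, fid, "freetext", phrase, record_ref, date)
        for fid, phrase in index.scan(text, apply_exclusions=apply_exclusions, fuzzy=fuzzy)
    ]


def match_codes(
    records: pd.DataFrame,
    table: str,
    dictionary: TerminologyDictionary,
) -> Iterator[MatchResult]:
    """Yield code matches for one record table (diagnosis, lab, medication).

    A record matches when its normalized code equals a dictionary code of
    the table's system family; unknown codes simply produce no match.  A
    LOINC entry carrying a numeric threshold only fires when the lab value
    parses and satisfies it; entries without thresholds fire on presence.
    One result per (record, factor).
    """
    lookup = dictionary.code_lookup()
    kind = _TABLE_KIND[table]
    system = _TABLE_SYSTEM[table]
    code_col = {"diagnosis": "code", "lab": "loinc_code", "medication": "atc_code"}[table]
    date_col = DATE_COLUMN[table]
    for idx, row in records.iterrows():
        code = normalize_code(row[code_col])
        if not code:
            continue
        entry = lookup.get((system, code))
        if entry is None:
            continue
        if entry.threshold_direction is not None and table == "lab":
            if not _passes_threshold(row.get("value", ""), entry):
                continue
        yield MatchResult(
            patient_id=row["patient_id"],
            factor_id=entry.factor_id,
            entry_kind=kind,
            matched_value=code,
            record_ref=f"{table}:{idx}",
            date=row[date_col],
        )


def _passes_threshold(raw_value: str, entry: CodeEntry) -> bool:
    try:
        value = float(raw_value)
    except (TypeError, ValueError):
        return False
    if entry.threshold_direction == ">":
        return value > entry.threshold_value
    return value < entry.threshold_value


def detect_factor_evidence(
    cohort: EmrCohort,
    dictionary: TerminologyDictionary,
    window: ObservationWindow,
    *,
    eligible: Iterable[str] | None = None,
    apply_exclusions: bool = True,
    fuzzy: bool = False,
) -> list[MatchResult]:
    """All factor evidence for a cohort within the observation window.

    Union of code matches over the diagnosis/lab/medication tables and
    free-text matches over the diagnosis text field, restricted to the
    eligible patients (when given) and to in-window records, deduplicated
    at (patient, factor, record) granularity.
    """
    eligible_set = set(eligible) if eligible is not None else None
    results: list[MatchResult] = []

    def keep(patient_id: str) -> bool:
        return eligible_set is None or patient_id in eligible_set

    for table in ("diagnosis", "lab", "medication"):
        df = window_records(cohort.table(table), DATE_COLUMN[table], window)
        results.extend(r for r in match_codes(df, table, dictionary) if keep(r.patient_id))

    index = _TextIndex(dictionary)
    diagnoses = window_records(cohort.diagnoses, DATE_COLUMN["diagnosis"], window)
    for idx, row in diagnoses.iterrows():
        if not row["text"] or not keep(row["patient_id"]):
            continue
        for fid, phrase in index.scan(
            row["text"], apply_exclusions=apply_exclusions, fuzzy=fuzzy
        ):
            results.append(
                MatchResult(
                    patient_id=row["patient_id"],
                    factor_id=fid,
                    entry_kind="freetext",
                    matched_value=phrase,
                    record_ref=f"diagnosis:{idx}",
                    date=row["encounter_date"],
                )
            )

    deduped: dict[tuple[str, int, str], MatchResult] = {}
    for r in results:
        deduped.setdefault((r.patient_id, r.factor_id, r.record_ref), r)
    out = sorted(
        deduped.values(), key=lambda r: (r.patient_id, r.factor_id, r.record_ref, r.entry_kind)
    )
    logger.info("evidence detection: %d raw hits, %d after dedup", len(results), len(out))
    return out


def matches_to_frame(matches: Iterable[MatchResult]) -> pd.DataFrame:
    """Audit table of matches (patient_id,factor,entry_kind,matched_value,record_ref,date)."""
    from .factors import FACTOR_BY_ID

    rows = [
        {
            "patient_id": m.patient_id,
            "factor": FACTOR_BY_ID[m.factor_id].name,
            "entry_kind": m.entry_kind,
            "matched_value": m.matched_value,
            "record_ref": m.record_ref,
            "date": m.date.isoformat() if m.date else "",
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "factor", "entry_kind", "matched_value", "record_ref", "date"]
    )
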