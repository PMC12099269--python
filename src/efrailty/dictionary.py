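"""Terminology dictionary for the 36-factor eFI.

The dictionary is the case-finding engine's knowledge base: for every
frailty factor, a *superset* of standardized codes (ICD9 / ICD9-CM
diagnoses, LOINC labs, ATC medications) and semi-structured free-text
phrases under which clinicians document that factor.  Maximal inclusivity
is the point — the same deficit may be billed as a code by one clinician
and typed as an acronym or misspelling by another — and the presence rule
downstream is "any one entry fires ⇒ the factor is present".

Two structural rules keep the score honest:

* a (system, code) pair belongs to exactly one factor, so no record can be
  double-counted across deficits; the same constraint is applied to
  free-text phrases;
* polypharmacy carries no dictionary entries at all — it is decided by a
  medication-count rule at scoring time.

Free-text entries support two refinements observed in real charting:
``exclusions`` (phrases whose presence anywhere in the same text field
vetoes the match — capture "flutter" but not "ventricular flutter") and
``subsumes`` (longer phrases counted under a parent term — "disability"
already captures "disability form").
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .factors import (
    FACTORS,
    FACTOR_BY_ID,
    FACTOR_BY_NAME,
    N_FACTORS,
    POLYPHARMACY_ID,
    FrailtyFactor,
)
from ._normalize import normalize_code, normalize_text

CODE_SYSTEMS = frozenset({"ICD9", "ICD9CM", "LOINC", "ATC"})
SOURCES = frozenset({"manual", "automatic"})


@dataclass(frozen=True)
class CodeEntry:
    """One standardized code mapped to one frailty factor.

    ``threshold_direction``/``threshold_value`` optionally restrict a LOINC
    lab entry to abnormal results (direction ``">"`` or ``"<"`` against the
    numeric result); by default the mere presence of the coded result
    counts as evidence.
    """

    system: str
    code: str
    factor_id: int
    source: str = "manual"
    threshold_direction: str | None = None
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        if self.system not in CODE_SYSTEMS:
            raise ValueError(f"unknown code system {self.system!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def key(self) -> tuple[str, str]:
        # ICD9 is a subset of ICD9-CM; both live in one normalized code space
        # so a record coded either way matches either entry.
        system = "ICD9" if self.system == "ICD9CM" else self.system
        return (system, self.code)


@dataclass(frozen=True)
class FreeTextTerm:
    """One free-text phrase mapped to one frailty factor."""

    phrase: str
    factor_id: int
    exclusions: tuple[str, ...] = ()
    subsumes: tuple[str, ...] = ()

    @property
    def all_phrases(self) -> tuple[str, ...]:
        """The parent phrase plus every subsumed phrase (all can fire)."""
        return (self.phrase, *self.subsumes)


@dataclass
class TerminologyDictionary:
    """The 36-factor superset of code entries and free-text terms."""

    codes: list[CodeEntry] = field(default_factory=list)
    terms: list[FreeTextTerm] = field(default_factory=list)
    version: str = "unversioned"
    factors: tuple[FrailtyFactor, ...] = FACTORS

    def codes_for(self, factor_id: int) -> list[CodeEntry]:
        return [c for c in self.codes if c.factor_id == factor_id]

    def terms_for(self, factor_id: int) -> list[FreeTextTerm]:
        return [t for t in self.terms if t.factor_id == factor_id]

    def code_lookup(self) -> dict[tuple[str, str], CodeEntry]:
        """(system-family, normalized code) -> entry; assumes validity."""
        return {c.key: c for c in self.codes}


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class MergeDelta:
    """Outcome of folding a second code source into the manual dictionary."""

    n_added: int = 0
    n_skipped_duplicate: int = 0
    n_skipped_excluded: int = 0
    total_after: int = 0

    @property
    def percent_added(self) -> float:
        return 100.0 * self.n_added / self.total_after if self.total_after else 0.0

    def to_json(self) -> str:
        payload = asdict(self)
        payload["percent_added"] = self.percent_added
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# validation


def validate_dictionary(dictionary: TerminologyDictionary) -> ValidationReport:
    """Check the structural invariants; the dictionary is valid iff no errors.

    Errors: a code or phrase mapped under more than one factor, empty
    phrases/codes, an exclusion equal to its own phrase, a phrase that is
    simultaneously a parent entry of one factor and subsumed under another,
    any entry attached to the rule-based polypharmacy factor.  A factor with
    no entries at all is only a warning (it can still be scored as absent).
    """
    report = ValidationReport()

    by_code: dict[tuple[str, str], list[CodeEntry]] = defaultdict(list)
    for entry in dictionary.codes:
        if not entry.code:
            report.errors.append(f"empty code under factor {entry.factor_id}")
            continue
        if entry.factor_id not in FACTOR_BY_ID:
            report.errors.append(f"unknown factor id {entry.factor_id} for code {entry.code}")
            continue
        by_code[entry.key].append(entry)
    for key, entries in by_code.items():
        factors = sorted({e.factor_id for e in entries})
        if len(factors) > 1:
            names = ", ".join(FACTOR_BY_ID[f].name for f in factors)
            report.errors.append(
                f"code {key[1]} ({key[0]}) mapped under multiple factors: {names}"
            )

    by_phrase: dict[str, set[int]] = defaultdict(set)
    subsumed_owner: dict[str, int] = {}
    for term in dictionary.terms:
        if not term.phrase:
            report.errors.append(f"empty phrase under factor {term.factor_id}")
            continue
        if term.factor_id not in FACTOR_BY_ID:
            report.errors.append(f"unknown factor id {term.factor_id} for phrase {term.phrase!r}")
            continue
        by_phrase[term.phrase].add(term.factor_id)
        for excl in term.exclusions:
            if not excl:
                report.errors.append(f"empty exclusion on phrase {term.phrase!r}")
            elif excl == term.phrase:
                report.errors.append(
                    f"exclusion equal to its own phrase: {term.phrase!r}"
                )
        for sub in term.subsumes:
            subsumed_owner[sub] = term.factor_id
    for phrase, factor_ids in by_phrase.items():
        if len(factor_ids) > 1:
            names = ", ".join(FACTOR_BY_ID[f].name for f in sorted(factor_ids))
            report.errors.append(f"phrase {phrase!r} mapped under multiple factors: {names}")
    for phrase, owner in subsumed_owner.items():
        for other in by_phrase.get(phrase, set()):
            if other != owner:
                report.errors.append(
                    f"phrase {phrase!r} is an entry of factor {other} but subsumed "
                    f"under factor {owner}"
                )

    for factor in dictionary.factors:
        n = len(dictionary.codes_for(factor.id)) + len(dictionary.terms_for(factor.id))
        if factor.rule_based:
            if n:
                report.errors.append(
                    f"{factor.name} is rule-based and must carry no dictionary entries"
                )
        elif n == 0:
            report.warnings.append(f"factor {factor.name!r} has no entries")

    return report


# ---------------------------------------------------------------------------
# loading / saving

_CSV_COLUMNS = ["factor", "kind", "system", "value", "exclusions", "subsumes", "source"]


class DictionaryError(ValueError):
    """Raised when a dictionary file cannot be loaded as a valid dictionary."""


def _entry_from_record(rec: dict) -> CodeEntry | FreeTextTerm:
    factor_name = rec.get("factor", "")
    if factor_name not in FACTOR_BY_NAME:
        raise DictionaryError(f"unknown factor name {factor_name!r}")
    fid = FACTOR_BY_NAME[factor_name].id
    kind = rec.get("kind", "")
    if kind == "code":
        code = normalize_code(rec.get("value", ""))
        if not code:
            raise DictionaryError(f"empty code for factor {factor_name!r}")
        system = (rec.get("system") or "").upper()
        thr = rec.get("threshold") or None
        direction = value = None
        if thr:
            direction, value = thr["direction"], float(thr["value"])
        return CodeEntry(
            system=system,
            code=code,
            factor_id=fid,
            source=rec.get("source") or "manual",
            threshold_direction=direction,
            threshold_value=value,
        )
    if kind == "term":
        phrase = normalize_text(rec.get("value", ""))
        if not phrase:
            raise DictionaryError(f"empty phrase for factor {factor_name!r}")
        exclusions = tuple(
            p for p in (normalize_text(x) for x in rec.get("exclusions") or []) if p
        )
        subsumes = tuple(
            p for p in (normalize_text(x) for x in rec.get("subsumes") or []) if p
        )
        return FreeTextTerm(phrase=phrase, factor_id=fid, exclusions=exclusions, subsumes=subsumes)
    raise DictionaryError(f"unknown entry kind {kind!r} (expected 'code' or 'term')")


def _build(records: Iterable[dict], version: str) -> TerminologyDictionary:
    codes: list[CodeEntry] = []
    terms: list[FreeTextTerm] = []
    for rec in records:
        entry = _entry_from_record(rec)
        if isinstance(entry, CodeEntry):
            codes.append(entry)
        else:
            terms.append(entry)
    dictionary = TerminologyDictionary(codes=codes, terms=terms, version=version)
    report = validate_dictionary(dictionary)
    if report.errors:
        raise DictionaryError("invalid dictionary:\n" + "\n".join(report.errors))
    return dictionary


def load_dictionary(path: str | Path) -> TerminologyDictionary:
    """Load and validate a dictionary from a JSON or CSV file.

    JSON layout: ``{"version": str, "entries": [{factor, kind, system,
    value, exclusions, subsumes, source}, ...]}``.  The CSV dialect uses the
    same fields as columns, with ``exclusions``/``subsumes`` pipe-delimited.
    All codes and phrases are normalized on load; validation failures raise
    :class:`DictionaryError` listing every offender.
    """
    path = Path(path)
    if not path.exists():
        raise DictionaryError(f"dictionary file not found: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if not isinstance(payload, dict) or "entries" not in payload:
            raise DictionaryError(f"{path}: expected an object with an 'entries' list")
        return _build(payload["entries"], str(payload.get("version", path.stem)))
    # CSV dialect
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _CSV_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise DictionaryError(f"{path}: missing columns {missing}")
        records = []
        for row in reader:
            rec = dict(row)
            rec["exclusions"] = [x for x in (row.get("exclusions") or "").split("|") if x]
            rec["subsumes"] = [x for x in (row.get("subsumes") or "").split("|") if x]
            records.append(rec)
    return _build(records, path.stem)


def save_dictionary(dictionary: TerminologyDictionary, path: str | Path) -> None:
    """Write a dictionary back out as JSON (the canonical interchange form)."""
    entries: list[dict] = []
    for c in dictionary.codes:
        rec: dict = {
            "factor": FACTOR_BY_ID[c.factor_id].name,
            "kind": "code",
            "system": c.system,
            "value": c.code,
            "source": c.source,
        }
        if c.threshold_direction is not None:
            rec["threshold"] = {
                "direction": c.threshold_direction,
                "value": c.threshold_value,
            }
        entries.append(rec)
    for t in dictionary.terms:
        entries.append(
            {
                "factor": FACTOR_BY_ID[t.factor_id].name,
                "kind": "term",
                "value": t.phrase,
                "exclusions": list(t.exclusions),
                "subsumes": list(t.subsumes),
            }
        )
    Path(path).write_text(
        json.dumps({"version": dictionary.version, "entries": entries}, indent=1)
    )


def seed_dictionary() -> TerminologyDictionary:
    """The packaged seed dictionary (see data/seed_dictionary_synthetic.json)."""
    ref = resources.files("efrailty").joinpath("data/seed_dictionary_synthetic.json")
    payload = json.loads(ref.read_text())
    return _build(payload["entries"], str(payload.get("version", "seed")))


# ---------------------------------------------------------------------------
# merging a second code source


def merge_term_sources(
    base: TerminologyDictionary,
    additions: Sequence[CodeEntry],
    excluded: Iterable[tuple[str, str]] = (),
) -> tuple[TerminologyDictionary, MergeDelta]:
    """Fold automatically-mapped codes into the manual dictionary.

    The result is the set union after normalization: additions already
    present are skipped, as are additions on the ``excluded`` list of
    previously rejected (system, code) keys.  An addition whose code exists
    under a *different* factor is a hard error — that conflict requires
    human adjudication, never silent resolution.

    Returns the merged superset dictionary and a :class:`MergeDelta` whose
    ``percent_added`` is n_added / total codes after merge.
    """
    existing = {c.key: c for c in base.codes}
    excluded_keys = {( "ICD9" if s == "ICD9CM" else s, normalize_code(c)) for s, c in excluded}
    delta = MergeDelta()
    merged_codes = list(base.codes)
    conflicts: list[str] = []
    seen_new: set[tuple[str, str]] = set()
    for entry in additions:
        entry = CodeEntry(
            system=entry.system,
            code=normalize_code(entry.code),
            factor_id=entry.factor_id,
            source="automatic",
            threshold_direction=entry.threshold_direction,
            threshold_value=entry.threshold_value,
        )
        if entry.key in excluded_keys:
            delta.n_skipped_excluded += 1
            continue
        present = existing.get(entry.key)
        if present is not None:
            if present.factor_id != entry.factor_id:
                conflicts.append(
                    f"code {entry.code} ({entry.system}): addition maps to "
                    f"{FACTOR_BY_ID[entry.factor_id].name} but base has "
                    f"{FACTOR_BY_ID[present.factor_id].name}"
                )
            else:
                delta.n_skipped_duplicate += 1
            continue
        if entry.key in seen_new:
            delta.n_skipped_duplicate += 1
            continue
        seen_new.add(entry.key)
        merged_codes.append(entry)
        delta.n_added += 1
    if conflicts:
        raise DictionaryError(
            "cross-factor code collisions need manual adjudication:\n" + "\n".join(conflicts)
        )
    merged = TerminologyDictionary(
        codes=merged_codes, terms=list(base.terms), version=base.version + "+auto"
    )
    delta.total_after = len(merged.codes)
    return merged, delta


# ---------------------------------------------------------------------------
# analytics

CAPTURE_CATEGORIES = ("mostly_codes", "mostly_freetext", "equal", "rule_based")


@dataclass
class FactorStats:
    factor_id: int
    name: str
    n_codes: int
    n_freetext: int
    capture_category: str | None


@dataclass
class DictionaryStats:
    per_factor: list[FactorStats]
    n_codes_total: int
    n_terms_total: int
    n_by_system: dict[str, int]
    category_counts: dict[str, int]
    warnings: list[str]

    @property
    def n_entries_total(self) -> int:
        return self.n_codes_total + self.n_terms_total

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_factor": [asdict(f) for f in self.per_factor],
                "totals": {
                    "entries": self.n_entries_total,
                    "codes": self.n_codes_total,
                    "freetext": self.n_terms_total,
                    "by_system": self.n_by_system,
                },
                "category_counts": self.category_counts,
                "warnings": self.warnings,
            },
            indent=2,
        )


def dictionary_stats(
    dictionary: TerminologyDictionary, equal_threshold: float = 0.10
) -> DictionaryStats:
    """Per-factor entry counts and capture categories.

    Subsumed phrases count as separate unique free-text terms (a parent
    with two subsumed phrases contributes three to ``n_freetext``).  A
    factor is ``equal`` when the relative difference between its code and
    free-text counts, |c − t| / (c + t), is below ``equal_threshold``
    (default 10%); otherwise the larger side decides ``mostly_codes`` vs
    ``mostly_freetext``.  Polypharmacy is always ``rule_based``; a factor
    with no entries has an undefined category, reported as a warning.
    """
    per_factor: list[FactorStats] = []
    warnings: list[str] = []
    by_system: dict[str, int] = defaultdict(int)
    # ICD9 and ICD9-CM are reported together, as one code space.
    for entry in dictionary.codes:
        label = "ICD9/ICD9CM" if entry.system in ("ICD9", "ICD9CM") else entry.system
        by_system[label] += 1
    for factor in dictionary.factors:
        n_codes = len(dictionary.codes_for(factor.id))
        n_freetext = sum(1 + len(t.subsumes) for t in dictionary.terms_for(factor.id))
        if factor.rule_based:
            category: str | None = "rule_based"
        elif n_codes + n_freetext == 0:
            category = None
            warnings.append(f"factor {factor.name!r} has no entries; category undefined")
        elif abs(n_codes - n_freetext) / (n_codes + n_freetext) < equal_threshold:
            category = "equal"
        elif n_codes > n_freetext:
            category = "mostly_codes"
        else:
            category = "mostly_freetext"
        per_factor.append(FactorStats(factor.id, factor.name, n_codes, n_freetext, category))
    category_counts = {c: 0 for c in CAPTURE_CATEGORIES}
    for stats in per_factor:
        if stats.capture_category:
            category_counts[stats.capture_category] += 1
    return DictionaryStats(
        per_factor=per_factor,
        n_codes_total=sum(f.n_codes for f in per_factor),
        n_terms_total=sum(f.n_freetext for f in per_factor),
        n_by_system=dict(by_system),
        category_counts=category_counts,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# full-scale synthetic stand-in
#
# The complete published term list lives in a supplement that is not part of
# this repository, so scale testing uses a synthetic dictionary constructed
# to the published marginal totals: 2987 ICD9/ICD9-CM codes, 31 LOINC labs,
# 3 ATC medications (3021 codes), 747 free-text terms, 3768 entries in all;
# 24 factors mostly captured by codes, 7 mostly by free text, 4 roughly
# equally, with polypharmacy rule-based; housebound 1 code / 14 terms and
# social vulnerability 22 / 66.

_MOSTLY_FREETEXT = {
    "Activity limitation": (6, 40),
    "Dyspnoea": (5, 30),
    "Housebound": (1, 14),
    "Hypotension or syncope": (8, 25),
    "Parkinsonism and tremor": (9, 20),
    "Social vulnerability": (22, 66),
    "Weight loss": (4, 22),
}
_EQUAL = {
    "Falls": (20, 20),
    "Foot problems": (12, 11),
    "Memory and cognitive problems": (25, 23),
    "Sleep disturbance": (18, 16),
}
_LOINC_ALLOC = {
    "Anaemia and haematinic deficiency": 6,
    "Chronic kidney disease": 6,
    "Diabetes": 6,
    "Thyroid disease": 5,
    "Urinary system disease": 4,
    "Respiratory disease": 4,
}
_ATC_ALLOC = {
    "Diabetes": "A10AB01",          # insulin
    "Thyroid disease": "H03AA01",   # levothyroxine
    "Parkinsonism and tremor": "N04BA02",  # levodopa-carbidopa
}
_N_AUTOMATIC = 16


def fullscale_synthetic() -> TerminologyDictionary:
    """Synthetic full-scale dictionary matching the published marginal totals.

    A labelled stand-in for the unpublished supplementary term list: entry
    *contents* are generated placeholders, but every count the analytics
    report — per-system totals, code/free-text split, per-factor capture
    categories — is constrained to the published figures, so the analytics
    pipeline can be exercised at real scale.
    """
    manual, additions = fullscale_synthetic_split()
    merged, _ = merge_term_sources(manual, additions)
    merged.version = "fullscale-synthetic"
    return merged


def fullscale_synthetic_split() -> tuple[TerminologyDictionary, list[CodeEntry]]:
    """The same stand-in split as (manual-only dictionary, automatic additions).

    The manual dictionary carries 2971 ICD9/ICD9-CM codes; the 16 additions
    are the codes contributed only by automatic mapping, so merging them
    reproduces the published merge delta (16 added, ≈0.5% of 2987).
    """
    # decide (n_codes, n_freetext) for every factor
    counts: dict[str, tuple[int, int]] = dict(_MOSTLY_FREETEXT) | dict(_EQUAL)
    mostly_codes = [
        f.name
        for f in FACTORS
        if not f.rule_based and f.name not in counts
    ]
    assert len(mostly_codes) == 24
    for i, name in enumerate(sorted(mostly_codes)):
        n_codes = 121 if i < 11 else 120
        n_text = 20 if i < 4 else 19
        counts[name] = (n_codes, n_text)

    codes: list[CodeEntry] = []
    terms: list[FreeTextTerm] = []
    for factor in FACTORS:
        if factor.rule_based:
            continue
        n_codes, n_text = counts[factor.name]
        n_loinc = _LOINC_ALLOC.get(factor.name, 0)
        atc = _ATC_ALLOC.get(factor.name)
        n_icd = n_codes - n_loinc - (1 if atc else 0)
        for j in range(n_icd):
            codes.append(
                CodeEntry(system="ICD9CM", code=f"S{factor.id:02d}{j:04d}", factor_id=factor.id)
            )
        for j in range(n_loinc):
            codes.append(
                CodeEntry(system="LOINC", code=f"{9000 + factor.id * 10 + j}-0", factor_id=factor.id)
            )
        if atc:
            codes.append(CodeEntry(system="ATC", code=atc, factor_id=factor.id))
        slug = normalize_text(factor.name)
        for j in range(n_text):
            terms.append(FreeTextTerm(phrase=f"{slug} marker {j}", factor_id=factor.id))

    # the last 16 ICD entries stand for the codes only automatic mapping found
    icd_entries = [c for c in codes if c.system == "ICD9CM"]
    automatic_keys = {c.key for c in icd_entries[-_N_AUTOMATIC:]}
    manual_codes = [c for c in codes if c.key not in automatic_keys]
    additions = [
        CodeEntry(system=c.system, code=c.code, factor_id=c.factor_id, source="automatic")
        for c in codes
        if c.key in automatic_keys
    ]
    manual = TerminologyDictionary(
        codes=manual_codes, terms=terms, version="fullscale-synthetic-manual"
    )
    return manual, additions
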