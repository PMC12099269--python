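"""Terminology dictionary: loading, validation, merging, analytics."""

import json

import pytest

import efrailty as ef
from efrailty.factors import FACTOR_NAMES, POLYPHARMACY


def entry(factor, kind, value, system="ICD9", **kw):
    rec = {"factor": factor, "kind": kind, "value": value}
    if kind == "code":
        rec["system"] = system
    rec.update(kw)
    return rec


def write_dict(tmp_path, entries, name="d.json"):
    path = tmp_path / name
    path.write_text(json.dumps({"version": "test", "entries": entries}))
    return path


class TestLoading:
    def test_seed_dictionary_covers_all_factors(self, seed_dict):
        """Every factor except rule-based polypharmacy has at least one term."""
        for factor in seed_dict.factors:
            n_terms = len(seed_dict.terms_for(factor.id))
            n_codes = len(seed_dict.codes_for(factor.id))
            if factor.rule_based:
                assert n_terms == 0 and n_codes == 0
            else:
                assert n_terms >= 1, factor.name

    def test_entries_normalized_on_load(self, tmp_path):
        d = ef.load_dictionary(
            write_dict(
                tmp_path,
                [
                    entry("Heart failure", "code", " 428.0 "),
                    entry("Heart failure", "term", "  Cardiac   Failure!"),
                ],
            )
        )
        assert d.codes[0].code == "4280"
        assert d.terms[0].phrase == "cardiac failure"

    def test_duplicate_code_across_factors_is_hard_error_naming_both(self, tmp_path):
        path = write_dict(
            tmp_path,
            [
                entry("Heart failure", "code", "4280"),
                entry("Atrial fibrillation", "code", "428.0"),
            ],
        )
        with pytest.raises(ef.DictionaryError) as err:
            ef.load_dictionary(path)
        assert "Heart failure" in str(err.value)
        assert "Atrial fibrillation" in str(err.value)

    def test_unknown_factor_and_system_rejected(self, tmp_path):
        with pytest.raises(ef.DictionaryError, match="unknown factor"):
            ef.load_dictionary(write_dict(tmp_path, [entry("Not A Factor", "term", "x")]))
        with pytest.raises(ValueError, match="unknown code system"):
            ef.load_dictionary(
                write_dict(tmp_path, [entry("Heart failure", "code", "1", system="SNOMED")])
            )

    def test_missing_file_is_error(self, tmp_path):
        with pytest.raises(ef.DictionaryError, match="not found"):
            ef.load_dictionary(tmp_path / "nope.json")

    def test_csv_dialect_round_trip(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "factor,kind,system,value,exclusions,subsumes,source\n"
            "Atrial fibrillation,term,,flutter,ventricular,,\n"
            "Activity limitation,term,,disability,,disability form,\n"
            "Heart failure,code,ICD9,428.0,,,manual\n"
        )
        d = ef.load_dictionary(path)
        assert d.terms[0].exclusions == ("ventricular",)
        assert d.terms[1].subsumes == ("disability form",)
        assert d.codes[0].code == "4280"

    def test_csv_missing_column_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("factor,kind,value\nHeart failure,code,4280\n")
        with pytest.raises(ef.DictionaryError, match="missing columns"):
            ef.load_dictionary(path)


class TestValidation:
    def test_seed_dictionary_has_zero_errors(self, seed_dict):
        report = ef.validate_dictionary(seed_dict)
        assert report.valid and report.errors == []

    def test_same_phrase_under_two_factors_is_error(self):
        d = ef.TerminologyDictionary(
            terms=[
                ef.FreeTextTerm("falls", factor_id=10),
                ef.FreeTextTerm("falls", factor_id=8),
            ]
        )
        report = ef.validate_dictionary(d)
        assert any("falls" in e and "multiple factors" in e for e in report.errors)

    def test_factor_with_terms_but_no_codes_is_fine(self):
        # a factor can be carried entirely by free text (e.g. housebound)
        d = ef.TerminologyDictionary(terms=[ef.FreeTextTerm("housebound", factor_id=16)])
        report = ef.validate_dictionary(d)
        assert not any("Housebound" in e for e in report.errors)

    def test_empty_factor_is_warning_not_error(self):
        d = ef.TerminologyDictionary(terms=[ef.FreeTextTerm("stroke", factor_id=5)])
        report = ef.validate_dictionary(d)
        assert report.valid
        assert any("no entries" in w for w in report.warnings)

    def test_exclusion_equal_to_phrase_is_error(self):
        d = ef.TerminologyDictionary(
            terms=[ef.FreeTextTerm("flutter", factor_id=4, exclusions=("flutter",))]
        )
        assert not ef.validate_dictionary(d).valid

    def test_polypharmacy_entries_are_error(self):
        d = ef.TerminologyDictionary(
            terms=[ef.FreeTextTerm("many meds", factor_id=ef.POLYPHARMACY_ID)]
        )
        report = ef.validate_dictionary(d)
        assert any("rule-based" in e for e in report.errors)

    def test_phrase_subsumed_under_other_factor_is_error(self):
        d = ef.TerminologyDictionary(
            terms=[
                ef.FreeTextTerm("disability", factor_id=1, subsumes=("disability form",)),
                ef.FreeTextTerm("disability form", factor_id=21),
            ]
        )
        assert not ef.validate_dictionary(d).valid


class TestMerge:
    def base(self):
        return ef.TerminologyDictionary(
            codes=[
                ef.CodeEntry("ICD9", "A1", factor_id=1),
                ef.CodeEntry("ICD9", "B2", factor_id=2),
            ]
        )

    def test_set_union_semantics(self):
        additions = [
            ef.CodeEntry("ICD9", "B2", factor_id=2, source="automatic"),
            ef.CodeEntry("ICD9", "C3", factor_id=3, source="automatic"),
        ]
        merged, delta = ef.merge_term_sources(self.base(), additions)
        assert {c.code for c in merged.codes} == {"A1", "B2", "C3"}
        assert delta.n_added == 1 and delta.n_skipped_duplicate == 1

    def test_exclusion_list_blocks_previously_rejected_codes(self):
        additions = [ef.CodeEntry("ICD9", "C3", factor_id=3, source="automatic")]
        merged, delta = ef.merge_term_sources(
            self.base(), additions, excluded=[("ICD9", "C3")]
        )
        assert delta.n_added == 0 and delta.n_skipped_excluded == 1
        assert {c.code for c in merged.codes} == {"A1", "B2"}

    def test_cross_factor_collision_requires_adjudication(self):
        additions = [ef.CodeEntry("ICD9", "A1", factor_id=5, source="automatic")]
        with pytest.raises(ef.DictionaryError, match="adjudication"):
            ef.merge_term_sources(self.base(), additions)

    def test_merge_is_idempotent(self):
        additions = [ef.CodeEntry("ICD9", "C3", factor_id=3, source="automatic")]
        once, _ = ef.merge_term_sources(self.base(), additions)
        twice, delta2 = ef.merge_term_sources(once, additions)
        assert delta2.n_added == 0
        assert [c.key for c in twice.codes] == [c.key for c in once.codes]

    def test_icd9cm_addition_duplicating_icd9_code_is_skipped(self):
        # one normalized code space across ICD9 / ICD9-CM
        additions = [ef.CodeEntry("ICD9CM", "A1", factor_id=1, source="automatic")]
        _, delta = ef.merge_term_sources(self.base(), additions)
        assert delta.n_added == 0 and delta.n_skipped_duplicate == 1


class TestStats:
    def mini(self, n_codes, n_text, factor_id=16):
        return ef.TerminologyDictionary(
            codes=[ef.CodeEntry("ICD9", f"C{i}", factor_id=factor_id) for i in range(n_codes)],
            terms=[ef.FreeTextTerm(f"term {i}", factor_id=factor_id) for i in range(n_text)],
        )

    @pytest.mark.parametrize(
        "n_codes,n_text,expected",
        [
            (1, 14, "mostly_freetext"),   # housebound-like split
            (22, 66, "mostly_freetext"),  # social-vulnerability-like split
            (10, 10, "equal"),
            (120, 19, "mostly_codes"),
            (19, 21, "equal"),            # |19-21|/40 = 0.05 < 0.10
            (18, 22, "mostly_freetext"),  # |18-22|/40 = 0.10, not < 0.10
        ],
    )
    def test_capture_category_rule(self, n_codes, n_text, expected):
        stats = ef.dictionary_stats(self.mini(n_codes, n_text))
        assert stats.per_factor[15].capture_category == expected

    def test_category_symmetry_under_count_swap(self):
        for c, t in [(3, 30), (30, 3), (10, 11), (5, 5)]:
            cat = ef.dictionary_stats(self.mini(c, t)).per_factor[15].capture_category
            swapped = ef.dictionary_stats(self.mini(t, c)).per_factor[15].capture_category
            flip = {"mostly_codes": "mostly_freetext", "mostly_freetext": "mostly_codes"}
            assert swapped == flip.get(cat, cat)

    def test_subsumed_phrases_count_as_separate_terms(self):
        d = ef.TerminologyDictionary(
            terms=[ef.FreeTextTerm("disability", factor_id=1, subsumes=("disability form",))]
        )
        stats = ef.dictionary_stats(d)
        assert stats.per_factor[0].n_freetext == 2

    def test_totals_equal_sums_over_factors(self, seed_dict):
        stats = ef.dictionary_stats(seed_dict)
        assert stats.n_codes_total == sum(f.n_codes for f in stats.per_factor)
        assert stats.n_terms_total == sum(f.n_freetext for f in stats.per_factor)
        assert stats.n_entries_total == stats.n_codes_total + stats.n_terms_total

    def test_polypharmacy_always_rule_based(self, seed_dict):
        stats = ef.dictionary_stats(seed_dict)
        poly = next(f for f in stats.per_factor if f.name == POLYPHARMACY)
        assert poly.capture_category == "rule_based"

    def test_empty_factor_category_undefined_with_warning(self):
        stats = ef.dictionary_stats(self.mini(0, 0))
        assert stats.per_factor[15].capture_category is None
        assert any("Housebound" in w for w in stats.warnings)


class TestFullscaleSynthetic:
    def test_marginals_match_published_totals(self):
        stats = ef.dictionary_stats(ef.fullscale_synthetic())
        assert stats.n_entries_total == 3768
        assert stats.n_codes_total == 3021
        assert stats.n_terms_total == 747
        assert stats.n_by_system == {"ICD9/ICD9CM": 2987, "LOINC": 31, "ATC": 3}
        assert stats.category_counts == {
            "mostly_codes": 24,
            "mostly_freetext": 7,
            "equal": 4,
            "rule_based": 1,
        }

    def test_fullscale_is_valid(self):
        assert ef.validate_dictionary(ef.fullscale_synthetic()).valid
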