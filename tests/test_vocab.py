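"""Drug-name normalization and concept mapping."""
import pytest

from faerskit import vocab as fv
from faerskit.records import CaseVersion, DemographicKey, DrugEntry, SourceDialect
from faerskit.synth import SyntheticConfig, generate_fixture_vocabulary


@pytest.fixture(scope="module")
def fixture():
    return generate_fixture_vocabulary(SyntheticConfig(n_ingredients=8, seed=7))


class TestNormalizeDrugName:
    @pytest.mark.parametrize("raw,expected", [
        ("aspirin", "ASPIRIN"),                       # case fold
        ("  aspirin  ", "ASPIRIN"),                   # trim
        ("ETANERCEPT (50 MG)", "ETANERCEPT"),         # parenthesized suffix
        ("ETANERCEPT  50   MG", "ETANERCEPT"),        # whitespace + dose
        ('"ETANERCEPT"', "ETANERCEPT"),               # surrounding quotes
        ("ETANERCEPT 100MG", "ETANERCEPT"),           # fused number+unit
        ("ETANERCEPT TABLET", "ETANERCEPT"),          # form token
        ("ETANERCEPT 50 MG TABLET", "ETANERCEPT"),    # stacked tokens
        ("ETANERCEPT SOLUTION", "ETANERCEPT"),
        ("ETANERCEPT CAPSULE", "ETANERCEPT"),
        ("ETANERCEPT.", "ETANERCEPT"),                # trailing punctuation
        ("", ""),
        ("TABLET", "TABLET"),                         # never strip to empty
    ])
    def test_rules(self, raw, expected):
        assert fv.normalize_drug_name(raw) == expected


class TestMapDrugName:
    def test_plain_ingredient_maps_regex_exact(self, fixture):
        ing = fixture.ingredients[0]
        r = fv.map_drug_name(ing.name.lower(), None, None, fixture.vocab)
        assert r.method is fv.MappingMethod.REGEX_EXACT
        assert r.concept.concept_id == ing.concept_id

    def test_brand_resolves_to_standard_target(self, fixture):
        bname, (_, target) = next(iter(fixture.brands.items()))
        r = fv.map_drug_name(bname, None, None, fixture.vocab)
        assert r.mapped and r.concept.concept_id == target
        assert r.concept.standard

    def test_active_ingredient_fallback(self, fixture):
        ing = fixture.ingredients[1]
        r = fv.map_drug_name("UNSPECIFIED PRODUCT 1", ing.name, None,
                             fixture.vocab)
        assert r.method is fv.MappingMethod.ACTIVE_INGREDIENT
        assert r.concept.concept_id == ing.concept_id

    def test_nda_number_fallback(self, fixture):
        cid, num = next(iter(fixture.nda_numbers.items()))
        r = fv.map_drug_name(f"PRODUCT {num}", None, num, fixture.vocab)
        assert r.method is fv.MappingMethod.NDA
        assert r.concept.concept_id == cid

    def test_manual_map_last_resort(self, fixture):
        ing = fixture.ingredients[2]
        manual = {"MYSTERY SYRUP": ing.concept_id}
        r = fv.map_drug_name("Mystery Syrup", None, None, fixture.vocab, manual)
        assert r.method is fv.MappingMethod.MANUAL
        assert r.concept.concept_id == ing.concept_id

    def test_garbage_is_unmapped(self, fixture):
        r = fv.map_drug_name("XYZZY PLUGH", None, None, fixture.vocab)
        assert r.method is fv.MappingMethod.UNMAPPED and r.concept is None

    def test_every_mapped_result_is_standard(self, fixture):
        for name in fixture.vocab.name_lookup:
            r = fv.map_drug_name(name, None, None, fixture.vocab)
            assert r.mapped and r.concept.standard


class TestResolveToStandard:
    def test_standard_concept_is_identity(self, fixture):
        ing = fixture.ingredients[0]
        assert fv.resolve_to_standard(ing, fixture.vocab) is ing

    def test_orphan_nonstandard_yields_none_with_warning(self, fixture, caplog):
        orphan = fv.Concept(999, "X", "RxNorm", "ORPHAN", standard=False)
        fixture.vocab.concepts[999] = orphan
        try:
            with caplog.at_level("WARNING"):
                assert fv.resolve_to_standard(orphan, fixture.vocab) is None
            assert "unmapped" in caplog.text
        finally:
            del fixture.vocab.concepts[999]

    def test_inconsistent_bundle_rejected_at_load(self, fixture):
        with pytest.raises(fv.VocabularyError):
            fv.Vocabulary(concepts=dict(fixture.vocab.concepts),
                          name_lookup={"GHOST": 123456789},
                          relationship={}, pt_map={}, nda={})


class TestMapMeddraPt:
    def test_mapped_pt_returns_both_ids(self, fixture):
        pt = next(p for p, m in fixture.pt_mapping.items() if m)
        std, sno = fv.map_meddra_pt(pt, fixture.vocab)
        assert (std, sno) == fixture.pt_mapping[pt]

    def test_case_variant_same_snomed(self, fixture):
        pt = next(p for p, m in fixture.pt_mapping.items() if m)
        assert (fv.map_meddra_pt(pt.upper(), fixture.vocab)
                == fv.map_meddra_pt(pt.lower(), fixture.vocab))

    def test_unmapped_pt_returns_nulls(self, fixture):
        assert fv.map_meddra_pt("No such term", fixture.vocab) == (None, None)


def _case(drugs, reactions=("Cardiac failure",)):
    return CaseVersion(caseid="1", init_fu_code="I",
                       dialect=SourceDialect.CURRENT, primaryid="1",
                       demo=DemographicKey(),
                       drugs=[DrugEntry("1", "PS", d) for d in drugs],
                       reactions=list(reactions))


class TestCoverageReport:
    def test_all_mapped_gives_one(self, fixture):
        ing = fixture.ingredients[0]
        results = [fv.map_drug_name(ing.name, None, None, fixture.vocab)]
        rep = fv.coverage_report(results, [_case([ing.name])], fixture.vocab)
        assert rep.drug_string_coverage == 1.0
        assert rep.case_all_drugs_mapped_fraction == 1.0

    def test_known_unmappable_fraction(self, fixture):
        ing = fixture.ingredients[0]
        strings = [ing.name, "JUNKDRUGNAME"]
        results = [fv.map_drug_name(s, None, None, fixture.vocab)
                   for s in strings]
        rep = fv.coverage_report(results, [_case(strings)], fixture.vocab)
        assert rep.drug_string_coverage == 0.5
        assert rep.case_all_drugs_mapped_fraction == 0.0
        assert rep.case_any_drug_mapped_fraction == 1.0

    def test_empty_input_flags_zero_denominators(self, fixture):
        rep = fv.coverage_report([], [], fixture.vocab)
        assert rep.drug_string_coverage is None
        assert "drug_strings" in rep.zero_denominators
        assert "cases" in rep.zero_denominators
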