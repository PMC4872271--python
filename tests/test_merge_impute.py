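"""Demographic normalization, dataset merging and single-value imputation."""
import copy

import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerskit import merge
from faerskit.records import CaseVersion, DemographicKey, SourceDialect


class TestNormalizeAge:
    @pytest.mark.parametrize("value,unit,expected", [
        ("24", "MON", 2.0),
        ("50", "YR", 50.0),
        ("5", "DEC", 50.0),
        ("52", "WK", 1.0),
        ("365", "DY", 1.0),
        ("8760", "HR", 1.0),
        ("30", "", 30.0),        # blank unit read as years
        ("30", None, 30.0),
    ])
    def test_unit_conversion(self, value, unit, expected):
        assert merge.normalize_age(value, unit) == pytest.approx(expected)

    @pytest.mark.parametrize("value,unit", [
        ("", "YR"), (None, "YR"), ("abc", "YR"), ("-5", "YR"),
    ])
    def test_unparseable_is_null(self, value, unit):
        assert merge.normalize_age(value, unit) is None


class TestNormalizeCountry:
    def test_legacy_name_maps_to_code(self):
        assert merge.normalize_country("UNITED STATES",
                                       SourceDialect.LEGACY) == "US"

    def test_code_passes_through(self):
        assert merge.normalize_country("US", SourceDialect.CURRENT) == "US"

    def test_same_country_both_dialects_same_code(self):
        legacy = merge.normalize_country("Japan", SourceDialect.LEGACY)
        current = merge.normalize_country("JP", SourceDialect.CURRENT)
        assert legacy == current == "JP"

    def test_empty_is_null_and_unknown_uppercased(self):
        assert merge.normalize_country("", SourceDialect.LEGACY) is None
        assert merge.normalize_country("narnia", None) == "NARNIA"


class TestNormalizeEventDate:
    @pytest.mark.parametrize("raw,expected", [
        ("20120315", "20120315"),
        ("201203", "20120301"),   # partial dates padded, still populated
        ("2012", "20120101"),
        ("", None),
        ("15-03-2012", None),
    ])
    def test_padding(self, raw, expected):
        assert merge.normalize_event_date(raw) == expected


def _version(caseid="1", dialect=SourceDialect.LEGACY, key="100", **demo):
    base = dict(event_date="20120101", age_years=50.0, sex="F", country="US")
    base.update(demo)
    kwargs = {"isr": key} if dialect is SourceDialect.LEGACY else {"primaryid": key}
    return CaseVersion(caseid=caseid, init_fu_code="I", dialect=dialect,
                       demo=DemographicKey(**base), **kwargs)


class TestMergeDatasets:
    def test_counts_add(self):
        legacy = [_version(key=str(i)) for i in range(2)]
        current = [_version(dialect=SourceDialect.CURRENT, key=str(i))
                   for i in range(3)]
        assert len(merge.merge_datasets(legacy, current)) == 5

    def test_legacy_record_keeps_isr_with_null_primaryid(self):
        merged = merge.merge_datasets([_version(key="7")], [])
        assert merged[0].isr == "7" and merged[0].primaryid is None

    def test_empty_inputs(self):
        assert merge.merge_datasets([], []) == []

    def test_caseid_key_multiset_preserved(self):
        legacy = [_version(caseid="a", key="1"), _version(caseid="a", key="2")]
        current = [_version(caseid="b", dialect=SourceDialect.CURRENT, key="9")]
        merged = merge.merge_datasets(legacy, current)
        assert sorted((v.caseid, v.case_key) for v in merged) == [
            ("a", "1"), ("a", "2"), ("b", "9")]


class TestImputeSingleMissing:
    def test_fully_populated_versions_unchanged(self):
        versions = [_version(key="1"), _version(key="2")]
        before = [copy.deepcopy(v.demo) for v in versions]
        merge.impute_single_missing(versions)
        assert [v.demo for v in versions] == before

    def test_single_missing_filled_from_full_sibling(self):
        v1 = _version(key="1")                       # 20120101, 50, F, US
        v2 = _version(key="2", age_years=None)
        merge.impute_single_missing([v1, v2])
        assert v2.demo.age_years == 50.0

    def test_two_missing_fields_left_alone(self):
        v1 = _version(key="1")
        v2 = _version(key="2", age_years=None, sex=None)
        merge.impute_single_missing([v1, v2])
        assert v2.demo.age_years is None and v2.demo.sex is None

    def test_no_full_version_means_no_imputation(self):
        v1 = _version(key="1", country=None)
        v2 = _version(key="2", age_years=None)
        merge.impute_single_missing([v1, v2])
        assert v1.demo.country is None and v2.demo.age_years is None

    def test_donor_is_per_field_maximum(self):
        v1 = _version(key="1", event_date="20120101", age_years=40.0)
        v2 = _version(key="2", event_date="20130101", age_years=30.0)
        v3 = _version(key="3", age_years=None)
        merge.impute_single_missing([v1, v2, v3])
        assert v3.demo.age_years == 40.0
        v4 = _version(key="4", event_date=None)
        merge.impute_single_missing([v1, v2, v4])
        assert v4.demo.event_date == "20130101"


# -- property tests ----------------------------------------------------------

_dates = st.sampled_from(["20120101", "20120615", "20131231", None])
_ages = st.sampled_from([0.0, 2.0, 50.0, 99.0, None])
_sexes = st.sampled_from(["M", "F", None])
_countries = st.sampled_from(["US", "JP", "DE", None])


@st.composite
def version_sets(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    out = []
    for i in range(n):
        out.append(_version(
            key=str(i + 1),
            event_date=draw(_dates), age_years=draw(_ages),
            sex=draw(_sexes), country=draw(_countries)))
    return out


@given(version_sets())
def test_imputation_is_idempotent(versions):
    once = [copy.deepcopy(v) for v in versions]
    merge.impute_single_missing(once)
    snapshot = [copy.deepcopy(v.demo) for v in once]
    merge.impute_single_missing(once)
    assert [v.demo for v in once] == snapshot


@given(version_sets())
def test_imputation_never_alters_populated_fields(versions):
    before = [copy.deepcopy(v.demo) for v in versions]
    merge.impute_single_missing(versions)
    for old, v in zip(before, versions):
        for name in DemographicKey.FIELDS:
            if getattr(old, name) is not None:
                assert getattr(v.demo, name) == getattr(old, name)


@given(version_sets())
def test_imputation_contract_on_missing_counts(versions):
    before = [copy.deepcopy(v.demo) for v in versions]
    has_full = any(d.is_complete() for d in before)
    merge.impute_single_missing(versions)
    for old, v in zip(before, versions):
        if old.missing_count() == 1 and has_full:
            assert v.demo.is_complete()
        elif old.missing_count() >= 2 or not has_full:
            assert v.demo == old
        assert v.demo.missing_count() <= old.missing_count()
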