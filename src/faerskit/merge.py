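"""Merging the two report dialects and single missing-value imputation.

Legacy and current case versions are concatenated into one stream of
:class:`~faerskit.records.CaseVersion` rows that carry both key columns
(``isr`` for legacy, ``primaryid`` for current; the other is null).  The
four demographic fields used downstream — event date, age, sex, reporter
country — are normalized here so that the same underlying value spells
identically in both dialects.

Imputation is deliberately conservative: within one case, a version
missing exactly one of the four fields receives that field from the
per-field maximum over the case's fully populated versions; versions
missing two or more fields are left untouched, and populated fields are
never altered.
"""
from __future__ import annotations

import logging
import re
from typing import Iterable, Optional, Sequence

from .io import ParsedTable
from .records import (CaseVersion, DemographicKey, DrugEntry, QuarterFileRef,
                      SourceDialect)

log = logging.getLogger(__name__)

#: Age-unit codes of the DEMO files, as a factor converting to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "DEC": 10.0,          # decades
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

#: Bundled reporter-country normalization table (name-style spellings, as
#: used by legacy quarters, to ISO-3166-ish codes used by current quarters).
#: Callers may pass their own table to :func:`normalize_country`.
COUNTRY_TABLE: dict[str, str] = {
    "UNITED STATES": "US",
    "USA": "US",
    "UNITED STATES OF AMERICA": "US",
    "UNITED KINGDOM": "GB",
    "GREAT BRITAIN": "GB",
    "JAPAN": "JP",
    "GERMANY": "DE",
    "FRANCE": "FR",
    "CANADA": "CA",
    "ITALY": "IT",
    "SPAIN": "ES",
    "AUSTRALIA": "AU",
    "BRAZIL": "BR",
    "NETHERLANDS": "NL",
}


def normalize_age(age_value: str | None, age_unit_code: str | None) -> Optional[float]:
    """Convert a DEMO age value + unit code to decimal years.

    A blank or unrecognised unit code is treated as years (the dominant
    FDA convention); an unparseable or absent value yields ``None``.
    """
    if age_value is None:
        return None
    text = age_value.strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        log.debug("unparseable age value %r", age_value)
        return None
    if value < 0:
        return None
    unit = (age_unit_code or "").strip().upper() or "YR"
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        factor = 1.0
    return value * factor


def normalize_country(raw: str | None, dialect: SourceDialect | None = None,
                      table: dict[str, str] | None = None) -> Optional[str]:
    """Normalize a reporter-country value to a two-letter code.

    Name-style spellings (legacy dialect) map through the bundled table;
    values already looking like codes, and unmapped non-empty values, pass
    through upper-cased so the same true country compares equal whichever
    dialect it came from.
    """
    if raw is None:
        return None
    text = raw.strip().upper()
    if not text:
        return None
    lookup = COUNTRY_TABLE if table is None else table
    return lookup.get(text, text)


_DATE_RE = re.compile(r"^\d{4}(\d{2})?(\d{2})?$")


def normalize_event_date(raw: str | None) -> Optional[str]:
    """Normalize an event date to an 8-digit YYYYMMDD string.

    Partial dates (YYYY or YYYYMM) are padded with "01" components so
    they order and compare; they still count as populated.  Anything not
    matching 4/6/8 digits is missing.
    """
    if raw is None:
        return None
    text = raw.strip()
    if not text or not _DATE_RE.match(text):
        return None
    return text + "01" * ((8 - len(text)) // 2)


def _opt(text: str) -> Optional[str]:
    return text if text else None


def assemble_case_versions(demo: ParsedTable,
                           drug: ParsedTable | None = None,
                           reac: ParsedTable | None = None,
                           indi: ParsedTable | None = None,
                           outc: ParsedTable | None = None,
                           country_table: dict[str, str] | None = None,
                           ) -> list[CaseVersion]:
    """Join one quarter's content tables into :class:`CaseVersion` rows.

    One DEMO row is one case version; DRUG/REAC/INDI/OUTC rows attach via
    the dialect-native row key.  Demographics are normalized here.
    """
    ref: QuarterFileRef = demo.ref
    dialect = ref.dialect
    legacy = dialect is SourceDialect.LEGACY

    def by_key(table: ParsedTable | None) -> dict[str, list]:
        grouped: dict[str, list] = {}
        if table is not None:
            for rec in table:
                grouped.setdefault(rec.case_key, []).append(rec.fields)
        return grouped

    drugs_by, reacs_by = by_key(drug), by_key(reac)
    indis_by, outcs_by = by_key(indi), by_key(outc)

    versions: list[CaseVersion] = []
    for rec in demo:
        f = rec.fields
        sex_col = "gndr_cod" if legacy else "sex"
        key = DemographicKey(
            event_date=normalize_event_date(f.get("event_dt", "")),
            age_years=normalize_age(f.get("age", ""), f.get("age_cod", "")),
            sex=_opt(f.get(sex_col, "").strip().upper()),
            country=normalize_country(f.get("reporter_country", ""), dialect,
                                      country_table),
        )
        drugs = [
            DrugEntry(
                drug_seq=d.get("drug_seq", ""),
                role_code=d.get("role_cod", "").strip().upper(),
                verbatim=d.get("drugname", ""),
                active_ingredient=_opt(d.get("prod_ai", "").strip()),
                nda=_opt(d.get("nda_num", "").strip()),
            )
            for d in drugs_by.get(rec.case_key, [])
        ]
        reactions = [r.get("pt", "").strip() for r in reacs_by.get(rec.case_key, [])]
        reactions = [r for r in reactions if r]
        seq_col = "drug_seq" if legacy else "indi_drug_seq"
        indications = [
            (i.get(seq_col, "") or i.get("indi_drug_seq", ""), i.get("indi_pt", "").strip())
            for i in indis_by.get(rec.case_key, [])
        ]
        indications = [(s, p) for s, p in indications if p]
        outcome_codes = [o.get("outc_cod", "").strip().upper()
                         for o in outcs_by.get(rec.case_key, [])]
        outcome_codes = [o for o in outcome_codes if o]
        versions.append(CaseVersion(
            caseid=rec.caseid,
            init_fu_code=f.get("i_f_cod", f.get("i_f_code", "")).strip().upper() or "I",
            dialect=dialect,
            demo=key,
            isr=rec.case_key if legacy else None,
            primaryid=None if legacy else rec.case_key,
            drugs=drugs,
            reactions=reactions,
            indications=indications,
            outcome_codes=outcome_codes,
            source_file=ref,
        ))
    return versions


def merge_datasets(legacy: Sequence[CaseVersion],
                   current: Sequence[CaseVersion]) -> list[CaseVersion]:
    """Concatenate legacy and current case versions into one stream.

    Nothing is dropped here — picking the single surviving version per
    case is the de-duplication stage's job.  Each record keeps its native
    key and a null for the other dialect's key.
    """
    return list(legacy) + list(current)


def group_by_case(versions: Iterable[CaseVersion]) -> dict[str, list[CaseVersion]]:
    grouped: dict[str, list[CaseVersion]] = {}
    for v in versions:
        grouped.setdefault(v.caseid, []).append(v)
    return grouped


def impute_single_missing(versions_of_one_case: Sequence[CaseVersion]
                          ) -> list[CaseVersion]:
    """Fill single missing demographic fields within one case.

    Requires at least one version with all four fields populated; the
    donor value for each field is the maximum over those fully populated
    versions (dates by calendar order, age numerically, sex and country
    lexicographically).  Only versions missing *exactly one* field change;
    populated values are never overwritten.  Mutates and returns the list.
    """
    full = [v for v in versions_of_one_case if v.demo.is_complete()]
    if not full:
        return list(versions_of_one_case)
    donor = DemographicKey(
        event_date=max(v.demo.event_date for v in full),
        age_years=max(v.demo.age_years for v in full),
        sex=max(v.demo.sex for v in full),
        country=max(v.demo.country for v in full),
    )
    for v in versions_of_one_case:
        if v.demo.missing_count() == 1:
            for name in DemographicKey.FIELDS:
                if getattr(v.demo, name) is None:
                    setattr(v.demo, name, getattr(donor, name))
    return list(versions_of_one_case)


def impute_all(versions: Iterable[CaseVersion]) -> list[CaseVersion]:
    """Apply :func:`impute_single_missing` case by case; order-preserving."""
    versions = list(versions)
    for case_versions in group_by_case(versions).values():
        impute_single_missing(case_versions)
    return versions
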