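"""Core record types shared across the pipeline.

A *case* is one adverse-event report; it may have several *versions*: the
initial submission (``I``) and follow-ups (``F``), each appearing as one row
of a quarterly DEMO file.  The legacy distribution (pre-September-2012,
"LAERS") keys rows by ``isr``/``case``; the current distribution ("FAERS")
keys them by ``primaryid``/``caseid``.  Merged records carry both key
columns so every row can be traced back to its source.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class SourceDialect(str, Enum):
    """Which of the two FDA quarterly-file dialects a file belongs to."""

    LEGACY = "LEGACY"    # key columns isr / case
    CURRENT = "CURRENT"  # key columns primaryid / caseid

    @property
    def rank(self) -> int:
        """CURRENT outranks LEGACY when choosing the most recent version."""
        return 1 if self is SourceDialect.CURRENT else 0


TABLE_KINDS = ("DEMO", "DRUG", "REAC", "INDI", "OUTC", "THER", "RPSR")


@dataclass(frozen=True)
class QuarterFileRef:
    """One quarterly source file (e.g. DEMO12Q4)."""

    table_kind: str
    year: int
    quarter: int
    dialect: SourceDialect
    path: str

    def __post_init__(self) -> None:
        if self.table_kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.table_kind!r}")
        if not 1 <= self.quarter <= 4:
            raise ValueError(f"quarter must be 1-4, got {self.quarter}")

    @property
    def period(self) -> tuple[int, int]:
        return (self.year, self.quarter)


@dataclass
class RawRecord:
    """One data row of a quarterly file, untyped.

    ``fields`` maps lower-cased column name to the (whitespace-trimmed)
    cell text; the empty string means missing.
    """

    case_key: str
    caseid: str
    fields: dict[str, str]
    source: QuarterFileRef


@dataclass
class DemographicKey:
    """The four fields used for imputation and step-2 de-duplication.

    ``event_date`` is a normalized YYYYMMDD string (partial dates padded
    with "01" components), ``age_years`` is age normalized to years.
    ``None`` means missing.
    """

    event_date: Optional[str] = None
    age_years: Optional[float] = None
    sex: Optional[str] = None
    country: Optional[str] = None

    FIELDS = ("event_date", "age_years", "sex", "country")

    def missing_count(self) -> int:
        return sum(getattr(self, f) is None for f in self.FIELDS)

    def is_complete(self) -> bool:
        return self.missing_count() == 0

    def key(self) -> tuple:
        """Hashable comparison key; ages rounded so unit-converted values
        (24 MON vs 2 YR) compare equal."""
        age = None if self.age_years is None else round(self.age_years, 4)
        return (self.event_date, age, self.sex, self.country)

    def copy(self) -> "DemographicKey":
        return replace(self)


@dataclass
class DrugEntry:
    """One row of a DRUG table: a medication reported for the case."""

    drug_seq: str
    role_code: str            # PS / SS / C / I
    verbatim: str             # drug name as reported
    active_ingredient: Optional[str] = None  # prod_ai (current dialect only)
    nda: Optional[str] = None


@dataclass
class CaseVersion:
    """One version of one case, assembled from the five content tables."""

    caseid: str
    init_fu_code: str                 # 'I' or 'F'
    dialect: SourceDialect
    demo: DemographicKey
    isr: Optional[str] = None         # legacy key
    primaryid: Optional[str] = None   # current key
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)          # MedDRA PTs
    indications: list[tuple[str, str]] = field(default_factory=list)  # (drug_seq, PT)
    outcome_codes: list[str] = field(default_factory=list)      # OUTC categories
    source_file: Optional[QuarterFileRef] = None

    @property
    def case_key(self) -> str:
        """The dialect-native unique row key (isr or primaryid)."""
        key = self.isr if self.dialect is SourceDialect.LEGACY else self.primaryid
        if key is None:
            raise ValueError(f"case {self.caseid}: missing {self.dialect.value} key")
        return key
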