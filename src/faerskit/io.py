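"""Reading FDA quarterly ASCII files and writing the standardized outputs.

The FDA distributes LAERS/FAERS quarters as "$"-delimited text with one
header row.  Legacy files key rows by ``ISR``, current files by
``primaryid``; :func:`detect_dialect` tells them apart from the header
alone.  Source files are read as Latin-1 (legacy quarters contain bytes
that are not valid UTF-8); all outputs are UTF-8 tab-delimited tables with
a fixed column order per schema.
"""
from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

from .records import QuarterFileRef, RawRecord, SourceDialect, TABLE_KINDS

log = logging.getLogger(__name__)

DEFAULT_DELIMITER = "$"

#: Fixed column order of each published output table.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "standard_case_drug": (
        "primaryid", "isr", "caseid", "drug_seq", "role_cod",
        "drug_name", "standard_concept_id",
    ),
    "standard_case_outcome": (
        "primaryid", "isr", "caseid", "pt",
        "outcome_concept_id", "snomed_outcome_concept_id",
    ),
    "standard_case_outcome_category": (
        "primaryid", "isr", "caseid", "outc_code", "snomed_concept_id",
    ),
    "standard_case_indication": (
        "primaryid", "isr", "caseid", "indi_drug_seq", "indi_pt",
        "indication_concept_id", "snomed_indication_concept_id",
    ),
    "standard_drug_outcome_contingency_table": (
        "drug_concept_id", "outcome_concept_id",
        "count_a", "count_b", "count_c", "count_d",
    ),
    "standard_drug_outcome_count": (
        "drug_concept_id", "outcome_concept_id", "drug_outcome_pair_count",
    ),
    "standard_drug_outcome_statistics": (
        "drug_concept_id", "outcome_concept_id", "case_count",
        "prr", "prr_95_ci_lower", "prr_95_ci_upper",
        "ror", "ror_95_ci_lower", "ror_95_ci_upper",
    ),
    "standard_drug_outcome_drilldown": (
        "drug_concept_id", "outcome_concept_id", "snomed_outcome_concept_id",
        "primaryid", "isr", "caseid",
    ),
}


class UnreadableFileError(ValueError):
    """Raised when a source file's header carries no recognizable key column."""


def detect_dialect(header_line: str, path: str | None = None,
                   delimiter: str = DEFAULT_DELIMITER) -> SourceDialect:
    """Classify a quarterly file as LEGACY or CURRENT from its header.

    Legacy files name their key column ``ISR``; current files name it
    ``primaryid`` (both matched case-insensitively).  Pure function of the
    header text.
    """
    columns = [c.strip().lower() for c in header_line.rstrip("\r\n").split(delimiter)]
    if "isr" in columns:
        return SourceDialect.LEGACY
    if "primaryid" in columns:
        return SourceDialect.CURRENT
    where = f" in {path}" if path else ""
    raise UnreadableFileError(
        f"header{where} has neither an ISR nor a primaryid column: {header_line!r}"
    )


@dataclass
class ParsedTable:
    """Records of one quarterly file plus a count of malformed rows skipped."""

    ref: QuarterFileRef
    columns: list[str]
    records: list[RawRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_quarter_table(ref: QuarterFileRef,
                       delimiter: str = DEFAULT_DELIMITER) -> ParsedTable:
    """Read one quarterly file into :class:`RawRecord` rows.

    Fields are whitespace-trimmed; the empty string is kept as the missing
    marker at this layer.  Rows whose field count disagrees with the header
    are skipped and counted (the FDA files occasionally contain stray
    delimiters); the skip count is logged and reported on the result.
    """
    if not os.path.exists(ref.path):
        raise FileNotFoundError(f"missing quarterly file: {ref.path}")
    with open(ref.path, "r", encoding="latin-1", errors="replace") as fh:
        header = fh.readline()
        if not header.strip():
            raise UnreadableFileError(f"empty file: {ref.path}")
        columns = [c.strip().lower() for c in header.rstrip("\r\n").split(delimiter)]
        key_col = "isr" if ref.dialect is SourceDialect.LEGACY else "primaryid"
        caseid_col = "case" if ref.dialect is SourceDialect.LEGACY else "caseid"
        if key_col not in columns:
            raise UnreadableFileError(
                f"{ref.path}: expected key column {key_col!r}, header has {columns}"
            )
        table = ParsedTable(ref=ref, columns=columns)
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) != len(columns):
                table.n_skipped += 1
                continue
            fields = dict(zip(columns, parts))
            key = fields.get(key_col, "")
            if not key:
                table.n_skipped += 1
                continue
            table.records.append(
                RawRecord(case_key=key, caseid=fields.get(caseid_col, ""),
                          fields=fields, source=ref)
            )
        if table.n_skipped:
            log.warning("%s: skipped %d malformed row(s)", ref.path, table.n_skipped)
    return table


def write_standard_table(rows, schema_name: str, path: str) -> str:
    """Write one published output table (tab-delimited, UTF-8).

    ``rows`` is an iterable of mappings; every schema column must be
    present in every row (``None`` is written as the empty string).
    Returns ``path``.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown output schema {schema_name!r}")
    columns = SCHEMAS[schema_name]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for i, row in enumerate(rows):
            cells = []
            for col in columns:
                if col not in row:
                    raise KeyError(
                        f"{schema_name} row {i}: missing column {col!r}"
                    )
                value = row[col]
                cells.append("" if value is None else str(value))
            fh.write("\t".join(cells) + "\n")
    return path


def read_standard_table(path: str) -> list[dict[str, str]]:
    """Read back a tab-delimited output table as a list of dicts."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        columns = header.split("\t") if header else []
        out = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append(dict(zip(columns, parts)))
    return out


_QUARTER_FILE_RE = re.compile(
    r"^(DEMO|DRUG|REAC|INDI|OUTC|THER|RPSR)(\d\d)Q([1-4])\.(?:txt|TXT)$"
)


def discover_quarter_files(input_dir: str,
                           delimiter: str = DEFAULT_DELIMITER) -> list[QuarterFileRef]:
    """Find quarterly files named like ``DEMO12Q4.txt`` under ``input_dir``.

    The dialect of each file is detected from its header.  Two-digit years
    are expanded into 2000-2099 (the FDA convention).
    """
    refs: list[QuarterFileRef] = []
    for name in sorted(os.listdir(input_dir)):
        m = _QUARTER_FILE_RE.match(name)
        if not m:
            continue
        kind, yy, q = m.group(1), int(m.group(2)), int(m.group(3))
        path = os.path.join(input_dir, name)
        with open(path, "r", encoding="latin-1", errors="replace") as fh:
            header = fh.readline()
        dialect = detect_dialect(header, path=path, delimiter=delimiter)
        refs.append(QuarterFileRef(table_kind=kind, year=2000 + yy, quarter=q,
                                   dialect=dialect, path=path))
    refs.sort(key=lambda r: (r.year, r.quarter, r.dialect.value, r.table_kind))
    return refs
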