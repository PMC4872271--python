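"""Two-step case de-duplication.

Step 1 keeps, for each case id, only the most recent version.  Recency is
resolved by a precedence key: current-dialect versions outrank legacy
ones (a case reported in both systems keeps its current version), then
the unique row key descending (keys are assigned chronologically by the
FDA), then the source file's year/quarter descending.

Step 2 collapses *different* case numbers that nevertheless describe the
same report: among surviving versions whose four demographic fields
(event date, age, sex, reporter country) are all populated and pairwise
equal, only the precedence-maximal one is kept.  A version with any
missing demographic field is never collapsed — missing never matches
missing, because merging on absent data would conflate unrelated cases
(the imputation stage exists precisely to populate these fields first).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import CaseVersion


@dataclass(frozen=True)
class VersionSignature:
    """Content fields the de-duplication logic compares between versions.

    Drug and reaction lists are upper-cased, trimmed, alphabetically
    sorted and joined with ``|`` (a character not occurring in names), so
    the signature is invariant to input ordering.
    """

    caseid: str
    init_fu_code: str
    event_date: Optional[str]
    age_years: Optional[float]
    sex: Optional[str]
    country: Optional[str]
    drug_list_key: str
    reaction_list_key: str

    @classmethod
    def of(cls, v: CaseVersion) -> "VersionSignature":
        date, age, sex, country = v.demo.key()
        return cls(
            caseid=v.caseid,
            init_fu_code=v.init_fu_code,
            event_date=date, age_years=age, sex=sex, country=country,
            drug_list_key=join_name_list(d.verbatim for d in v.drugs),
            reaction_list_key=join_name_list(v.reactions),
        )


def join_name_list(names: Iterable[str], sep: str = "|") -> str:
    """Canonical list key: upper-case, trim, sort alphabetically, join."""
    return sep.join(sorted(n.strip().upper() for n in names))


def _key_rank(case_key: str) -> tuple:
    # Numeric keys compare as integers and outrank non-numeric ones;
    # non-numeric keys fall back to lexicographic order among themselves.
    key = case_key.strip()
    if key.isdigit():
        return (1, int(key), "")
    return (0, 0, key)


def precedence_key(v: CaseVersion) -> tuple:
    """Total order over versions; the maximum is the most recent.

    Orders by dialect (CURRENT > LEGACY), then unique row key, then the
    source file's (year, quarter).
    """
    period = v.source_file.period if v.source_file is not None else (0, 0)
    return (v.dialect.rank, _key_rank(v.case_key), period)


def select_latest_version(versions_of_one_case: Sequence[CaseVersion]) -> CaseVersion:
    """Return the single most recent version of one case.

    Content signatures carry no recency information, so the winner —
    whether the versions are identical duplicates or genuine follow-ups —
    is the precedence-key maximum.
    """
    if not versions_of_one_case:
        raise ValueError("select_latest_version: empty version list")
    caseids = {v.caseid for v in versions_of_one_case}
    if len(caseids) > 1:
        raise ValueError(f"versions of multiple cases passed: {sorted(caseids)}")
    return max(versions_of_one_case, key=precedence_key)


def dedup_by_demographic_key(latest_cases: Sequence[CaseVersion],
                             audit_log: list | None = None
                             ) -> list[CaseVersion]:
    """Collapse cases sharing a fully populated demographic key.

    Input must hold one version per case id.  Output preserves input
    order of the survivors.
    """
    groups: dict[tuple, list[CaseVersion]] = {}
    for v in latest_cases:
        if v.demo.is_complete():
            groups.setdefault(v.demo.key(), []).append(v)
    dropped: set[int] = set()
    for demo_key, members in groups.items():
        if len(members) < 2:
            continue
        survivor = max(members, key=precedence_key)
        for v in members:
            if v is not survivor:
                dropped.add(id(v))
                if audit_log is not None:
                    audit_log.append({
                        "caseid": v.caseid,
                        "stage": "demographic_key",
                        "reason": "duplicate demographic key",
                        "survivor_caseid": survivor.caseid,
                        "survivor_key": survivor.case_key,
                    })
    return [v for v in latest_cases if id(v) not in dropped]


def deduplicate(cases: Iterable[CaseVersion],
                audit_log: list | None = None) -> list[CaseVersion]:
    """Full de-duplication: latest version per case id, then demographic
    collapse across case ids.

    The result has unique case ids and at most one survivor per fully
    populated demographic key, is a subset of the input, and does not
    depend on input ordering (ordered by case id for determinism).
    """
    grouped: dict[str, list[CaseVersion]] = {}
    for v in cases:
        grouped.setdefault(v.caseid, []).append(v)
    latest: list[CaseVersion] = []
    for caseid in sorted(grouped):
        versions = grouped[caseid]
        winner = select_latest_version(versions)
        latest.append(winner)
        if audit_log is not None:
            for v in versions:
                if v is not winner:
                    audit_log.append({
                        "caseid": caseid,
                        "stage": "latest_version",
                        "reason": "superseded case version",
                        "survivor_caseid": winner.caseid,
                        "survivor_key": winner.case_key,
                    })
    return dedup_by_demographic_key(latest, audit_log=audit_log)
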