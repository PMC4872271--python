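"""Drug–outcome contingency tables and disproportionality statistics.

Counting unit.  All 2×2 tables are counted over the *triple universe*:
the set of distinct (case, drug concept, outcome concept) combinations
from the de-duplicated, mapped reports, with drugs taken from every role
(primary suspect, secondary suspect, concomitant, interacting).  For a
drug D and outcome O,

    a = triples with D and O          b = triples with D, other outcome
    c = triples with other drug and O d = all remaining triples

so a+b+c+d = N, the universe size, for every pair in a run.  Counting
distinct *cases* instead of triples is available via ``counting_unit``.

Statistics.  Two standard disproportionality measures:

    PRR = (a/(a+b)) / (c/(c+d))
    95% CI = exp( ln PRR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)) )

    ROR = (a/c) / (b/d) = ad/(bc)
    95% CI = exp( ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d) )

Zero cells yield null statistics (no continuity correction by default; a
0.5 Haldane–Anscombe correction is available behind a flag).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

Z_95 = 1.96

TRIPLE_COLUMNS = ["case", "drug_concept_id", "outcome_concept_id"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of one drug–outcome 2×2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalStatistics:
    prr: Optional[float]
    prr_ci_low: Optional[float]
    prr_ci_high: Optional[float]
    ror: Optional[float]
    ror_ci_low: Optional[float]
    ror_ci_high: Optional[float]
    case_count: int


def enumerate_triples(case_records: Iterable[tuple[str, Iterable[int], Iterable[int]]]
                      ) -> pd.DataFrame:
    """Build the triple universe from mapped, de-duplicated cases.

    ``case_records`` yields ``(case identifier, drug concept ids, outcome
    concept ids)`` per surviving case; unmapped entries must already be
    excluded.  Returns the distinct (case, drug, outcome) combinations.
    """
    rows = []
    for case, drug_ids, outcome_ids in case_records:
        for d in sorted(set(drug_ids)):
            for o in sorted(set(outcome_ids)):
                rows.append((case, d, o))
    df = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    return df.drop_duplicates(ignore_index=True)


def _cells(t) -> tuple[int, int, int, int]:
    if isinstance(t, ContingencyTable):
        return t.a, t.b, t.c, t.d
    return t


def _apply_haldane(a, b, c, d, haldane: bool):
    if haldane and min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def compute_prr(t, haldane: bool = False
                ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Proportional reporting ratio with 95% CI; nulls on zero cells.

    PRR requires a > 0, c > 0 (and hence both denominators positive).
    """
    a, b, c, d = _apply_haldane(*_cells(t), haldane)
    if a <= 0 or c <= 0:
        return (None, None, None)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo = math.exp(math.log(prr) - Z_95 * se)
    hi = math.exp(math.log(prr) + Z_95 * se)
    return (prr, lo, hi)


def compute_ror(t, haldane: bool = False
                ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Reporting odds ratio ad/(bc) with 95% CI; nulls on any zero cell."""
    a, b, c, d = _apply_haldane(*_cells(t), haldane)
    if min(a, b, c, d) <= 0:
        return (None, None, None)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z_95 * se)
    hi = math.exp(math.log(ror) + Z_95 * se)
    return (ror, lo, hi)


def compute_statistics(t, haldane: bool = False) -> SignalStatistics:
    prr, plo, phi = compute_prr(t, haldane)
    ror, rlo, rhi = compute_ror(t, haldane)
    a = _cells(t)[0]
    return SignalStatistics(prr, plo, phi, ror, rlo, rhi, case_count=a)


def _case_level_universe(triples: pd.DataFrame) -> pd.DataFrame:
    # distinct (case, drug) and (case, outcome) pairs; N = distinct cases
    return triples


def contingency_all(triples: pd.DataFrame,
                    counting_unit: str = "triple") -> pd.DataFrame:
    """Cell counts for every observed (drug, outcome) pair, vectorized.

    With the default triple counting unit, N is the universe size and
    the marginals are triple counts per drug / per outcome.  With
    ``counting_unit="case"``, a counts distinct cases reporting both D
    and O, the marginals count distinct cases per drug / outcome, and
    N is the number of distinct cases.
    """
    if counting_unit not in ("triple", "case"):
        raise ValueError(f"unknown counting unit {counting_unit!r}")
    if triples.empty:
        return pd.DataFrame(columns=["drug_concept_id", "outcome_concept_id",
                                     "a", "b", "c", "d"])
    if counting_unit == "triple":
        n_total = len(triples)
        a = (triples.groupby(["drug_concept_id", "outcome_concept_id"])
             .size().rename("a").reset_index())
        drug_tot = triples.groupby("drug_concept_id").size().rename("drug_total")
        out_tot = triples.groupby("outcome_concept_id").size().rename("outcome_total")
    else:
        n_total = triples["case"].nunique()
        a = (triples.groupby(["drug_concept_id", "outcome_concept_id"])["case"]
             .nunique().rename("a").reset_index())
        drug_tot = (triples.drop_duplicates(["case", "drug_concept_id"])
                    .groupby("drug_concept_id").size().rename("drug_total"))
        out_tot = (triples.drop_duplicates(["case", "outcome_concept_id"])
                   .groupby("outcome_concept_id").size().rename("outcome_total"))
    df = a.merge(drug_tot, on="drug_concept_id").merge(out_tot, on="outcome_concept_id")
    df["b"] = df["drug_total"] - df["a"]
    df["c"] = df["outcome_total"] - df["a"]
    df["d"] = n_total - df["a"] - df["b"] - df["c"]
    df = df.drop(columns=["drug_total", "outcome_total"])
    return df.sort_values(["drug_concept_id", "outcome_concept_id"],
                          ignore_index=True)


def build_contingency(triples: pd.DataFrame, drug_concept: int,
                      outcome_concept: int,
                      counting_unit: str = "triple") -> ContingencyTable:
    """2×2 table for one (drug, outcome) pair over the triple universe."""
    all_tables = contingency_all(triples, counting_unit)
    row = all_tables[(all_tables["drug_concept_id"] == drug_concept)
                     & (all_tables["outcome_concept_id"] == outcome_concept)]
    if row.empty:
        if counting_unit == "triple":
            n = len(triples)
            b = int((triples["drug_concept_id"] == drug_concept).sum())
            c = int((triples["outcome_concept_id"] == outcome_concept).sum())
        else:
            n = triples["case"].nunique() if not triples.empty else 0
            b = triples.loc[triples["drug_concept_id"] == drug_concept, "case"].nunique()
            c = triples.loc[triples["outcome_concept_id"] == outcome_concept, "case"].nunique()
        return ContingencyTable(a=0, b=b, c=c, d=n - b - c)
    r = row.iloc[0]
    return ContingencyTable(a=int(r["a"]), b=int(r["b"]), c=int(r["c"]), d=int(r["d"]))


def compute_all_statistics(triples: pd.DataFrame,
                           counting_unit: str = "triple",
                           haldane: bool = False) -> pd.DataFrame:
    """One row of cells + PRR/ROR (+95% CIs) per observed pair (a ≥ 1)."""
    cells = contingency_all(triples, counting_unit)
    records = []
    for r in cells.itertuples(index=False):
        t = ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
        s = compute_statistics(t, haldane)
        records.append({
            "drug_concept_id": r.drug_concept_id,
            "outcome_concept_id": r.outcome_concept_id,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "case_count": s.case_count,
            "prr": s.prr, "prr_ci_low": s.prr_ci_low, "prr_ci_high": s.prr_ci_high,
            "ror": s.ror, "ror_ci_low": s.ror_ci_low, "ror_ci_high": s.ror_ci_high,
        })
    columns = ["drug_concept_id", "outcome_concept_id", "a", "b", "c", "d",
               "case_count", "prr", "prr_ci_low", "prr_ci_high",
               "ror", "ror_ci_low", "ror_ci_high"]
    return pd.DataFrame(records, columns=columns)


# -- model/results surface ---------------------------------------------------

class DisproportionalityModel:
    """Disproportionality analysis of a triple universe.

    Parameters
    ----------
    triples : DataFrame with columns ``case, drug_concept_id,
        outcome_concept_id`` (one row per distinct triple), e.g. from
        :func:`enumerate_triples`.
    counting_unit : "triple" (default) or "case".
    continuity_correction : apply the 0.5 Haldane–Anscombe correction to
        tables with a zero cell (default off).
    """

    def __init__(self, triples: pd.DataFrame, counting_unit: str = "triple",
                 continuity_correction: bool = False):
        missing = [c for c in TRIPLE_COLUMNS if c not in triples.columns]
        if missing:
            raise ValueError(f"triples frame missing columns {missing}")
        if counting_unit not in ("triple", "case"):
            raise ValueError(f"unknown counting unit {counting_unit!r}")
        self.triples = triples.drop_duplicates(TRIPLE_COLUMNS, ignore_index=True)
        self.counting_unit = counting_unit
        self.continuity_correction = continuity_correction

    @classmethod
    def from_cases(cls, case_records, **kwargs) -> "DisproportionalityModel":
        return cls(enumerate_triples(case_records), **kwargs)

    def fit(self) -> "DisproportionalityResults":
        table = compute_all_statistics(self.triples, self.counting_unit,
                                       self.continuity_correction)
        return DisproportionalityResults(self, table)


class DisproportionalityResults:
    """Fitted PRR/ROR estimates with 95% CIs for every observed pair."""

    def __init__(self, model: DisproportionalityModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def universe_size(self) -> int:
        if self.table.empty:
            return 0
        first = self.table.iloc[0]
        return int(first["a"] + first["b"] + first["c"] + first["d"])

    def top(self, n: int = 10, by: str = "prr") -> pd.DataFrame:
        return (self.table.dropna(subset=[by])
                .sort_values(by, ascending=False).head(n))

    def summary(self, n: int = 10) -> str:
        lines = [
            "Disproportionality analysis",
            f"  counting unit : {self.model.counting_unit}",
            f"  universe size : {self.universe_size}",
            f"  pairs (a >= 1): {self.n_pairs}",
            "",
            f"Top {min(n, self.n_pairs)} pairs by PRR:",
            f"{'drug':>12} {'outcome':>12} {'a':>6} "
            f"{'PRR':>9} {'95% CI':>19} {'ROR':>9} {'95% CI':>19}",
        ]
        for r in self.top(n).itertuples(index=False):
            prr_ci = f"[{r.prr_ci_low:8.3f},{r.prr_ci_high:8.3f}]"
            ror_ci = (f"[{r.ror_ci_low:8.3f},{r.ror_ci_high:8.3f}]"
                      if r.ror is not None and not math.isnan(r.ror) else
                      f"{'--':>19}")
            ror_txt = (f"{r.ror:9.3f}"
                       if r.ror is not None and not math.isnan(r.ror)
                       else f"{'--':>9}")
            lines.append(
                f"{r.drug_concept_id:>12} {r.outcome_concept_id:>12} {r.a:>6} "
                f"{r.prr:9.3f} {prr_ci} {ror_txt} {ror_ci}")
        return "\n".join(lines)
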