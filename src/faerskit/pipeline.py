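"""End-to-end orchestration: parse → merge → impute → de-duplicate →
map → count → write the eight published output tables.

Every stage logs its input/output record counts (the run report mirrors a
count-based audit), and all outputs are written in a canonical sort order
so a run is byte-identical for identical inputs regardless of the record
order inside the source files.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

from . import dedup as dedup_mod
from . import io as io_mod
from . import merge as merge_mod
from . import stats as stats_mod
from . import vocab as vocab_mod
from .records import CaseVersion, SourceDialect

log = logging.getLogger(__name__)

OUTPUT_TABLES = tuple(io_mod.SCHEMAS)


@dataclass
class PipelineConfig:
    input_dir: str
    vocab_dir: str
    output_dir: str
    manual_map_path: Optional[str] = None
    delimiter: str = io_mod.DEFAULT_DELIMITER
    counting_unit: str = "triple"          # or "case"
    continuity_correction: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("input_dir", "vocab_dir"):
            path = getattr(self, name)
            if not os.path.isdir(path):
                raise FileNotFoundError(f"{name} does not exist: {path}")
        if self.manual_map_path and not os.path.exists(self.manual_map_path):
            raise FileNotFoundError(
                f"manual map does not exist: {self.manual_map_path}")
        if self.counting_unit not in ("triple", "case"):
            raise ValueError(f"unknown counting unit {self.counting_unit!r}")


@dataclass
class RunReport:
    """Per-stage record counts, mapping coverage and warnings of one run."""

    counts: dict[str, int] = field(default_factory=dict)
    coverage: dict[str, object] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"counts": self.counts, "coverage": self.coverage,
                       "warnings": self.warnings}, fh, indent=2, sort_keys=True)
            fh.write("\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sort_key(v: CaseVersion) -> tuple:
    return (v.caseid, v.case_key)


def _ids(v: CaseVersion) -> dict[str, object]:
    return {"primaryid": v.primaryid, "isr": v.isr, "caseid": v.caseid}


def _parse_stage(config: PipelineConfig) -> tuple[list[CaseVersion], int]:
    refs = io_mod.discover_quarter_files(config.input_dir, config.delimiter)
    demos = [r for r in refs if r.table_kind == "DEMO"]
    if not demos:
        raise FileNotFoundError(f"no DEMO quarterly files in {config.input_dir}")
    by_quarter: dict[tuple, dict[str, object]] = {}
    n_skipped = 0
    for ref in refs:
        if ref.table_kind in ("THER", "RPSR"):
            continue  # pass-through tables: no role in the curation
        table = io_mod.read_quarter_table(ref, config.delimiter)
        n_skipped += table.n_skipped
        by_quarter.setdefault((ref.dialect, ref.year, ref.quarter), {})[
            ref.table_kind] = table
    versions: list[CaseVersion] = []
    for key in sorted(by_quarter, key=lambda k: (k[0].value, k[1], k[2])):
        tables = by_quarter[key]
        if "DEMO" not in tables:
            continue
        versions.extend(merge_mod.assemble_case_versions(
            tables["DEMO"], tables.get("DRUG"), tables.get("REAC"),
            tables.get("INDI"), tables.get("OUTC")))
    return versions, n_skipped


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full curation + statistics run; returns the run report.

    Writes the eight ``standard_*`` tables, a de-duplication audit log
    and ``run_report.json`` to ``config.output_dir``.  Any stage failure
    raises :class:`PipelineError` naming the stage, after removing the
    partial outputs.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    report = RunReport()
    written: list[str] = []
    stage = "setup"

    def out(name: str) -> str:
        path = os.path.join(config.output_dir, name)
        written.append(path)
        return path

    try:
        stage = "io_faers"
        t0 = time.time()
        legacy_and_current, n_skipped = _parse_stage(config)
        legacy = [v for v in legacy_and_current
                  if v.dialect is SourceDialect.LEGACY]
        current = [v for v in legacy_and_current
                   if v.dialect is SourceDialect.CURRENT]
        report.counts["parsed_versions_legacy"] = len(legacy)
        report.counts["parsed_versions_current"] = len(current)
        report.counts["malformed_rows_skipped"] = n_skipped
        log.info("io_faers: %d legacy + %d current versions (%.2fs)",
                 len(legacy), len(current), time.time() - t0)

        stage = "merge_impute"
        merged = merge_mod.merge_datasets(legacy, current)
        report.counts["merged_versions"] = len(merged)
        merged = merge_mod.impute_all(merged)
        log.info("merge_impute: %d versions", len(merged))

        stage = "dedup"
        audit: list[dict] = []
        survivors = dedup_mod.deduplicate(merged, audit_log=audit)
        survivors.sort(key=_sort_key)
        report.counts["deduplicated_cases"] = len(survivors)
        log.info("dedup: %d surviving cases (%d removals)",
                 len(survivors), len(audit))
        with open(out("dedup_audit.tsv"), "w", encoding="utf-8") as fh:
            fh.write("caseid\tstage\treason\tsurvivor_caseid\tsurvivor_key\n")
            for entry in sorted(audit, key=lambda e: (e["caseid"], e["stage"])):
                fh.write("\t".join(str(entry[k]) for k in (
                    "caseid", "stage", "reason", "survivor_caseid",
                    "survivor_key")) + "\n")

        stage = "vocab_map"
        vocab = vocab_mod.Vocabulary.from_dir(config.vocab_dir)
        manual = (vocab_mod.load_manual_map(config.manual_map_path)
                  if config.manual_map_path else None)
        drug_results: dict[tuple, vocab_mod.MappingResult] = {}

        def map_drug(entry) -> vocab_mod.MappingResult:
            key = (entry.verbatim, entry.active_ingredient, entry.nda)
            if key not in drug_results:
                drug_results[key] = vocab_mod.map_drug_name(
                    entry.verbatim, entry.active_ingredient, entry.nda,
                    vocab, manual)
            return drug_results[key]

        pt_cache: dict[str, tuple] = {}

        def map_pt(pt: str) -> tuple:
            if pt not in pt_cache:
                pt_cache[pt] = vocab_mod.map_meddra_pt(pt, vocab)
            return pt_cache[pt]

        unique_results: dict[str, vocab_mod.MappingResult] = {}
        for v in survivors:
            for d in v.drugs:
                r = map_drug(d)
                unique_results.setdefault(d.verbatim, r)
        coverage = vocab_mod.coverage_report(unique_results.values(),
                                             survivors, vocab)
        report.coverage = coverage.as_dict()
        report.counts["unique_drug_strings"] = coverage.n_unique_drug_strings
        report.counts["mapped_drug_strings"] = coverage.n_mapped_drug_strings
        log.info("vocab_map: %d/%d unique drug strings mapped",
                 coverage.n_mapped_drug_strings, coverage.n_unique_drug_strings)

        stage = "write_case_tables"
        drug_rows, outcome_rows, category_rows, indication_rows = [], [], [], []
        for v in survivors:
            ids = _ids(v)
            for d in sorted(v.drugs, key=lambda d: (int(d.drug_seq)
                                                    if d.drug_seq.isdigit()
                                                    else 0, d.drug_seq)):
                r = map_drug(d)
                drug_rows.append(dict(ids, drug_seq=d.drug_seq,
                                      role_cod=d.role_code,
                                      drug_name=d.verbatim,
                                      standard_concept_id=(
                                          r.concept.concept_id if r.mapped
                                          else None)))
            for pt in sorted(set(v.reactions)):
                std, sno = map_pt(pt)
                outcome_rows.append(dict(ids, pt=pt, outcome_concept_id=std,
                                         snomed_outcome_concept_id=sno))
            for code in sorted(set(v.outcome_codes)):
                std, sno = map_pt(code)
                category_rows.append(dict(ids, outc_code=code,
                                          snomed_concept_id=sno))
            for seq, pt in sorted(set(v.indications)):
                std, sno = map_pt(pt)
                indication_rows.append(dict(ids, indi_drug_seq=seq, indi_pt=pt,
                                            indication_concept_id=std,
                                            snomed_indication_concept_id=sno))
        io_mod.write_standard_table(drug_rows, "standard_case_drug",
                                    out("standard_case_drug.tsv"))
        io_mod.write_standard_table(outcome_rows, "standard_case_outcome",
                                    out("standard_case_outcome.tsv"))
        io_mod.write_standard_table(category_rows,
                                    "standard_case_outcome_category",
                                    out("standard_case_outcome_category.tsv"))
        io_mod.write_standard_table(indication_rows, "standard_case_indication",
                                    out("standard_case_indication.tsv"))
        report.counts["case_drug_rows"] = len(drug_rows)
        report.counts["case_outcome_rows"] = len(outcome_rows)
        report.counts["case_indication_rows"] = len(indication_rows)

        stage = "signal_stats"
        case_records = []
        outcome_snomed: dict[int, int] = {}
        for v in survivors:
            drug_ids = {map_drug(d).concept.concept_id for d in v.drugs
                        if map_drug(d).mapped}
            out_ids = set()
            for pt in v.reactions:
                std, sno = map_pt(pt)
                if std is not None:
                    out_ids.add(std)
                    outcome_snomed[std] = sno
            case_records.append((v.caseid, drug_ids, out_ids))
        triples = stats_mod.enumerate_triples(case_records)
        report.counts["drug_outcome_triples"] = len(triples)
        model = stats_mod.DisproportionalityModel(
            triples, counting_unit=config.counting_unit,
            continuity_correction=config.continuity_correction)
        results = model.fit()
        table = results.table
        report.counts["drug_outcome_pairs"] = len(table)

        def fmt(x):
            return None if x is None or x != x else f"{x:.10g}"

        contingency_rows, count_rows, stat_rows = [], [], []
        for r in table.itertuples(index=False):
            pair = {"drug_concept_id": r.drug_concept_id,
                    "outcome_concept_id": r.outcome_concept_id}
            contingency_rows.append(dict(pair, count_a=r.a, count_b=r.b,
                                         count_c=r.c, count_d=r.d))
            count_rows.append(dict(pair, drug_outcome_pair_count=r.a))
            stat_rows.append(dict(pair, case_count=r.case_count,
                                  prr=fmt(r.prr), prr_95_ci_lower=fmt(r.prr_ci_low),
                                  prr_95_ci_upper=fmt(r.prr_ci_high),
                                  ror=fmt(r.ror), ror_95_ci_lower=fmt(r.ror_ci_low),
                                  ror_95_ci_upper=fmt(r.ror_ci_high)))
        io_mod.write_standard_table(
            contingency_rows, "standard_drug_outcome_contingency_table",
            out("standard_drug_outcome_contingency_table.tsv"))
        io_mod.write_standard_table(count_rows, "standard_drug_outcome_count",
                                    out("standard_drug_outcome_count.tsv"))
        io_mod.write_standard_table(stat_rows, "standard_drug_outcome_statistics",
                                    out("standard_drug_outcome_statistics.tsv"))
        by_caseid = {v.caseid: v for v in survivors}
        drilldown_rows = [
            {"drug_concept_id": t.drug_concept_id,
             "outcome_concept_id": t.outcome_concept_id,
             "snomed_outcome_concept_id": outcome_snomed.get(t.outcome_concept_id),
             **_ids(by_caseid[t.case])}
            for t in triples.sort_values(
                ["drug_concept_id", "outcome_concept_id", "case"]
            ).itertuples(index=False)
        ]
        io_mod.write_standard_table(drilldown_rows,
                                    "standard_drug_outcome_drilldown",
                                    out("standard_drug_outcome_drilldown.tsv"))

        stage = "report"
        report.to_json(out("run_report.json"))
        return report
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise PipelineError(stage, exc) from exc
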