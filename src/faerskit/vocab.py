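"""Mapping verbatim drug names and MedDRA preferred terms to standard
vocabulary concepts.

Drug strings map through an ordered chain of deterministic steps:

1. ``REGEX_EXACT`` — rule-based normalization of the verbatim name (see
   :func:`normalize_drug_name`), then exact lookup in the name table;
2. ``ACTIVE_INGREDIENT`` — the same lookup applied to the separate
   active-ingredient field carried by current-dialect DRUG rows;
3. ``NDA`` — the New Drug Application number, looked up in an orange-book
   style NDA→ingredient table;
4. ``MANUAL`` — an optional user-supplied verbatim-string→concept table
   (the stand-in for interactive curation of the residue).

Any hit on a non-standard concept (a brand name) is resolved through the
vocabulary's relationship table to its unique standard concept (an
ingredient, or a clinical drug form for multi-ingredient products).
Reaction and indication preferred terms map through a simplified
MedDRA-PT→SNOMED table; misses stay in the outputs with null concept ids.
"""
from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .records import CaseVersion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Concept:
    concept_id: int
    code: str
    vocabulary: str
    name: str
    standard: bool


class MappingMethod(str, Enum):
    REGEX_EXACT = "REGEX_EXACT"
    ACTIVE_INGREDIENT = "ACTIVE_INGREDIENT"
    NDA = "NDA"
    MANUAL = "MANUAL"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class MappingResult:
    source_text: str
    concept: Optional[Concept]
    method: MappingMethod

    @property
    def mapped(self) -> bool:
        return self.concept is not None


class VocabularyError(ValueError):
    """Inconsistent vocabulary bundle (dangling relationship endpoints etc.)."""


#: Bundle file names (tab-delimited, one header row each).
VOCAB_FILES = {
    "concept": "concept.tsv",                # concept_id code vocabulary name standard
    "name_lookup": "name_lookup.tsv",        # name concept_id
    "relationship": "relationship.tsv",      # concept_id standard_concept_id
    "pt_map": "pt_snomed_map.tsv",           # pt standard_concept_id snomed_concept_id
    "nda": "nda_ingredient.tsv",             # nda_num concept_id
}


@dataclass
class Vocabulary:
    """In-memory vocabulary bundle with validated cross-references."""

    concepts: dict[int, Concept]
    name_lookup: dict[str, int]                       # UPPER name -> concept_id
    relationship: dict[int, list[int]]                # non-standard -> standard ids
    pt_map: dict[str, tuple[int, int]]                # UPPER PT -> (standard, snomed)
    nda: dict[str, int]                               # NDA number -> concept_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, cid in self.name_lookup.items():
            if cid not in self.concepts:
                raise VocabularyError(f"name {name!r} points at unknown concept {cid}")
        for src, targets in self.relationship.items():
            if src not in self.concepts:
                raise VocabularyError(f"relationship source {src} not in concept table")
            for t in targets:
                if t not in self.concepts:
                    raise VocabularyError(
                        f"relationship target {t} (of {src}) not in concept table")
        for nda, cid in self.nda.items():
            if cid not in self.concepts:
                raise VocabularyError(f"NDA {nda} points at unknown concept {cid}")

    # -- loading -----------------------------------------------------------

    @classmethod
    def from_dir(cls, vocab_dir: str) -> "Vocabulary":
        def read(fname: str) -> list[list[str]]:
            path = os.path.join(vocab_dir, fname)
            if not os.path.exists(path):
                raise FileNotFoundError(f"vocabulary file missing: {path}")
            with open(path, "r", encoding="utf-8") as fh:
                lines = [ln.rstrip("\n") for ln in fh]
            return [ln.split("\t") for ln in lines[1:] if ln]

        concepts: dict[int, Concept] = {}
        for cid, code, vocabulary, name, standard in read(VOCAB_FILES["concept"]):
            concepts[int(cid)] = Concept(int(cid), code, vocabulary, name,
                                         standard.strip().upper() in ("Y", "S", "TRUE", "1"))
        name_lookup = {name.strip().upper(): int(cid)
                       for name, cid in read(VOCAB_FILES["name_lookup"])}
        relationship: dict[int, list[int]] = {}
        for src, dst in read(VOCAB_FILES["relationship"]):
            relationship.setdefault(int(src), []).append(int(dst))
        pt_map = {pt.strip().upper(): (int(std), int(sno))
                  for pt, std, sno in read(VOCAB_FILES["pt_map"])}
        nda = {num.strip(): int(cid) for num, cid in read(VOCAB_FILES["nda"])}
        return cls(concepts=concepts, name_lookup=name_lookup,
                   relationship=relationship, pt_map=pt_map, nda=nda)


def load_manual_map(path: str) -> dict[str, int]:
    """Read an optional user-supplied mapping file.

    Two tab-separated columns: verbatim drug string, concept id.  Keys are
    matched on the trimmed upper-cased verbatim string.
    """
    out: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            out[parts[0].strip().upper()] = int(parts[1])
    return out


# -- drug-name normalization -------------------------------------------------

_WHITESPACE_RE = re.compile(r"\s+")
_PAREN_RE = re.compile(r"\([^)]*\)")
#: Trailing tokens stripped one by one: bare numbers, number+unit (spaced
#: or fused), bare units, and dose-form words.
_TRAILING_TOKEN_RE = re.compile(
    r"^(?:\d+(?:\.\d+)?(?:MG|MCG|ML|G|IU|%)?|MG|MCG|ML|IU|%"
    r"|TABS?|TABLETS?|CAPS?|CAPSULES?|INJ|INJECTION|SOLUTION|SOLN)$"
)
_TRAILING_PUNCT_RE = re.compile(r"[.,;:\-/]+$")


def normalize_drug_name(raw: str) -> str:
    """Rule-based normalization of a verbatim drug name.

    Deterministic chain, applied in order: upper-case; trim; strip
    surrounding quotes; drop parenthesized groups; collapse internal
    whitespace; repeatedly strip trailing dose/form tokens (numbers,
    number+unit such as ``50 MG``/``100MG``, bare units, TAB/TABLET/
    CAP/CAPSULE/INJ/INJECTION/SOLUTION); strip trailing punctuation.
    Each rule is unit-tested; the full list is in the methods note.
    """
    text = raw.upper().strip()
    if len(text) >= 2 and text[0] in "\"'" and text[-1] == text[0]:
        text = text[1:-1].strip()
    text = _PAREN_RE.sub(" ", text)
    text = _WHITESPACE_RE.sub(" ", text).strip()
    tokens = text.split(" ")
    while len(tokens) > 1 and _TRAILING_TOKEN_RE.match(tokens[-1]):
        tokens.pop()
    text = " ".join(tokens)
    text = _TRAILING_PUNCT_RE.sub("", text).strip()
    return text


# -- concept resolution ------------------------------------------------------

def resolve_to_standard(c: Concept, vocab: Vocabulary) -> Optional[Concept]:
    """Follow a non-standard concept to its unique standard target.

    Standard concepts return unchanged.  A non-standard concept with zero
    or multiple standard targets is unresolvable: a warning is logged and
    ``None`` is returned (the string counts as unmapped rather than being
    mapped arbitrarily).
    """
    if c.standard:
        return c
    targets = [vocab.concepts[t] for t in vocab.relationship.get(c.concept_id, [])]
    standard_targets = [t for t in targets if t.standard]
    if len(standard_targets) != 1:
        log.warning("concept %d (%s) has %d standard targets; left unmapped",
                    c.concept_id, c.name, len(standard_targets))
        return None
    return standard_targets[0]


def _lookup_name(text: str | None, vocab: Vocabulary) -> Optional[Concept]:
    if not text:
        return None
    cid = vocab.name_lookup.get(normalize_drug_name(text))
    return vocab.concepts[cid] if cid is not None else None


def map_drug_name(raw: str,
                  active_ingredient: str | None,
                  nda: str | None,
                  vocab: Vocabulary,
                  manual_map: dict[str, int] | None = None) -> MappingResult:
    """Map one verbatim drug string through the stepwise chain.

    The first step that yields a concept wins and is recorded as the
    mapping method; brand-level hits resolve to their standard concept.
    """
    attempts: list[tuple[MappingMethod, Optional[Concept]]] = [
        (MappingMethod.REGEX_EXACT, _lookup_name(raw, vocab)),
        (MappingMethod.ACTIVE_INGREDIENT, _lookup_name(active_ingredient, vocab)),
    ]
    if nda and nda.strip() in vocab.nda:
        attempts.append((MappingMethod.NDA, vocab.concepts[vocab.nda[nda.strip()]]))
    if manual_map:
        cid = manual_map.get(raw.strip().upper())
        if cid is not None and cid in vocab.concepts:
            attempts.append((MappingMethod.MANUAL, vocab.concepts[cid]))
    for method, concept in attempts:
        if concept is None:
            continue
        standard = resolve_to_standard(concept, vocab)
        if standard is not None:
            return MappingResult(source_text=raw, concept=standard, method=method)
    return MappingResult(source_text=raw, concept=None, method=MappingMethod.UNMAPPED)


def map_meddra_pt(pt_text: str, vocab: Vocabulary
                  ) -> tuple[Optional[int], Optional[int]]:
    """Map a MedDRA preferred term to (standard concept id, SNOMED id).

    Lookup key is the trimmed upper-cased PT; misses return ``(None,
    None)`` and are retained downstream with null concept ids.
    """
    hit = vocab.pt_map.get(pt_text.strip().upper())
    return hit if hit is not None else (None, None)


# -- coverage ---------------------------------------------------------------

@dataclass
class CoverageReport:
    """Mapping-coverage summary over a pipeline run.

    Fractions are in [0, 1]; a ``None`` fraction means the denominator
    was zero (flagged rather than dividing).
    """

    n_unique_drug_strings: int = 0
    n_mapped_drug_strings: int = 0
    n_unique_drug_concepts: int = 0
    n_cases: int = 0
    n_cases_all_drugs_mapped: int = 0
    n_cases_any_drug_mapped: int = 0
    n_unique_reaction_pts: int = 0
    n_mapped_reaction_pts: int = 0
    n_unique_indication_pts: int = 0
    n_mapped_indication_pts: int = 0
    zero_denominators: list[str] = field(default_factory=list)

    @staticmethod
    def _frac(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    @property
    def drug_string_coverage(self) -> Optional[float]:
        return self._frac(self.n_mapped_drug_strings, self.n_unique_drug_strings)

    @property
    def case_all_drugs_mapped_fraction(self) -> Optional[float]:
        return self._frac(self.n_cases_all_drugs_mapped, self.n_cases)

    @property
    def case_any_drug_mapped_fraction(self) -> Optional[float]:
        return self._frac(self.n_cases_any_drug_mapped, self.n_cases)

    @property
    def reaction_pt_coverage(self) -> Optional[float]:
        return self._frac(self.n_mapped_reaction_pts, self.n_unique_reaction_pts)

    @property
    def indication_pt_coverage(self) -> Optional[float]:
        return self._frac(self.n_mapped_indication_pts, self.n_unique_indication_pts)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_unique_drug_strings", "n_mapped_drug_strings",
            "n_unique_drug_concepts", "n_cases", "n_cases_all_drugs_mapped",
            "n_cases_any_drug_mapped", "n_unique_reaction_pts",
            "n_mapped_reaction_pts", "n_unique_indication_pts",
            "n_mapped_indication_pts", "zero_denominators")}
        d.update({
            "drug_string_coverage": self.drug_string_coverage,
            "case_all_drugs_mapped_fraction": self.case_all_drugs_mapped_fraction,
            "case_any_drug_mapped_fraction": self.case_any_drug_mapped_fraction,
            "reaction_pt_coverage": self.reaction_pt_coverage,
            "indication_pt_coverage": self.indication_pt_coverage,
        })
        return d


def coverage_report(results: Iterable[MappingResult],
                    cases: Sequence[CaseVersion],
                    vocab: Vocabulary) -> CoverageReport:
    """Summarize mapping coverage over unique strings and over cases.

    ``results`` holds one MappingResult per unique verbatim drug string;
    PT coverage is recomputed from the unique reaction/indication terms
    of ``cases`` against the simplified PT table.
    """
    rep = CoverageReport()
    by_string: dict[str, MappingResult] = {}
    for r in results:
        by_string.setdefault(r.source_text, r)
    rep.n_unique_drug_strings = len(by_string)
    mapped = [r for r in by_string.values() if r.mapped]
    rep.n_mapped_drug_strings = len(mapped)
    rep.n_unique_drug_concepts = len({r.concept.concept_id for r in mapped})

    rep.n_cases = len(cases)
    for v in cases:
        if not v.drugs:
            continue
        flags = [by_string.get(d.verbatim, None) is not None
                 and by_string[d.verbatim].mapped for d in v.drugs]
        if all(flags):
            rep.n_cases_all_drugs_mapped += 1
        if any(flags):
            rep.n_cases_any_drug_mapped += 1

    reaction_pts = {pt.strip().upper() for v in cases for pt in v.reactions}
    indication_pts = {pt.strip().upper() for v in cases for _, pt in v.indications}
    rep.n_unique_reaction_pts = len(reaction_pts)
    rep.n_mapped_reaction_pts = sum(pt in vocab.pt_map for pt in reaction_pts)
    rep.n_unique_indication_pts = len(indication_pts)
    rep.n_mapped_indication_pts = sum(pt in vocab.pt_map for pt in indication_pts)

    for name, den in (("drug_strings", rep.n_unique_drug_strings),
                      ("cases", rep.n_cases),
                      ("reaction_pts", rep.n_unique_reaction_pts),
                      ("indication_pts", rep.n_unique_indication_pts)):
        if den == 0:
            rep.zero_denominators.append(name)
    return rep
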