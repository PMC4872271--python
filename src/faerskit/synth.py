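"""Ground-truthed miniature FAERS/LAERS corpus and fixture vocabulary.

The generator emits quarterly "$"-delimited files in both source dialects
(legacy ``ISR``/``CASE`` keys, current ``primaryid``/``caseid`` keys)
together with a small internally consistent vocabulary bundle, so every
downstream stage — parsing, merging, imputation, de-duplication, drug and
PT mapping, signal statistics — can be tested end to end without any
download.  Emulated phenomena:

* multi-version cases (initial ``I`` plus follow-up ``F`` submissions);
* cases present in both the legacy and the current data set;
* single and double missing demographic fields;
* "orphan" duplicates: the same report re-filed under a different case
  number with an identical demographic key;
* drug-name variants — brand names, trailing dose/form tokens,
  misspellings (deliberately unmappable), NDA-number strings, and
  current-dialect rows mappable only via the active-ingredient field;
* MedDRA PT strings with a configurable mapped fraction.

:class:`GroundTruth` records which case version survives the curation
rules and what every emitted drug string / PT should map to.  The
surviving-case computation here is a second, structurally independent
implementation of the imputation and de-duplication rules operating on
the generator's internal records; it never calls the ``merge`` or
``dedup`` modules, so it can serve as an oracle for them.
"""
from __future__ import annotations

import datetime
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .records import QuarterFileRef, SourceDialect
from .vocab import VOCAB_FILES, Concept, Vocabulary

UNMAPPABLE = "UNMAPPABLE"
UNMAPPED = "UNMAPPED"

LEGACY_QUARTERS = [(2011, 3), (2011, 4), (2012, 1)]
CURRENT_QUARTERS = [(2012, 4), (2013, 1), (2013, 2)]

#: (legacy name-style spelling, current code) — all resolvable by the
#: bundled country table so the two dialects normalize identically.
SYN_COUNTRIES = [
    ("UNITED STATES", "US"), ("UNITED KINGDOM", "GB"), ("JAPAN", "JP"),
    ("GERMANY", "DE"), ("FRANCE", "FR"), ("CANADA", "CA"), ("ITALY", "IT"),
    ("SPAIN", "ES"), ("AUSTRALIA", "AU"), ("BRAZIL", "BR"),
]

OUTCOME_CODES = ["DE", "LT", "HO", "DS", "CA", "RI", "OT"]

_SYLLABLES = ["VAR", "NOL", "TEP", "MIR", "ZOL", "DAK", "FEN", "RUX", "PAM",
              "LOT", "QUE", "SIB", "TRA", "VEL", "XAN", "COR", "DEL", "GRI"]
_ING_SUFFIX = ["MAB", "PRIL", "OLOL", "STAT", "CEPT", "VIR", "ZINE", "IDE"]
_BRAND_SUFFIX = ["EX", "IA", "ON", "ULE", "ARA", "IVO"]
_PT_FIRST = ["Injection site", "Application site", "Abdominal", "Cardiac",
             "Renal", "Hepatic", "Skin", "Ocular", "Muscle", "Joint"]
_PT_SECOND = ["pain", "erythema", "failure", "rash", "oedema", "haemorrhage",
              "disorder", "swelling", "necrosis", "discomfort", "spasm",
              "pruritus"]

_DOSE_TEMPLATES = [
    "{n} 50 MG", "{n} 100MG", "{n} (10 MG)", "{n} TABLET", "{n} TAB",
    "{n} 50 MG TABLET", '"{n}"', "{n} SOLUTION", "{n} CAPSULE", "{n} 2.5 MG",
]


@dataclass
class VariantRates:
    """Probabilities of the drug-string variant classes (rest: plain name)."""

    brand: float = 0.25
    dose_suffix: float = 0.20
    misspelling: float = 0.05
    nda: float = 0.10

    def total(self) -> float:
        return self.brand + self.dose_suffix + self.misspelling + self.nda


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic corpus.

    Defaults are chosen to exercise every comparison path of the pipeline
    at realistic-looking intensities: roughly a third of cases have
    follow-up versions, a modest minority appear in both data sets, and
    missingness/duplication rates are small but non-negligible.
    """

    n_cases: int = 200
    followup_rate: float = 0.35
    cross_dataset_rate: float = 0.15
    missing_one_rate: float = 0.20
    missing_two_rate: float = 0.07
    orphan_duplicate_rate: float = 0.05
    n_ingredients: int = 12
    variant_rates: VariantRates = field(default_factory=VariantRates)
    ai_fallback_rate: float = 0.08   # current-dialect rows mappable only via prod_ai
    n_pts: int = 30
    pt_mapped_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "followup_rate": self.followup_rate,
            "cross_dataset_rate": self.cross_dataset_rate,
            "missing_one_rate": self.missing_one_rate,
            "missing_two_rate": self.missing_two_rate,
            "orphan_duplicate_rate": self.orphan_duplicate_rate,
            "ai_fallback_rate": self.ai_fallback_rate,
            "pt_mapped_fraction": self.pt_mapped_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.missing_one_rate + self.missing_two_rate > 1.0:
            raise ValueError("missing_one_rate + missing_two_rate exceeds 1")
        if self.variant_rates.total() > 1.0:
            raise ValueError("variant rates sum exceeds 1")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.n_ingredients < 1:
            raise ValueError("n_ingredients must be >= 1")


@dataclass
class GroundTruth:
    """What the curation rules should produce on this corpus."""

    #: step-1 winner per case id: caseid -> its dialect-native row key
    latest_version_of_case: dict[str, str] = field(default_factory=dict)
    #: case ids surviving both de-duplication steps
    surviving_cases: set[str] = field(default_factory=set)
    #: verbatim drug string -> standard concept id, or "UNMAPPABLE"
    drug_string_truth: dict[str, object] = field(default_factory=dict)
    #: emitted PT string -> SNOMED concept id, or "UNMAPPED"
    pt_truth: dict[str, object] = field(default_factory=dict)


@dataclass
class FixtureVocabulary:
    """The fixture vocabulary bundle plus its construction ground truth."""

    vocab: Vocabulary
    ingredients: list[Concept]
    #: brand name -> (brand concept id, standard target concept id)
    brands: dict[str, tuple[int, int]]
    #: ingredient concept id -> NDA number (subset of ingredients)
    nda_numbers: dict[int, str]
    pts: list[str]
    #: PT text -> (standard concept id, snomed concept id) or None
    pt_mapping: dict[str, Optional[tuple[int, int]]]


# ---------------------------------------------------------------------------
# fixture vocabulary

def _unique_name(rng: random.Random, used: set[str], syllables: int,
                 suffixes: list[str]) -> str:
    while True:
        name = "".join(rng.choice(_SYLLABLES) for _ in range(syllables))
        name += rng.choice(suffixes)
        if name not in used:
            used.add(name)
            return name


def generate_fixture_vocabulary(config: SyntheticConfig,
                                out_dir: str | None = None) -> FixtureVocabulary:
    """Build a miniature internally consistent vocabulary bundle.

    Standard ingredient concepts plus non-standard brand concepts that
    each relate to exactly one standard target; if at least two
    ingredients exist, one multi-ingredient brand resolves to a standard
    clinical-drug-form concept.  ``round(pt_mapped_fraction * n_pts)`` of
    the PT strings receive a SNOMED mapping row; the seven FDA outcome
    category codes are always mapped.  Writes the five tab-delimited
    bundle files when ``out_dir`` is given.
    """
    config.validate()
    rng = random.Random(config.seed)
    used_names: set[str] = set()

    concepts: dict[int, Concept] = {}
    name_lookup: dict[str, int] = {}
    relationship: dict[int, list[int]] = {}
    pt_map: dict[str, tuple[int, int]] = {}
    nda: dict[str, int] = {}

    ingredients: list[Concept] = []
    for i in range(config.n_ingredients):
        cid = 1_000_000 + i
        name = _unique_name(rng, used_names, 3, _ING_SUFFIX)
        c = Concept(cid, f"RX{10000 + i}", "RxNorm", name, standard=True)
        concepts[cid] = c
        name_lookup[name] = cid
        ingredients.append(c)

    brands: dict[str, tuple[int, int]] = {}
    brand_cid = 2_000_000
    for ing in ingredients:
        if rng.random() < 0.7:
            bname = _unique_name(rng, used_names, 2, _BRAND_SUFFIX)
            c = Concept(brand_cid, f"RXB{brand_cid}", "RxNorm", bname, standard=False)
            concepts[brand_cid] = c
            name_lookup[bname] = brand_cid
            relationship[brand_cid] = [ing.concept_id]
            brands[bname] = (brand_cid, ing.concept_id)
            brand_cid += 1

    if len(ingredients) >= 2:
        # one multi-ingredient product: brand -> standard clinical drug form
        pair = rng.sample(ingredients, 2)
        cdf_cid = 3_000_000
        cdf = Concept(cdf_cid, f"RXC{cdf_cid}", "RxNorm",
                      f"{pair[0].name} / {pair[1].name} ORAL TABLET", standard=True)
        concepts[cdf_cid] = cdf
        bname = _unique_name(rng, used_names, 2, _BRAND_SUFFIX)
        bc = Concept(brand_cid, f"RXB{brand_cid}", "RxNorm", bname, standard=False)
        concepts[brand_cid] = bc
        name_lookup[bname] = brand_cid
        relationship[brand_cid] = [cdf_cid]
        brands[bname] = (brand_cid, cdf_cid)

    nda_numbers: dict[int, str] = {}
    for i, ing in enumerate(ingredients):
        if rng.random() < 0.6:
            num = f"{20000 + i}"
            nda[num] = ing.concept_id
            nda_numbers[ing.concept_id] = num

    # MedDRA preferred terms
    combos = [(a, b) for a in _PT_FIRST for b in _PT_SECOND]
    if config.n_pts > len(combos):
        raise ValueError(f"n_pts must be <= {len(combos)}")
    pts = [f"{a} {b}" for a, b in rng.sample(combos, config.n_pts)]
    n_mapped = round(config.pt_mapped_fraction * config.n_pts)
    mapped_idx = sorted(rng.sample(range(config.n_pts), n_mapped))
    pt_mapping: dict[str, Optional[tuple[int, int]]] = {pt: None for pt in pts}
    for j, i in enumerate(mapped_idx):
        std_cid = 40_000_000 + j
        sno_cid = 90_000_000 + j
        concepts[std_cid] = Concept(std_cid, f"S{sno_cid}", "SNOMED",
                                    pts[i], standard=True)
        pt_map[pts[i].upper()] = (std_cid, sno_cid)
        pt_mapping[pts[i]] = (std_cid, sno_cid)
    for j, code in enumerate(OUTCOME_CODES):
        std_cid = 45_000_000 + j
        sno_cid = 95_000_000 + j
        concepts[std_cid] = Concept(std_cid, f"S{sno_cid}", "SNOMED",
                                    f"Outcome category {code}", standard=True)
        pt_map[code] = (std_cid, sno_cid)

    vocab = Vocabulary(concepts=concepts, name_lookup=name_lookup,
                       relationship=relationship, pt_map=pt_map, nda=nda)
    fixture = FixtureVocabulary(vocab=vocab, ingredients=ingredients,
                                brands=brands, nda_numbers=nda_numbers,
                                pts=pts, pt_mapping=pt_mapping)
    if out_dir is not None:
        write_vocabulary(fixture.vocab, out_dir)
    return fixture


def write_vocabulary(vocab: Vocabulary, out_dir: str) -> None:
    """Write the bundle as five tab-delimited tables."""
    os.makedirs(out_dir, exist_ok=True)

    def write(fname: str, header: list[str], rows: list[list]) -> None:
        with open(os.path.join(out_dir, fname), "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

    write(VOCAB_FILES["concept"],
          ["concept_id", "code", "vocabulary", "name", "standard"],
          [[c.concept_id, c.code, c.vocabulary, c.name, "Y" if c.standard else "N"]
           for c in sorted(vocab.concepts.values(), key=lambda c: c.concept_id)])
    write(VOCAB_FILES["name_lookup"], ["name", "concept_id"],
          [[n, cid] for n, cid in sorted(vocab.name_lookup.items())])
    write(VOCAB_FILES["relationship"], ["concept_id", "standard_concept_id"],
          [[src, dst] for src in sorted(vocab.relationship)
           for dst in vocab.relationship[src]])
    write(VOCAB_FILES["pt_map"], ["pt", "standard_concept_id", "snomed_concept_id"],
          [[pt, std, sno] for pt, (std, sno) in sorted(vocab.pt_map.items())])
    write(VOCAB_FILES["nda"], ["nda_num", "concept_id"],
          [[num, cid] for num, cid in sorted(vocab.nda.items())])


# ---------------------------------------------------------------------------
# corpus

@dataclass
class _SimVersion:
    caseid: str
    dialect: SourceDialect
    key: str                     # isr or primaryid, numeric text
    year: int
    quarter: int
    i_f: str
    # rendered DEMO fields ("" = missing)
    event_dt: str
    age: str
    age_cod: str
    sex: str
    country: str                 # name-style for legacy, code for current
    # normalized truth values (None = missing); independent of merge module
    true_date: Optional[str]
    true_age: Optional[float]
    true_sex: Optional[str]
    true_country: Optional[str]


@dataclass
class _SimCase:
    caseid: str
    versions: list[_SimVersion]
    drugs: list[tuple[str, str, str, Optional[str], Optional[str]]]
    # (drug_seq, role, verbatim, prod_ai, nda_num)
    reactions: list[str]
    indications: list[tuple[str, str]]
    outcomes: list[str]


def _pad_date(text: str) -> str:
    return text + "01" * ((8 - len(text)) // 2)


def _render_age(rng: random.Random, age: int) -> tuple[str, str]:
    r = rng.random()
    if r < 0.15:
        return str(age * 12), "MON"
    if r < 0.20 and age % 10 == 0:
        return str(age // 10), "DEC"
    if r < 0.22:
        return str(age), ""        # blank unit code: read as years
    return str(age), "YR"


class _CorpusBuilder:
    def __init__(self, config: SyntheticConfig, fixture: FixtureVocabulary):
        config.validate()
        self.config = config
        self.fx = fixture
        self.rng = random.Random(config.seed + 1)
        self.truth = GroundTruth()
        self.cases: list[_SimCase] = []
        self._isr = 4_000_000
        self._pid = 100_000_000
        self._case_no = 900_000
        self._ai_counter = 0
        self._used_strings: set[str] = set(fixture.vocab.name_lookup)

    # -- drug strings -------------------------------------------------------

    def _misspell(self, name: str) -> str:
        rng = self.rng
        for _ in range(20):
            i = rng.randrange(len(name) - 1)
            if rng.random() < 0.5:
                cand = name[:i] + name[i + 1] + name[i] + name[i + 2:]
            else:
                cand = name[:i] + name[i + 1:]
            if cand not in self._used_strings:
                break
        else:
            cand = name + "XQ"
        self._used_strings.add(cand)
        return cand

    def _drug_entry(self, seq: int, role: str, in_current: bool
                    ) -> tuple[str, str, str, Optional[str], Optional[str]]:
        rng, fx, vr = self.rng, self.fx, self.config.variant_rates
        ing = rng.choice(fx.ingredients)
        verbatim, ai, nda_num = ing.name, None, None
        truth: object = ing.concept_id

        r = rng.random()
        if r < vr.brand:
            branded = [(b, tgt) for b, (_, tgt) in fx.brands.items()]
            bname, tgt = branded[rng.randrange(len(branded))]
            verbatim, truth = bname, tgt
            if rng.random() < 0.3:
                verbatim = rng.choice(_DOSE_TEMPLATES).format(n=bname)
        elif r < vr.brand + vr.dose_suffix:
            verbatim = rng.choice(_DOSE_TEMPLATES).format(n=ing.name)
        elif r < vr.brand + vr.dose_suffix + vr.misspelling:
            verbatim, truth = self._misspell(ing.name), UNMAPPABLE
        elif r < vr.total():
            num = fx.nda_numbers.get(ing.concept_id)
            if num is not None:
                verbatim, nda_num = f"PRODUCT {num}", num
            # ingredient without an NDA number: keep the plain name
        if in_current and rng.random() < self.config.ai_fallback_rate:
            self._ai_counter += 1
            verbatim = f"UNSPECIFIED PRODUCT {self._ai_counter}"
            ai, nda_num, truth = ing.name, None, ing.concept_id
        elif in_current and truth is not UNMAPPABLE and rng.random() < 0.5:
            # incidental prod_ai on an already-mappable row; never on
            # misspellings, whose truth is constructed as unmappable
            ai = ing.name

        existing = self.truth.drug_string_truth.get(verbatim)
        if existing is not None and existing != truth:
            # same text would carry two truths; disambiguate misspellings
            verbatim = verbatim + "QX"
            truth = UNMAPPABLE
        self.truth.drug_string_truth[verbatim] = truth
        return (str(seq), role, verbatim, ai, nda_num)

    # -- cases --------------------------------------------------------------

    def _next_caseid(self) -> str:
        self._case_no += 1
        return str(self._case_no)

    def _base_demo(self) -> tuple[str, int, str, tuple[str, str]]:
        rng = self.rng
        start = datetime.date(2012, 1, 1).toordinal()
        date = datetime.date.fromordinal(start + rng.randrange(730))
        return (date.strftime("%Y%m%d"), rng.randrange(0, 101),
                rng.choice("MF"), rng.choice(SYN_COUNTRIES))

    def _content(self) -> tuple[list, list, list, list]:
        rng = self.rng
        n_drugs = rng.randint(1, 5)
        roles = ["PS"] + [rng.choice(["SS", "C", "I"]) for _ in range(n_drugs - 1)]
        drugs = [self._drug_entry(i + 1, roles[i], self._case_in_current)
                 for i in range(n_drugs)]
        reactions = rng.sample(self.fx.pts, rng.randint(1, min(5, len(self.fx.pts))))
        for pt in reactions:
            mapping = self.fx.pt_mapping[pt]
            self.truth.pt_truth[pt] = mapping[1] if mapping else UNMAPPED
        indications = []
        for seq, _, _, _, _ in drugs:
            for pt in rng.sample(self.fx.pts,
                                 rng.randint(0, min(2, len(self.fx.pts)))):
                indications.append((seq, pt))
                mapping = self.fx.pt_mapping[pt]
                self.truth.pt_truth[pt] = mapping[1] if mapping else UNMAPPED
        outcomes = rng.sample(OUTCOME_CODES, rng.randint(0, 2))
        return drugs, reactions, indications, outcomes

    def _make_version(self, caseid: str, dialect: SourceDialect, i_f: str,
                      quarter_idx: int, demo: tuple) -> _SimVersion:
        rng = self.rng
        date_s, age, sex, (cname, ccode) = demo
        if dialect is SourceDialect.LEGACY:
            self._isr += 1
            key = str(self._isr)
            year, q = LEGACY_QUARTERS[min(quarter_idx, len(LEGACY_QUARTERS) - 1)]
            country_render = cname
        else:
            self._pid += 1
            key = str(self._pid)
            year, q = CURRENT_QUARTERS[min(quarter_idx, len(CURRENT_QUARTERS) - 1)]
            country_render = ccode

        date_render = date_s[:6] if rng.random() < 0.05 else date_s
        age_render, age_cod = _render_age(rng, age)

        true = {
            "date": _pad_date(date_render),
            "age": float(age),
            "sex": sex,
            "country": ccode,
        }
        render = {"date": date_render, "age": age_render, "age_cod": age_cod,
                  "sex": sex, "country": country_render}

        r = rng.random()
        n_blank = 2 if r < self.config.missing_two_rate else (
            1 if r < self.config.missing_two_rate + self.config.missing_one_rate
            else 0)
        if n_blank:
            for fieldname in rng.sample(["date", "age", "sex", "country"], n_blank):
                true[fieldname] = None
                render[fieldname] = ""
                if fieldname == "age":
                    render["age_cod"] = ""

        return _SimVersion(
            caseid=caseid, dialect=dialect, key=key, year=year, quarter=q,
            i_f=i_f, event_dt=render["date"], age=render["age"],
            age_cod=render["age_cod"], sex=render["sex"],
            country=render["country"],
            true_date=true["date"], true_age=true["age"],
            true_sex=true["sex"], true_country=true["country"],
        )

    def _build_case(self, demo: tuple | None = None,
                    force_dialects: tuple | None = None) -> _SimCase:
        rng, cfg = self.rng, self.config
        caseid = self._next_caseid()
        base_demo = demo if demo is not None else self._base_demo()

        if force_dialects is not None:
            dialects = force_dialects
        elif rng.random() < cfg.cross_dataset_rate:
            dialects = (SourceDialect.LEGACY, SourceDialect.CURRENT)
        else:
            dialects = (rng.choice((SourceDialect.LEGACY, SourceDialect.CURRENT)),)
        self._case_in_current = SourceDialect.CURRENT in dialects

        drugs, reactions, indications, outcomes = self._content()

        n_extra = (1 if rng.random() < cfg.followup_rate else 0)
        n_extra += (1 if rng.random() < cfg.followup_rate * 0.4 else 0)
        if len(dialects) == 2 and n_extra == 0:
            n_extra = 1  # a cross-dataset case needs a version in each set

        versions: list[_SimVersion] = []
        codes = ["I"] + ["F"] * n_extra
        if len(dialects) == 2:
            n_legacy = max(1, len(codes) - 1)
            plan = ([(SourceDialect.LEGACY, i) for i in range(n_legacy)]
                    + [(SourceDialect.CURRENT, i)
                       for i in range(len(codes) - n_legacy)])
        else:
            plan = [(dialects[0], i) for i in range(len(codes))]
        for (dialect, qidx), code in zip(plan, codes):
            vdemo = base_demo
            if code == "F" and rng.random() < 0.15:
                # follow-up corrects the age: differing content signature
                vdemo = (base_demo[0], min(base_demo[1] + 1, 100),
                         base_demo[2], base_demo[3])
            versions.append(self._make_version(caseid, dialect, code, qidx, vdemo))

        case = _SimCase(caseid=caseid, versions=versions, drugs=drugs,
                        reactions=reactions, indications=indications,
                        outcomes=outcomes)
        self.cases.append(case)
        return case

    def build(self) -> None:
        for _ in range(self.config.n_cases):
            case = self._build_case()
            if self.rng.random() < self.config.orphan_duplicate_rate:
                # same report re-filed under a new case number: copy the
                # first version's demographics where complete, else draw fresh
                base = case.versions[0]
                demo = None
                pair = next(((n, c) for n, c in SYN_COUNTRIES
                             if c == base.true_country), None)
                if (base.true_date and base.true_age is not None
                        and base.true_sex and pair):
                    demo = (base.true_date, int(base.true_age),
                            base.true_sex, pair)
                self._build_case(demo=demo,
                                 force_dialects=(self.rng.choice(
                                     (SourceDialect.LEGACY, SourceDialect.CURRENT)),))

    # -- independent ground-truth curation ----------------------------------

    def compute_ground_truth(self) -> None:
        """Direct application of the stated curation rules.

        Re-derives imputation, latest-version selection and the
        demographic-key collapse from the generator's internal records;
        shares no code with the pipeline modules.
        """
        def demo_tuple(v: _SimVersion):
            age = None if v.true_age is None else round(v.true_age, 4)
            return [v.true_date, age, v.true_sex, v.true_country]

        def precedence(v: _SimVersion):
            return (1 if v.dialect is SourceDialect.CURRENT else 0,
                    int(v.key), (v.year, v.quarter))

        winners: list[tuple[_SimVersion, list]] = []
        for case in self.cases:
            demos = {id(v): demo_tuple(v) for v in case.versions}
            full = [d for d in demos.values() if None not in d]
            if full:
                donor = [max(col) for col in zip(*full)]
                for d in demos.values():
                    missing = [i for i, x in enumerate(d) if x is None]
                    if len(missing) == 1:
                        d[missing[0]] = donor[missing[0]]
            winner = max(case.versions, key=precedence)
            winners.append((winner, demos[id(winner)]))
            self.truth.latest_version_of_case[case.caseid] = winner.key

        groups: dict[tuple, list[_SimVersion]] = {}
        surviving = set()
        for v, d in winners:
            if None in d:
                surviving.add(v.caseid)
            else:
                groups.setdefault(tuple(d), []).append(v)
        for members in groups.values():
            surviving.add(max(members, key=precedence).caseid)
        self.truth.surviving_cases = surviving


# -- file rendering ----------------------------------------------------------

_HEADERS = {
    SourceDialect.LEGACY: {
        "DEMO": "ISR$CASE$I_F_COD$EVENT_DT$AGE$AGE_COD$GNDR_COD$REPORTER_COUNTRY",
        "DRUG": "ISR$DRUG_SEQ$ROLE_COD$DRUGNAME$NDA_NUM",
        "REAC": "ISR$PT",
        "INDI": "ISR$DRUG_SEQ$INDI_PT",
        "OUTC": "ISR$OUTC_COD",
        "THER": "ISR$DSG_DRUG_SEQ$START_DT$END_DT",
        "RPSR": "ISR$RPSR_COD",
    },
    SourceDialect.CURRENT: {
        "DEMO": "primaryid$caseid$i_f_code$event_dt$age$age_cod$sex$reporter_country",
        "DRUG": "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$nda_num",
        "REAC": "primaryid$caseid$pt",
        "INDI": "primaryid$caseid$indi_drug_seq$indi_pt",
        "OUTC": "primaryid$caseid$outc_cod",
        "THER": "primaryid$caseid$dsg_drug_seq$start_dt$end_dt",
        "RPSR": "primaryid$caseid$rpsr_cod",
    },
}


def _version_rows(case: _SimCase, v: _SimVersion) -> dict[str, list[str]]:
    if v.dialect is SourceDialect.LEGACY:
        head = [v.key]
        demo = [v.key, case.caseid, v.i_f, v.event_dt, v.age, v.age_cod,
                v.sex, v.country]
        drug = [head + [seq, role, name, nda or ""]
                for seq, role, name, _, nda in case.drugs]
        indi = [head + [seq, pt] for seq, pt in case.indications]
    else:
        head = [v.key, case.caseid]
        demo = [v.key, case.caseid, v.i_f, v.event_dt, v.age, v.age_cod,
                v.sex, v.country]
        drug = [head + [seq, role, name, ai or "", nda or ""]
                for seq, role, name, ai, nda in case.drugs]
        indi = [head + [seq, pt] for seq, pt in case.indications]
    return {
        "DEMO": [demo],
        "DRUG": drug,
        "REAC": [head + [pt] for pt in case.reactions],
        "INDI": indi,
        "OUTC": [head + [code] for code in case.outcomes],
    }


def generate_corpus(config: SyntheticConfig, fixture: FixtureVocabulary,
                    out_dir: str) -> tuple[list[QuarterFileRef], GroundTruth]:
    """Write the quarterly files of a seeded synthetic corpus.

    Returns the file references and the independently computed
    :class:`GroundTruth`.  Identical config (including seed) produces
    byte-identical files.
    """
    builder = _CorpusBuilder(config, fixture)
    builder.build()
    builder.compute_ground_truth()

    buckets: dict[tuple[SourceDialect, int, int], dict[str, list[list[str]]]] = {}
    quarters = ([(SourceDialect.LEGACY, y, q) for y, q in LEGACY_QUARTERS]
                + [(SourceDialect.CURRENT, y, q) for y, q in CURRENT_QUARTERS])
    for key in quarters:
        buckets[key] = {kind: [] for kind in ("DEMO", "DRUG", "REAC", "INDI", "OUTC")}
    for case in builder.cases:
        for v in case.versions:
            rows = _version_rows(case, v)
            bucket = buckets[(v.dialect, v.year, v.quarter)]
            for kind, kind_rows in rows.items():
                bucket[kind].extend(kind_rows)

    os.makedirs(out_dir, exist_ok=True)
    refs: list[QuarterFileRef] = []
    for (dialect, year, q), tables in buckets.items():
        for kind in ("DEMO", "DRUG", "REAC", "INDI", "OUTC", "THER", "RPSR"):
            fname = f"{kind}{year % 100:02d}Q{q}.txt"
            path = os.path.join(out_dir, fname)
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(_HEADERS[dialect][kind] + "\n")
                for row in tables.get(kind, []):
                    fh.write("$".join(row) + "\n")
            refs.append(QuarterFileRef(table_kind=kind, year=year, quarter=q,
                                       dialect=dialect, path=path))
    return refs, builder.truth


def generate_all(config: SyntheticConfig, out_dir: str
                 ) -> tuple[FixtureVocabulary, list[QuarterFileRef], GroundTruth]:
    """Generate vocabulary (``vocab/``) and corpus (``data/``) under one root."""
    fixture = generate_fixture_vocabulary(config,
                                          out_dir=os.path.join(out_dir, "vocab"))
    refs, truth = generate_corpus(config, fixture, os.path.join(out_dir, "data"))
    return fixture, refs, truth
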