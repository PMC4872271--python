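# Methods

This note documents the curation and signal-detection procedure
implemented by `faerskit`, the choices made where the published
processing conventions for spontaneous-report data leave room, and what
the synthetic test corpus does and does not establish.

## Source data model

A *case* is one adverse-event report; each submission of it (initial
`I`, follow-ups `F`) is a *case version* appearing as one DEMO row in
some quarterly file.  The legacy distribution (LAERS, reports up to
August 2012) keys rows by `isr`/`case`; the current distribution (FAERS)
by `primaryid`/`caseid`.  Files are "$"-delimited text with one header
row; `faerskit` detects the dialect from the header key column alone.
Legacy quarters contain bytes that are not valid UTF-8, so source files
are read as Latin-1 with replacement; all outputs are UTF-8,
tab-delimited, with a fixed column order per table.  At the raw layer
the empty string is the missing marker; typed layers convert it to an
explicit null.  Rows whose field count disagrees with the header are
skipped and counted (the count appears in the run report); the original
processing convention for such rows is not documented anywhere, so
skip-and-log is this package's choice.  THER and RPSR files are parsed
only for pass-through; they play no role in curation.

## Demographic normalization

The four fields used for imputation and de-duplication are event date,
age, sex and reporter country.

* **Event dates** are normalized to `YYYYMMDD`.  Partial dates (`YYYY`
  or `YYYYMM`) are padded with `01` components so they order and
  compare; a partial date counts as populated.  Discarding partial
  dates would inflate missingness and block legitimate imputation.
* **Age** is converted to decimal years using the FDA unit codes
  (DEC×10, YR×1, MON÷12, WK÷52, DY÷365, HR÷8760).  A blank unit code is
  read as years, the dominant convention in the files.  Unparseable
  values become null and are logged.  When ages are *compared* (the
  step-2 demographic key) they are rounded to 4 decimals so that
  unit-converted equal ages (24 MON vs 2 YR) compare equal.
* **Reporter country** maps through a bundled name→ISO-code table
  (legacy quarters spell countries out, current quarters use codes);
  unmapped non-empty values pass through upper-cased, so the same true
  country yields the same code from either dialect.
* **Sex** is upper-cased; no recoding.

## Missing-value imputation

Within one case, if at least one version has all four fields populated,
the *donor* key is the per-field maximum over the fully populated
versions — dates by calendar order, age numerically, sex and country
lexicographically.  Every version missing **exactly one** field receives
that field from the donor; versions missing two or more fields are left
unchanged, and populated fields are never overwritten.  The per-field
maximum (rather than copying the single "maximal" full version) is this
package's reading of a genuinely ambiguous convention; the two differ
only when several fully populated versions disagree, and the choice is
isolated in `merge.impute_single_missing`.  Imputation is idempotent and
runs before de-duplication, which is the point: it populates the very
fields step 2 collapses on.

## Two-step de-duplication

*Step 1 — latest version per case.*  The comparison fields are the case
id, the I/F code, the four demographic fields, and canonical drug- and
reaction-list keys (names upper-cased, trimmed, alphabetically sorted,
joined with `|`, which occurs in no name).  Versions identical on all of
these are exact duplicates; among them — and equally among versions that
genuinely differ, since content carries no recency information — the
survivor is the maximum under the precedence key: current data set over
legacy (a case present in both keeps its current version), then the
unique row key descending (FDA keys are assigned chronologically; fully
numeric keys compare as integers, non-numeric keys rank below numeric
ones and compare lexicographically among themselves), then the source
file's (year, quarter) descending.

*Step 2 — collapse across case numbers.*  Among step-1 survivors whose
four demographic fields are **all populated** and pairwise equal, only
the precedence-maximal one is kept.  A version with any missing
demographic field is never collapsed: null never matches null, because
merging on absent data would conflate unrelated reports.  Probabilistic
or fuzzy duplicate detection is deliberately out of scope.

Every removal is written to a de-duplication audit log with the stage,
reason and surviving key.

## Vocabulary mapping

Drug strings map through four ordered deterministic steps; the first hit
wins and is recorded as the mapping method:

1. **Normalized exact lookup.**  The normalization chain, applied in
   order: upper-case; trim; strip surrounding quotes; drop parenthesized
   groups; collapse internal whitespace; repeatedly strip trailing
   dose/form tokens — bare numbers, number+unit (`50 MG`, `100MG`,
   `2.5 MG`, units MG/MCG/ML/G/IU/%), and the form words TAB(S), TABLET(S),
   CAP(S), CAPSULE(S), INJ, INJECTION, SOLUTION, SOLN — then strip
   trailing punctuation.  A single remaining token is never stripped to
   empty.  The original regex set behind the published resource is not
   available, so this chain is the package's own, fully documented and
   individually unit-tested.
2. **Active ingredient.**  The same lookup applied to the separate
   active-ingredient field present on current-dialect DRUG rows.
3. **NDA number**, looked up in an orange-book style NDA→ingredient
   table.
4. **Manual map**, an optional user-supplied two-column file (verbatim
   string → concept id), standing in for interactive curation of the
   residue.

Any hit on a non-standard concept (brand name) resolves through the
relationship table to its unique standard target — an ingredient, or a
clinical-drug-form concept for multi-ingredient products.  A
non-standard concept with zero or several standard targets is left
unmapped with a warning: a silent arbitrary choice would corrupt the
downstream counts.  Reaction and indication MedDRA preferred terms map
through a simplified PT→SNOMED table on the trimmed upper-cased string;
misses are retained in the outputs with empty concept columns.
Indications are mapped only for the surviving version of each case;
drugs of **all** roles (PS, SS, C, I) are mapped and counted.  The
coverage report gives fractions over unique strings and over cases
(all-drugs-mapped and any-drug-mapped), plus unique reaction/indication
PT coverage; zero denominators are flagged rather than divided by.

## Counting and statistics

The counting unit is the **triple universe**: the set of distinct
(case, drug concept, outcome concept) combinations over the
de-duplicated, mapped cases, with outcomes taken from the mapped
reaction terms.  For each observed pair, `a` = triples with this drug
and outcome, `b` = this drug with other outcomes, `c` = other drugs with
this outcome, `d` = the remainder, so `a+b+c+d = N` (the universe size)
for every pair in a run.  At full-FAERS scale the published pair counts
are consistent with this triple-level counting, not with unique-case
counting; case-level counting (distinct cases per cell, `N` = number of
cases) remains available via `counting_unit="case"`.

PRR and ROR with 95% confidence intervals are computed as in the README.
The PRR standard error uses the standard form
√(1/a − 1/(a+b) + 1/c − 1/(c+d)).  Zero cells yield null statistics —
PRR needs `a>0` and `c>0`, ROR needs all four cells positive; no
continuity correction is applied by default, and a 0.5 Haldane–Anscombe
correction (added to all four cells when any is zero) is available
behind a flag.  No multiple-testing adjustment is applied: the outputs
are the raw per-pair estimates and intervals.  Only pairs with `a ≥ 1`
are emitted.

A note on the published worked example for these formulas (etanercept ×
injection-site pain): the printed cell counts (30,793 / 647,134 /
140,853 / 61,815,244) under the formulas above give PRR = 19.9796
(CI 19.7394–20.2227) and ROR = 20.8827 (CI 20.6219–21.1469), verified by
exact rational arithmetic, whereas the prose alongside those cells
reports PRR 21.11113 and ROR 22.1693.  The printed statistics and the
printed cells cannot both be right and were likely taken from different
intermediate data; `faerskit` documents and tests the values implied by
the cells.

## Synthetic corpus: what it emulates and what it does not

The generator's defaults define the study conditions: 200 cases, 35%
follow-up probability (plus a smaller chance of a second follow-up), 15%
of cases present in both data sets, 20%/7% of versions missing exactly
one/two demographic fields, 5% orphan-duplicate probability, 12
ingredient concepts with brands/NDA numbers and one multi-ingredient
product, 30 preferred terms of which 80% carry a SNOMED mapping, and
drug-string variant probabilities of 25% brand, 20% dose-suffixed, 5%
misspelled (constructed unmappable), 10% NDA-number strings, plus an 8%
chance that a current-dialect row is mappable only through its
active-ingredient field.  These sizes keep the complete test suite and
the acceptance script in the seconds-to-a-few-minutes range while every
comparison path (dialect differences, unit-converted ages, name- versus
code-style countries, partial dates) is exercised.

Ground truth is computed by a *second, structurally independent*
implementation of the imputation and de-duplication rules inside the
generator, operating on its internal records before file rendering; it
shares no code with the pipeline modules and therefore serves as an
oracle for them.

The corpus does **not** emulate: realistic marginal frequencies of real
drugs and events, free-text noise beyond the documented variant rules
(e.g. arbitrary spelling errors that a fuzzy matcher might recover),
THER/RPSR content, XML-dialect distributions, or vocabulary content of
real RxNorm/MedDRA/SNOMED releases.  Passing tests therefore establish
that the *rules as specified* are implemented correctly and
deterministically — not that the rules recover every true duplicate in
real FAERS, where mapping coverage and duplicate rates depend on the
vocabulary release and on manual curation effort.

## Numerical and determinism choices

* Statistics are computed in double precision; agreement with exact
  rational arithmetic is ≤ ~1e-15 relative on random tables (tested at
  1e-9 tolerance).
* All outputs are written in a canonical sort order (case id and row
  key; drug/outcome concept ids), so runs are byte-identical for
  identical inputs regardless of record order in the source files — and
  byte-identical across record-order permutations of the inputs.
* The generator is driven by a single seeded PRNG; identical
  configuration (including seed) yields byte-identical corpora.
* Pipeline failures abort with the failing stage's name and remove
  partial outputs.

## Known limitations

* Step-2 de-duplication treats imputed and originally observed values
  identically; whether the original resource distinguished them is not
  documented.
* The drug-name normalization chain is intentionally conservative;
  strings outside its documented rules (true misspellings, compound
  free-text) remain unmapped unless supplied via the manual map.
* Coverage percentages on the synthetic corpus reflect the constructed
  variant mix, not real-world coverage of any vocabulary release.
* Only raw PRR/ROR are provided; Bayesian shrinkage measures (EBGM, IC)
  and stratified analyses are out of scope.
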