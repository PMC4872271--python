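# faerskit

Curation and disproportionality signal detection for spontaneous
adverse-event reports from the FDA Adverse Event Reporting System
(FAERS) and its legacy predecessor (LAERS).

Raw FAERS quarterly downloads cannot be analysed as-is: the legacy and
current distributions use different key fields (`isr`/`case` versus
`primaryid`/`caseid`), cases appear as multiple initial/follow-up
versions — sometimes in both distributions at once or under different
case numbers — demographic fields are partially missing, and drugs and
reactions are free-text or MedDRA strings rather than standard
vocabulary concepts.  `faerskit` implements the full curation chain for
pharmacovigilance researchers:

1. **Parse** the seven "$"-delimited quarterly table kinds
   (DEMO/DRUG/REAC/INDI/OUTC/THER/RPSR) in both dialects, detecting the
   dialect from each file's header.
2. **Merge** both data sets into case-version records that keep both key
   fields, normalizing event date, age (unit codes DEC/YR/MON/WK/DY/HR)
   and reporter country.
3. **Impute** single missing demographic values from the per-field
   maxima of a case's fully populated versions (never more than one
   missing field, never overwriting observed data).
4. **De-duplicate** in two steps: keep the most recent version per case
   (current data set over legacy, then descending row key, then file
   year/quarter), then collapse distinct case numbers whose four
   demographic fields — event date, age, sex, reporter country — are all
   populated and identical.
5. **Map** verbatim drug names to standard ingredient / clinical-drug-form
   concepts through an ordered chain (normalized exact name lookup →
   active-ingredient field → NDA number via an orange-book style table →
   optional user-supplied manual map), and reaction/indication MedDRA
   preferred terms to SNOMED-CT concepts via a simplified mapping table.
6. **Count and test**: build the universe of distinct (case, drug
   concept, outcome concept) triples and, for every observed pair, a 2×2
   contingency table with two standard disproportionality statistics:

   PRR = (a/(a+b)) / (c/(c+d)),
   95% CI = exp( ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)) )

   ROR = ad/(bc),
   95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )

   where `a` counts reports with the drug and the outcome, `b` with the
   drug only, `c` with the outcome only, and `d` the remainder.

The run emits the eight tab-delimited `standard_*` tables
(`standard_case_drug`, `standard_case_outcome`,
`standard_case_outcome_category`, `standard_case_indication`,
`standard_drug_outcome_contingency_table`, `standard_drug_outcome_count`,
`standard_drug_outcome_statistics`, `standard_drug_outcome_drilldown`),
a de-duplication audit log and a JSON run report with per-stage record
counts and mapping coverage.

A first-class synthetic-data generator (`faerskit.synth`) produces
seeded miniature corpora with a fixture vocabulary and an independently
computed ground truth (surviving cases, drug-string and PT mappings), so
the whole pipeline is testable without downloading FAERS or licensing
any vocabulary.

## Worked example

```bash
$ faerskit synth --out-dir demo --n-cases 200 --seed 1
wrote 42 quarterly files under demo/data, vocabulary under demo/vocab
cases: 200; surviving after curation rules: 207

$ faerskit run --input-dir demo/data --vocab-dir demo/vocab --out-dir demo/out
{
  "counts": {
    ...
    "deduplicated_cases": 207,
    "drug_outcome_pairs": 302,
    "drug_outcome_triples": 1237,
    "merged_versions": 333,
    ...
  },
  ...
}
```

The 200 requested cases gain orphan duplicates and follow-up versions
(333 parsed versions in total); curation keeps 207 unique reports, which
yield 1,237 distinct case–drug–outcome triples and 302 observed
drug–outcome pairs with statistics.  The surviving case set equals the
generator's independently computed ground truth.

The `stats` subcommand evaluates a single 2×2 table — here the cell
counts of a published etanercept × injection-site-pain example
(a=30,793 reports with drug and outcome out of N≈62.6 M):

```bash
$ faerskit stats --cells 30793 647134 140853 61815244
a      b       c       d         prr       prr_lo    prr_hi    ror       ror_lo    ror_hi
30793  647134  140853  61815244  19.97961  19.73940  20.22274  20.88273  20.62186  21.14690
```

i.e. injection-site pain is reported about 20× more frequently among
etanercept reports than among all other reports, with a tight confidence
interval — a strong disproportionality signal.

From Python, the statistics stage is exposed as a model/results pair:

```python
import faerskit as fk

triples = fk.enumerate_triples([
    ("case1", [1001], [40001]),
    ("case2", [1001, 1002], [40001, 40002]),
])
results = fk.DisproportionalityModel(triples).fit()
print(results.summary())
print(results.table)         # cells, PRR/ROR and 95% CIs per pair
```

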