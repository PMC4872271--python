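"""Contingency tables and PRR/ROR disproportionality statistics."""
import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerskit import stats


def oracle_prr(a, b, c, d):
    """Exact-rational PRR and 95% CI (independent of the implementation)."""
    if a == 0 or c == 0:
        return (None, None, None)
    prr = float(Fraction(a, a + b) / Fraction(c, c + d))
    se = math.sqrt(float(Fraction(1, a) - Fraction(1, a + b)
                         + Fraction(1, c) - Fraction(1, c + d)))
    return (prr, math.exp(math.log(prr) - 1.96 * se),
            math.exp(math.log(prr) + 1.96 * se))


def oracle_ror(a, b, c, d):
    if min(a, b, c, d) == 0:
        return (None, None, None)
    ror = float(Fraction(a * d, b * c))
    se = math.sqrt(float(Fraction(1, a) + Fraction(1, b)
                         + Fraction(1, c) + Fraction(1, d)))
    return (ror, math.exp(math.log(ror) - 1.96 * se),
            math.exp(math.log(ror) + 1.96 * se))


def _rel_close(x, y, tol=1e-9):
    return abs(x - y) <= tol * max(abs(x), abs(y), 1e-300)


class TestPrr:
    def test_equal_proportions_give_one(self):
        prr, lo, hi = stats.compute_prr(stats.ContingencyTable(10, 90, 100, 900))
        assert prr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example_cells_match_rational_oracle(self):
        # Etanercept x injection-site-pain cells; the oracle-verified
        # statistics for these cells (exact rational arithmetic):
        t = stats.ContingencyTable(30793, 647134, 140853, 61815244)
        prr, lo, hi = stats.compute_prr(t)
        assert _rel_close(prr, 19.979610645900653)
        assert _rel_close(lo, 19.739403205200798)
        assert _rel_close(hi, 20.22274115443431)

    def test_zero_a_cell_gives_nulls(self):
        assert stats.compute_prr(stats.ContingencyTable(0, 5, 5, 5)) == (
            None, None, None)


class TestRor:
    def test_symmetric_cells_give_one(self):
        ror, lo, hi = stats.compute_ror(stats.ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example_cells_match_rational_oracle(self):
        t = stats.ContingencyTable(30793, 647134, 140853, 61815244)
        ror, lo, hi = stats.compute_ror(t)
        assert _rel_close(ror, 20.88272986173419)
        assert _rel_close(lo, 20.621857956369023)
        assert _rel_close(hi, 21.14690186504168)

    def test_zero_cell_gives_nulls(self):
        assert stats.compute_ror(stats.ContingencyTable(1, 0, 1, 1)) == (
            None, None, None)

    def test_haldane_correction_recovers_estimate(self):
        ror, lo, hi = stats.compute_ror(stats.ContingencyTable(1, 0, 1, 1),
                                        haldane=True)
        assert ror is not None and lo < ror < hi


_cells = st.integers(min_value=1, max_value=100_000)


@given(a=_cells, b=_cells, c=_cells, d=_cells)
def test_ror_inversion_identity(a, b, c, d):
    """ROR(a,b,c,d) * ROR(b,a,d,c) = 1."""
    r1, _, _ = stats.compute_ror(stats.ContingencyTable(a, b, c, d))
    r2, _, _ = stats.compute_ror(stats.ContingencyTable(b, a, d, c))
    assert r1 * r2 == pytest.approx(1.0)


@given(a=_cells, b=_cells, c=_cells, d=_cells)
def test_point_estimates_match_rational_oracle(a, b, c, d):
    prr, plo, phi = stats.compute_prr(stats.ContingencyTable(a, b, c, d))
    ror, rlo, rhi = stats.compute_ror(stats.ContingencyTable(a, b, c, d))
    for got, want in zip((prr, plo, phi, ror, rlo, rhi),
                         oracle_prr(a, b, c, d) + oracle_ror(a, b, c, d)):
        assert _rel_close(got, want)


@given(a=st.integers(min_value=2, max_value=1000),
       b=st.integers(min_value=2, max_value=1000),
       c=_cells, d=_cells)
def test_monotonicity_in_a(a, b, c, d):
    """Shifting one report from b to a strictly increases PRR and ROR."""
    t1 = stats.ContingencyTable(a, b, c, d)
    t2 = stats.ContingencyTable(a + 1, b - 1, c, d)
    assert stats.compute_prr(t2)[0] > stats.compute_prr(t1)[0]
    assert stats.compute_ror(t2)[0] > stats.compute_ror(t1)[0]


def test_ci_width_shrinks_with_scale():
    t1 = stats.ContingencyTable(10, 90, 100, 900)
    t2 = stats.ContingencyTable(100, 900, 1000, 9000)
    _, lo1, hi1 = stats.compute_ror(t1)
    _, lo2, hi2 = stats.compute_ror(t2)
    assert (hi2 - lo2) < (hi1 - lo1)


class TestTriplesAndContingency:
    def test_product_of_distinct_concepts(self):
        triples = stats.enumerate_triples([("c1", [1, 2], [10, 20, 30])])
        assert len(triples) == 6

    def test_set_semantics_collapse_duplicates(self):
        triples = stats.enumerate_triples([("c1", [1, 1], [10])])
        assert len(triples) == 1

    def test_empty_input(self):
        assert stats.enumerate_triples([]).empty

    def test_four_triple_universe_cells(self):
        triples = stats.enumerate_triples([
            ("c1", [1], [10]), ("c2", [1], [20]),
            ("c3", [2], [10]), ("c4", [2], [20])])
        t = stats.build_contingency(triples, 1, 10)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_cells_sum_to_universe_for_every_pair(self, small_run):
        path = f"{small_run['out_dir']}/standard_drug_outcome_contingency_table.tsv"
        from faerskit.io import read_standard_table
        rows = read_standard_table(path)
        n = small_run["report"].counts["drug_outcome_triples"]
        assert rows
        for r in rows:
            assert (int(r["count_a"]) + int(r["count_b"]) + int(r["count_c"])
                    + int(r["count_d"])) == n

    def test_brute_force_cells_on_small_universe(self):
        import itertools, random
        rng = random.Random(9)
        records = [(f"c{i}", rng.sample(range(5), rng.randint(1, 3)),
                    rng.sample(range(100, 106), rng.randint(1, 3)))
                   for i in range(30)]
        triples = stats.enumerate_triples(records)
        universe = set(map(tuple, triples.itertuples(index=False)))
        cells = stats.contingency_all(triples)
        for r in cells.itertuples(index=False):
            a = sum(1 for _, dd, oo in universe
                    if dd == r.drug_concept_id and oo == r.outcome_concept_id)
            b = sum(1 for _, dd, oo in universe
                    if dd == r.drug_concept_id and oo != r.outcome_concept_id)
            c = sum(1 for _, dd, oo in universe
                    if dd != r.drug_concept_id and oo == r.outcome_concept_id)
            assert (r.a, r.b, r.c) == (a, b, c)
            assert r.d == len(universe) - a - b - c


class TestModelResults:
    def test_fit_returns_one_row_per_observed_pair(self):
        triples = stats.enumerate_triples([
            ("c1", [1], [10]), ("c2", [1], [20]), ("c3", [2], [10])])
        results = stats.DisproportionalityModel(triples).fit()
        assert results.n_pairs == 3
        assert results.universe_size == 3

    def test_case_counting_unit(self):
        triples = stats.enumerate_triples([
            ("c1", [1], [10]), ("c2", [1, 2], [10])])
        results = stats.DisproportionalityModel(
            triples, counting_unit="case").fit()
        row = results.table.set_index(["drug_concept_id",
                                       "outcome_concept_id"]).loc[(1, 10)]
        assert row["a"] == 2  # two distinct cases report drug 1 with outcome 10

    def test_summary_renders(self):
        triples = stats.enumerate_triples([("c1", [1], [10]),
                                           ("c2", [2], [20])])
        text = stats.DisproportionalityModel(triples).fit().summary()
        assert "counting unit" in text and "PRR" in text

    def test_empty_universe_gives_empty_table(self):
        results = stats.DisproportionalityModel(
            pd.DataFrame(columns=stats.TRIPLE_COLUMNS)).fit()
        assert results.table.empty and results.n_pairs == 0
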