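"""Exact 2x2 machinery, burden strata, CNVR scan, TDT, de novo and power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rarecnv import CnvCall, Pedigree, fisher_2x2, power_grid, tdt_exact
from rarecnv.cnvr import group_cnvrs, recount_carriers
from rarecnv.stats import (burden_2x2, burden_strata, bonferroni_threshold,
                           cnvr_scan, large_cnv_table, monte_carlo_power,
                           transmission_counts)
from tests._oracles import (binom_two_sided_doubling, cmle_or_enum,
                            fisher_p_enum)
from tests.conftest import make_sheet

N_CASE, N_CONTROL = 6524, 9238   # post-QC totals of the study cohort


class TestFisher2x2:
    def test_long_deletion_burden_counts(self):
        """82 of 6524 cases vs 74 of 9238 controls: CMLE OR 1.57,
        CI (1.14, 2.19), p 0.0053."""
        r = fisher_2x2(82, N_CASE - 82, 74, N_CONTROL - 74)
        assert r.or_cmle == pytest.approx(1.57, abs=0.01)
        assert r.ci_low == pytest.approx(1.14, abs=0.005)
        assert r.ci_high == pytest.approx(2.19, abs=0.005)
        assert r.p_two_sided == pytest.approx(0.0053, abs=0.0001)

    def test_large_cnv_cross_product(self):
        """11 vs 1 carriers: sample OR 15.60."""
        r = fisher_2x2(11, 6513, 1, 9237)
        assert r.or_sample == pytest.approx(15.60, abs=0.005)
        assert r.p_two_sided == pytest.approx(0.00045, abs=0.00005)

    def test_symmetric_table_is_null(self):
        r = fisher_2x2(5, 95, 5, 95)
        assert r.or_sample == 1.0
        assert r.or_cmle == pytest.approx(1.0, abs=1e-6)
        assert r.p_two_sided == 1.0

    def test_small_table_against_enumeration(self):
        r = fisher_2x2(2, 3, 1, 4)
        assert r.p_two_sided == pytest.approx(1.0, abs=1e-12)
        assert r.or_sample == pytest.approx(8 / 3, abs=1e-12)
        assert r.p_two_sided == pytest.approx(float(fisher_p_enum(2, 3, 1, 4)),
                                              abs=1e-12)

    def test_zero_cell_has_no_or_sample_or_ci(self):
        r = fisher_2x2(3, 50, 0, 60)
        assert r.or_sample is None and r.ci_low is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 60))
    def test_p_and_cmle_match_enumeration_oracles(self, a, b, c, d):
        """p agrees with hypergeometric enumeration to 1e-12 and the CMLE
        with conditional-likelihood bisection to 1e-6, for N <= 240."""
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        r = fisher_2x2(a, b, c, d)
        assert r.p_two_sided == pytest.approx(float(fisher_p_enum(a, b, c, d)),
                                              abs=1e-12)
        ref = cmle_or_enum(a, b, c, d)
        if np.isfinite(ref) and ref > 0:
            assert r.or_cmle == pytest.approx(ref, rel=1e-6, abs=1e-6)
        else:
            assert r.or_cmle == ref or np.isinf(r.or_cmle) == np.isinf(ref)


class TestBurdenStrata:
    def _calls(self, spec):
        calls = []
        i = 0
        for pheno, cls, length, n in spec:
            cn = 1 if cls == "DEL" else 3
            for _ in range(n):
                calls.append(CnvCall(f"{pheno}{i}", "chr1", 1000,
                                     1000 + length - 1, cn, 10, 0.99))
                i += 1
        return calls

    def test_table_of_printed_counts_reproduces_ors(self):
        """Length-stratified burden from the study's printed event counts
        reproduces the printed CMLE odds ratios."""
        spec = [("case", "DEL", 10_000, 570), ("control", "DEL", 10_000, 820),
                ("case", "DEL", 100_000, 372), ("control", "DEL", 100_000, 514),
                ("case", "DEL", 500_000, 82), ("control", "DEL", 500_000, 74),
                ("case", "DUP", 20_000, 740), ("control", "DUP", 20_000, 1098),
                ("case", "DUP", 100_000, 946), ("control", "DUP", 100_000, 1336),
                ("case", "DUP", 500_000, 230), ("control", "DUP", 500_000, 326)]
        calls = self._calls(spec)
        samples = sorted({c.sample_id for c in calls})
        sheet = make_sheet(samples,
                           phenotypes=["case" if s.startswith("case") else
                                       "control" for s in samples])
        res = {b.stratum: b for b in burden_strata(calls, sheet, N_CASE,
                                                   N_CONTROL)}
        for stratum, expect in [("DEL 0-20 kb", 0.98), ("DEL 20-400 kb", 1.03),
                                ("DEL >400 kb", 1.57), ("DUP 0-50 kb", 0.95),
                                ("DUP 50-400 kb", 1.00), ("DUP >400 kb", 1.00)]:
            assert res[stratum].or_cmle == pytest.approx(expect, abs=0.01), stratum
        assert res["DEL >400 kb"].p_two_sided == pytest.approx(0.0053, abs=1e-4)
        assert res["DEL >400 kb"].significant          # passes Bonferroni m=6
        assert not res["DEL 0-20 kb"].significant

    def test_bin_edges_are_half_open(self):
        spec = [("case", "DEL", 20_000, 1), ("control", "DEL", 20_001, 1)]
        calls = self._calls(spec)
        samples = sorted({c.sample_id for c in calls})
        sheet = make_sheet(samples, phenotypes=["case", "control"])
        res = {b.stratum: b for b in burden_strata(calls, sheet, 10, 10)}
        assert res["DEL 0-20 kb"].events_case == 1       # 20 kb in first bin
        assert res["DEL 20-400 kb"].events_control == 1  # 20,001 bp in second

    def test_equal_rates_are_null(self):
        b = burden_2x2(50, 50, 1000, 1000)
        assert b.or_cmle == pytest.approx(1.0, abs=1e-9)
        assert b.p_two_sided == 1.0


class TestCnvrScan:
    def test_bonferroni_threshold_for_383_tests(self):
        assert bonferroni_threshold(383) == pytest.approx(1.31e-4, abs=5e-7)

    def test_scan_attaches_threshold_and_qq(self):
        calls = [CnvCall("a", "chr1", 1, 100, 1, 10, 0.99),
                 CnvCall("b", "chr2", 1, 100, 1, 10, 0.99)]
        sheet = make_sheet(["a", "b"], phenotypes=["case", "control"])
        cnvrs = group_cnvrs([calls[0]], 100) + group_cnvrs([calls[1]], 100)
        recount_carriers(cnvrs, sheet)
        df = cnvr_scan(cnvrs, 50, 50)
        assert np.allclose(df["bonferroni_threshold"], 0.05 / 2)
        assert list(df["expected_p"]) == [0.25, 0.75]

    def test_null_scan_p_values_not_inflated(self):
        """Null CNVR scans (equal carrier frequencies) show no excess of
        small p-values: the one-sided KS statistic D+ against uniform stays
        below its 5% critical value in >= 90% of replicates.  (Exact-test
        p-values are conservative, so the two-sided distance is dominated
        by super-uniformity; inflation is what a QQ plot screens for.)"""
        rng = np.random.default_rng(0)
        crit = 1.224 / np.sqrt(200)
        ok = 0
        for rep in range(10):
            ps = []
            for _ in range(200):
                f = rng.uniform(0.005, 0.03)
                a, c = rng.binomial(3000, f), rng.binomial(3000, f)
                ps.append(fisher_2x2(a, 3000 - a, c, 3000 - c).p_two_sided)
            p_sorted = np.sort(ps)
            dplus = np.max(np.arange(1, 201) / 200 - p_sorted)
            ok += dplus <= crit
        assert ok >= 9


class TestTransmissions:
    def _ped(self, rows):
        return Pedigree(pd.DataFrame(rows, columns=list(Pedigree.REQUIRED)))

    def test_denominator_counts_children_times_carrier_parents(self):
        ped = self._ped([
            ("f1", "dad", None, None, "M", "unaffected"),
            ("f1", "mum", None, None, "F", "unaffected"),
            ("f1", "k1", "dad", "mum", "M", "affected"),
            ("f1", "k2", "dad", "mum", "F", "affected"),
            ("f1", "k3", "dad", "mum", "M", "affected")])
        calls = [CnvCall("dad", "chr1", 100, 200, 1, 10, 0.99),
                 CnvCall("k1", "chr1", 100, 200, 1, 10, 0.99),
                 CnvCall("k2", "chr1", 110, 210, 1, 10, 0.99)]
        df, agg = transmission_counts(calls, ped)
        t = agg["DEL"]
        assert (t.transmitted_affected, t.possible_affected) == (2, 3)

    def test_two_carrier_parents_double_the_denominator(self):
        ped = self._ped([
            ("f1", "dad", None, None, "M", "unaffected"),
            ("f1", "mum", None, None, "F", "unaffected"),
            ("f1", "k1", "dad", "mum", "M", "affected"),
            ("f1", "k2", "dad", "mum", "F", "affected")])
        calls = [CnvCall(s, "chr1", 100, 200, 1, 10, 0.99)
                 for s in ("dad", "mum", "k1", "k2")]
        _, agg = transmission_counts(calls, ped)
        assert agg["DEL"].possible_affected == 4
        assert agg["DEL"].transmitted_affected == 4

    def test_burden_ratio_from_printed_rates(self):
        """44.2% affected vs 43.8% unaffected transmission -> ratio 1.01."""
        assert 0.442 / 0.438 == pytest.approx(1.01, abs=0.005)

    def test_insufficient_reciprocal_overlap_not_transmitted(self):
        ped = self._ped([
            ("f1", "dad", None, None, "M", "unaffected"),
            ("f1", "mum", None, None, "F", "unaffected"),
            ("f1", "k1", "dad", "mum", "M", "affected")])
        calls = [CnvCall("dad", "chr1", 100, 1099, 1, 10, 0.99),
                 CnvCall("k1", "chr1", 1090, 5000, 1, 10, 0.99)]  # 10/1000 bp
        _, agg = transmission_counts(calls, ped)
        assert agg["DEL"].transmitted_affected == 0
        assert agg["DEL"].possible_affected == 1


class TestTdt:
    def test_five_of_five(self):
        assert tdt_exact(5, 5) == pytest.approx(0.0625, abs=1e-12)

    def test_balanced_is_capped_at_one(self):
        assert tdt_exact(10, 20) == 1.0

    def test_twenty_eight_of_eighty_one_matches_oracle(self):
        """The 28/81 transmission deficit: tail-doubled exact p ~ 0.0073."""
        assert tdt_exact(28, 81) == pytest.approx(
            float(binom_two_sided_doubling(28, 81)), abs=1e-12)
        assert tdt_exact(28, 81) == pytest.approx(0.00728, abs=5e-5)

    def test_zero_possible_errors(self):
        with pytest.raises(ValueError):
            tdt_exact(0, 0)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(1, 500), st.data())
    def test_matches_binomial_enumeration(self, n, data):
        t = data.draw(st.integers(0, n))
        assert tdt_exact(t, n) == pytest.approx(
            float(binom_two_sided_doubling(t, n)), abs=1e-12)


class TestLargeCnvs:
    def test_study_counts_give_or_15_60(self):
        calls = [CnvCall(f"c{i}", "chr1", 1, 3_200_000, 1, 50, 0.99)
                 for i in range(11)] + \
            [CnvCall("ctrl", "chr2", 1, 3_500_000, 1, 60, 0.99)]
        sheet = make_sheet([c.sample_id for c in calls],
                           phenotypes=["case"] * 11 + ["control"])
        df, test = large_cnv_table(calls, sheet, N_CASE, N_CONTROL)
        assert len(df) == 12
        assert test.or_sample == pytest.approx(15.60, abs=0.005)

    def test_three_mb_threshold_is_strict(self):
        calls = [CnvCall("a", "chr1", 1, 3_000_001, 1, 50, 0.99),   # included
                 CnvCall("b", "chr1", 1, 2_999_999, 1, 50, 0.99)]   # excluded
        sheet = make_sheet(["a", "b"], phenotypes=["case", "case"])
        df, _ = large_cnv_table(calls, sheet, 10, 10)
        assert list(df["sample_id"]) == ["a"]

    def test_empty_input_gives_empty_report(self):
        df, test = large_cnv_table([], make_sheet(["x"]), 10, 10)
        assert df.empty


class TestPower:
    def test_monotone_in_or_and_frequency(self):
        grid = power_grid([1.5, 2, 3, 5], [0.001, 0.005, 0.01, 0.05])
        units = grid.required_units
        assert np.all(np.diff(units, axis=1) <= 0)   # increasing OR
        assert np.all(np.diff(units, axis=0) <= 0)   # increasing frequency

    def test_or_at_most_one_is_undefined(self):
        grid = power_grid([1.0, 2.0], [0.01])
        assert np.isnan(grid.required_units[0, 0])
        assert np.isfinite(grid.required_units[0, 1])

    def test_monte_carlo_power_and_method_agreement(self):
        """MC power rises with N, and the closed-form required N is within
        a factor of two of the Monte-Carlo search at freq 0.05, OR 1.25."""
        p30 = monte_carlo_power(1.25, 0.05, 30_000, 5e-5, n_rep=300, seed=1)
        p40 = monte_carlo_power(1.25, 0.05, 40_000, 5e-5, n_rep=300, seed=2)
        assert p40 >= p30
        normal = power_grid([1.25], [0.05]).required_units[0, 0]
        mc = power_grid([1.25], [0.05], method="monte_carlo",
                        seed=3).required_units[0, 0]
        assert 0.5 <= normal / mc <= 2.0

    def test_study_scale_detectability(self):
        """At the study's n = 16,000 (1.6 units) an OR of 2 at 1% frequency
        is detectable but an OR of 2 at 0.1% is not."""
        grid = power_grid([2.0], [0.01, 0.001])
        assert grid.required_units[0, 0] <= 2
        assert grid.required_units[1, 0] > 2
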