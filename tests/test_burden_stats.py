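"""Poisson and Fisher burden tests, screens and yield arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import fisher_two_sided_enum, poisson_lower_limit_by_inversion
from trioburden.burden_stats import (
    CarrierTable,
    carrier_counts,
    diagnostic_yield,
    fisher_carrier_test,
    obs_minus_exp_ci,
    poisson_burden_test,
    screen_subset,
)
from trioburden.variant_io import GeneSet, Trio


class TestPoissonBurden:
    def test_lof_intolerant_row(self):
        r = poisson_burden_test(5, 3.12)
        assert round(r.enrichment, 2) == 1.60
        assert round(r.p_value, 2) == 0.21

    def test_denovodb_row(self):
        r = poisson_burden_test(3, 0.70)
        assert round(r.p_value, 2) == 0.03

    def test_zero_observed_has_unit_p(self):
        assert poisson_burden_test(0, 2.5).p_value == 1.0

    def test_invalid_expectation(self):
        with pytest.raises(ValueError):
            poisson_burden_test(1, 0.0)

    @given(st.integers(0, 40), st.floats(0.1, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_p_monotone_in_observed_and_expected(self, obs, exp):
        p = poisson_burden_test(obs, exp).p_value
        assert poisson_burden_test(obs + 1, exp).p_value <= p
        assert poisson_burden_test(obs, exp * 1.5).p_value >= p
        assert 0.0 < p <= 1.0 or obs == 0


class TestObsMinusExp:
    def test_enriched_set_estimate(self):
        est, _ = obs_minus_exp_ci(7, 1.25)
        assert est == pytest.approx(5.75)

    def test_zero_estimate_when_equal(self):
        est, _ = obs_minus_exp_ci(3, 3.0)
        assert est == 0.0

    @pytest.mark.parametrize("observed", [1, 3, 10, 25])
    def test_lower_bound_matches_grid_inversion(self, observed):
        _, lower = obs_minus_exp_ci(observed, 2.0)
        oracle = poisson_lower_limit_by_inversion(observed, alpha=0.025) - 2.0
        assert lower == pytest.approx(oracle, abs=1e-6)

    def test_zero_count_lower_limit_is_zero(self):
        _, lower = obs_minus_exp_ci(0, 2.0)
        assert lower == -2.0


class TestFisher:
    def test_pathogenic_missense_carrier_table(self):
        r = fisher_carrier_test(CarrierTable(5, 119, 2, 571))
        assert round(r.odds_ratio, 1) == 11.9
        assert r.p_value == pytest.approx(2.57e-3, rel=0.01)
        assert r.ci_lower < r.odds_ratio < r.ci_upper

    def test_null_table(self):
        r = fisher_carrier_test(CarrierTable(3, 7, 3, 7))
        assert r.p_value == 1.0
        assert r.odds_ratio == pytest.approx(1.0, abs=0.05)

    def test_degenerate_margin_flagged(self):
        r = fisher_carrier_test(CarrierTable(0, 0, 2, 8))
        assert r.degenerate and np.isnan(r.odds_ratio)

    def test_small_tables_match_enumeration(self):
        # every 2x2 with total <= 12
        n = 12
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    for d in range(n + 1 - a - b - c):
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        p = fisher_carrier_test(CarrierTable(a, b, c, d)).p_value
                        assert p == pytest.approx(
                            fisher_two_sided_enum(a, b, c, d), rel=1e-8
                        ), (a, b, c, d)


def _roster(n_cases=4, n_controls=4):
    return [
        *[Trio(f"CASE{i}", f"C{i}", f"M{i}", f"F{i}", True) for i in range(n_cases)],
        *[Trio(f"CTRL{i}", f"c{i}", f"m{i}", f"f{i}", False) for i in range(n_controls)],
    ]


def _calls(rows):
    return pd.DataFrame(
        rows,
        columns=["trio_id", "variant_key", "kind", "gene", "effect", "score", "clinvar", "loeuf"],
    )


class TestCarrierCounts:
    def test_each_subject_counts_once(self):
        calls = _calls([
            ("CASE0", "k1", "dnm", "G1", "missense", 20.0, "none", 1.0),
            ("CASE0", "k2", "dnm", "G1", "missense", 22.0, "none", 1.0),
            ("CASE1", "k3", "dnm", "G2", "LoF", 30.0, "none", 0.2),
            ("CTRL0", "k4", "dnm", "G1", "missense", 18.0, "none", 1.0),
        ])
        t = carrier_counts(calls, _roster(), ["G1", "G2"], "nonsynonymous")
        assert (t.cases_with, t.controls_with) == (2, 1)
        assert t.n_cases == 4 and t.n_controls == 4

    def test_mosaics_only_with_flag(self):
        calls = _calls([("CASE0", "k1", "mosaic", "G1", "missense", 20.0, "none", 1.0)])
        without = carrier_counts(calls, _roster(), None, "nonsynonymous", include_mosaics=False)
        with_m = carrier_counts(calls, _roster(), None, "nonsynonymous", include_mosaics=True)
        assert without.cases_with == 0 and with_m.cases_with == 1

    def test_empty_geneset_means_no_carriers(self):
        calls = _calls([("CASE0", "k1", "dnm", "G1", "missense", 20.0, "none", 1.0)])
        t = carrier_counts(calls, _roster(), [], "nonsynonymous")
        assert t.cases_with == 0 and t.controls_with == 0

    def test_excluded_trios_leave_both_margins(self):
        calls = _calls([("CASE0", "k1", "dnm", "G1", "missense", 20.0, "none", 1.0)])
        t = carrier_counts(calls, _roster(), None, "nonsynonymous",
                           excluded_trio_ids=["CASE0", "CTRL3"])
        assert t.n_cases == 3 and t.n_controls == 3 and t.cases_with == 0

    def test_unknown_subject_rejected(self):
        calls = _calls([("GHOST", "k1", "dnm", "G1", "missense", 20.0, "none", 1.0)])
        with pytest.raises(ValueError, match="roster"):
            carrier_counts(calls, _roster(), None, "nonsynonymous")


class TestScreens:
    def _calls(self):
        return _calls([
            ("T1", "k1", "dnm", "RYR2", "missense", 28.0, "pathogenic", 0.2),
            ("T2", "k2", "dnm", "RYR2", "missense", 25.0, "none", 0.2),
            ("T3", "k3", "dnm", "TNNI3", "missense", 24.0, "likely_pathogenic", 0.6),
            ("T4", "k4", "dnm", "OTHER", "LoF", 35.0, "none", 0.34),
            ("T5", "k5", "dnm", "OTHER2", "LoF", 35.0, "none", 0.35),
            ("T6", "k6", "dnm", "OTHER3", "synonymous", 2.0, "none", 0.1),
        ])

    def test_acmg_screen(self):
        acmg = GeneSet("acmg", ("RYR2", "TNNI3", "KCNH2"))
        out = screen_subset(self._calls(), "ACMG-59", acmg_genes=acmg)
        assert sorted(out["gene"]) == ["RYR2", "RYR2", "TNNI3"]

    def test_clinvar_pathogenic_missense(self):
        out = screen_subset(self._calls(), "ClinVar-pathogenic-missense")
        assert sorted(out["trio_id"]) == ["T1", "T3"]

    def test_loeuf_boundary_strict(self):
        out = screen_subset(self._calls(), "LOEUF<0.35")
        assert out["gene"].tolist() == ["OTHER"]  # 0.35 itself excluded

    def test_denovodb_intersection(self):
        out = screen_subset(self._calls(), "LOEUF<0.35+denovo-db", denovodb_genes=["OTHER"])
        assert len(out) == 1
        empty = screen_subset(self._calls(), "LOEUF<0.35+denovo-db", denovodb_genes=["NONE"])
        assert empty.empty

    def test_empty_calls_pass_through(self):
        empty = self._calls().iloc[0:0]
        assert screen_subset(empty, "LOEUF<0.35").empty

    def test_missing_column_is_error(self):
        calls = self._calls().drop(columns=["loeuf"])
        with pytest.raises(ValueError, match="loeuf"):
            screen_subset(calls, "LOEUF<0.35")


class TestYield:
    @pytest.mark.parametrize("count,n,expected", [(8, 124, 6.5), (7, 124, 5.6), (11, 124, 8.9), (0, 50, 0.0)])
    def test_yield_percentages(self, count, n, expected):
        assert diagnostic_yield(count, n) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diagnostic_yield(1, 0)
        with pytest.raises(ValueError):
            diagnostic_yield(5, 4)
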