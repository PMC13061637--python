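"""Voltage survey summaries, OER feasibility and comparative statistics,
checked against hand oracles and exhaustive enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from darkox.electrochem import (
    OERAssessment,
    VoltageSurvey,
    aggregate_taxa,
    anova_oneway,
    assess_oer,
    spearman_correlation,
    summarize_survey,
    water_splitting_potential,
)

import pandas as pd


class TestWaterSplitting:
    def test_standard_value(self):
        """237.1 kJ mol-1 over two electrons is 1.23 V."""
        assert round(water_splitting_potential(237.1, 2), 2) == 1.23

    def test_zero_energy(self):
        assert water_splitting_potential(0.0, 2) == 0.0

    def test_doubling_electrons_halves_potential(self):
        assert water_splitting_potential(237.1, 4) == pytest.approx(
            water_splitting_potential(237.1, 2) / 2
        )

    def test_invalid_electrons(self):
        with pytest.raises(ValueError):
            water_splitting_potential(237.1, 0)


class TestSurveySummary:
    def test_single_value(self):
        sv = VoltageSurvey("n1", "area", 21.0, [0.4], background=0.0)
        s = summarize_survey(sv)
        assert s.min == s.q1 == s.median == s.mean == s.q3 == s.max == 0.4
        assert s.n == 1

    def test_hand_quartiles_odd_n(self):
        sv = VoltageSurvey("n1", "area", 21.0, [0.1, 0.2, 0.3, 0.4, 0.5],
                           background=0.0)
        s = summarize_survey(sv)
        assert s.median == pytest.approx(0.3)
        assert s.mean == pytest.approx(0.3)
        # Tukey hinges excluding the median
        assert s.q1 == pytest.approx(0.15)
        assert s.q3 == pytest.approx(0.45)

    def test_background_correction(self):
        sv = VoltageSurvey("n1", "area", 21.0, [0.5, 0.6], background=0.003)
        s = summarize_survey(sv)
        assert s.max == pytest.approx(0.597)

    def test_empty_survey_rejected(self):
        with pytest.raises(ValueError):
            VoltageSurvey("n1", "area", 21.0, np.array([]), background=0.0)


class TestOER:
    def _survey(self, vmax):
        return VoltageSurvey("n1", "area", 21.0, [0.1, vmax], background=0.0)

    def test_standard_mechanism_infeasible_at_observed_max(self):
        a = assess_oer([self._survey(0.95)])
        assert a.required_v == pytest.approx(1.60)
        assert not a.feasible

    def test_lattice_oxygen_reduction_can_enable(self):
        a = assess_oer(
            [self._survey(0.95)],
            mechanism="lattice-oxygen-mediated",
            mechanism_reduction_v=0.7,
        )
        assert a.required_v == pytest.approx(0.90)
        assert a.feasible

    def test_boundary_is_inclusive(self):
        a = OERAssessment(observed_max_v=1.60)
        assert a.feasible

    def test_requires_surveys(self):
        with pytest.raises(ValueError):
            assess_oer([])


class TestAnova:
    def test_all_equal_gives_zero(self):
        res = anova_oneway([np.full(3, 2.0), np.full(4, 2.0)])
        assert res.f == 0.0 and res.p == 1.0

    def test_hand_sum_of_squares(self):
        """Textbook dataset: between SS 6, within SS 6, F = 3 on (2, 6)."""
        res = anova_oneway(
            [np.array([1, 2, 3.0]), np.array([2, 3, 4.0]), np.array([3, 4, 5.0])]
        )
        assert res.f == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(0.125, abs=1e-12)

    def test_df_shape_matches_design(self):
        groups = [np.arange(4.0), np.arange(4.0) + 1, np.arange(4.0) + 2]
        res = anova_oneway(groups)
        assert (res.df_between, res.df_within) == (2, 9)
        assert "F2,9" in res.format()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.lists(
                st.floats(min_value=-100, max_value=100,
                          allow_nan=False, allow_infinity=False),
                min_size=2, max_size=6,
            ),
            min_size=2, max_size=4,
        )
    )
    def test_matches_brute_force_oracle(self, data):
        groups = [np.asarray(g) for g in data]
        # independent textbook oracle
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        res = anova_oneway(groups)
        if ssb == 0.0:
            assert res.f == 0.0
        elif ssw == 0.0:
            assert math.isinf(res.f)
        else:
            f = (ssb / (len(groups) - 1)) / (ssw / (allv.size - len(groups)))
            assert res.f == pytest.approx(f, abs=1e-10, rel=1e-10)
            sp = stats.f_oneway(*groups)
            assert res.f == pytest.approx(sp.statistic, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0]), np.array([])])


def brute_force_spearman_p(x, y):
    """Exhaustive two-sided permutation p using the rank-difference formula
    (valid for tie-free data): rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_d2(a, b):
        d = a - b
        return 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))

    obs = abs(rho_d2(rx, ry))
    hits = sum(
        abs(rho_d2(rx, np.asarray(p))) >= obs - 1e-12
        for p in itertools.permutations(ry)
    )
    return hits / math.factorial(n)


class TestSpearman:
    def test_monotone_pair(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_hand_rank_example(self):
        rho, p = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert p == pytest.approx(10 / 24)  # frozen exhaustive enumeration

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(n).astype(float)
        y = rng.normal(size=n)
        rho, p = spearman_correlation(x, y)
        assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_t_approximation_beyond_threshold(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        rho, p = spearman_correlation(x, y)
        sp = stats.spearmanr(x, y)
        assert rho == pytest.approx(sp.statistic, abs=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0, 2.0], [3.0, 4.0])


class TestAggregateTaxa:
    def _table(self):
        return pd.DataFrame(
            [
                {"sample": "s1", "asv": "a1", "genus": "g1", "rel_abund": 0.2},
                {"sample": "s1", "asv": "a2", "genus": "g1", "rel_abund": 0.3},
                {"sample": "s1", "asv": "a3", "genus": "g2", "rel_abund": 0.5},
                {"sample": "s2", "asv": "a1", "genus": "g1", "rel_abund": 0.6},
                {"sample": "s2", "asv": "a3", "genus": "g2", "rel_abund": 0.4},
            ]
        )

    def test_sums_within_sample(self):
        out = aggregate_taxa(self._table(), "genus")
        assert out.loc["s1", "g1"] == pytest.approx(0.5)
        assert out.loc["s2", "g2"] == pytest.approx(0.4)

    def test_totals_conserved(self):
        t = self._table()
        out = aggregate_taxa(t, "genus")
        before = t.groupby("sample")["rel_abund"].sum()
        after = out.sum(axis=1)
        assert np.allclose(before.sort_index(), after.sort_index())

    def test_identity_when_one_asv_per_genus(self):
        t = self._table()[lambda d: d["asv"] != "a2"]
        out = aggregate_taxa(t, "genus")
        assert out.loc["s1", "g1"] == pytest.approx(0.2)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate_taxa(self._table(), "family")
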