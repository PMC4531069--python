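"""Group comparisons: ratios, proportion z-test, FDR, abundance, pathways."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from turnoverkit.comparative_stats import (
    bh_fdr,
    comparison_matrix,
    compute_hl_ratios,
    differential_abundance,
    hl_difference_test,
    pathway_summary,
    ratio_proportion_ztest,
    select_extreme_hl,
    spearman_comparison,
)
from turnoverkit.deconvolution import PeptideObservation
from turnoverkit.kinetics import LN2, TurnoverFit


def make_fit(protein, hl, cohort="A", se=0.01, n_points=12):
    return TurnoverFit(
        protein=protein, cohort=cohort, k=LN2 / hl, half_life=hl,
        slope_se=se, r_squared=0.99, n_points=n_points,
    )


class TestHLRatios:
    def test_identical_groups_ratio_one(self):
        fits = [make_fit(f"P{i}", 2.0 + i) for i in range(5)]
        ratios = compute_hl_ratios(fits, fits)
        assert np.allclose(ratios.table["ratio"], 1.0)
        assert ratios.median_ratio == pytest.approx(1.0)

    def test_multiplicative_effect_recovered(self):
        base = [2.0, 3.0, 5.0, 8.0, 1.5]
        a = [make_fit(f"P{i}", h * 1.6, "CR") for i, h in enumerate(base)]
        b = [make_fit(f"P{i}", h, "CL") for i, h in enumerate(base)]
        ratios = compute_hl_ratios(a, b)
        assert ratios.median_ratio == pytest.approx(1.6)
        assert np.allclose(ratios.table["log2_ratio"], math.log2(1.6))

    def test_disjoint_groups_error(self):
        a = [make_fit("P1", 2.0)]
        b = [make_fit("P2", 2.0)]
        with pytest.raises(ValueError, match="share no proteins"):
            compute_hl_ratios(a, b)

    def test_infinite_hl_excluded(self):
        a = [make_fit("P1", 2.0), make_fit("P2", math.inf)]
        b = [make_fit("P1", 1.0), make_fit("P2", 1.0)]
        ratios = compute_hl_ratios(a, b)
        assert list(ratios.table.index) == ["P1"]


class TestRatioProportionZTest:
    def test_balanced_gives_z_zero(self):
        ratios = np.concatenate([np.full(50, 1.5), np.full(50, 0.5)])
        prop, z, p = ratio_proportion_ztest(ratios)
        assert prop == 0.5 and z == 0.0 and p == pytest.approx(1.0)

    def test_65_of_100(self):
        """p-hat 0.65 on n=100: z = 0.15/sqrt(0.0025) = 3, p ~ 0.0027."""
        ratios = np.concatenate([np.full(65, 2.0), np.full(35, 0.5)])
        prop, z, p = ratio_proportion_ztest(ratios)
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(0.0027, abs=2e-4)

    def test_all_above_one(self):
        prop, z, p = ratio_proportion_ztest(np.full(100, 1.2))
        assert z == pytest.approx(10.0)
        assert p < 1e-15

    def test_ties_at_one_dropped(self):
        ratios = np.concatenate([np.full(10, 1.0), np.full(12, 2.0)])
        prop, z, p = ratio_proportion_ztest(ratios)
        assert prop == 1.0

    def test_small_n_refused(self):
        with pytest.raises(ValueError, match="normal approximation"):
            ratio_proportion_ztest(np.full(9, 1.2))


class TestHLDifference:
    def test_identical_fits_give_p_one(self):
        a = [make_fit("P1", 3.0, se=0.01)]
        b = [make_fit("P1", 3.0, se=0.01)]
        out = hl_difference_test(a, b)
        assert out.loc["P1", "t"] == 0.0
        assert out.loc["P1", "p_value"] == pytest.approx(1.0)

    def test_known_t_statistic(self):
        """k 0.3 vs 0.2 with SE 0.01 each: |t| = 0.1/sqrt(2e-4) ~ 7.07."""
        a = [TurnoverFit("P1", "A", 0.3, LN2 / 0.3, 0.01, 0.99, 12)]
        b = [TurnoverFit("P1", "B", 0.2, LN2 / 0.2, 0.01, 0.99, 12)]
        out = hl_difference_test(a, b)
        assert out.loc["P1", "t"] == pytest.approx(7.0711, abs=1e-3)
        assert out.loc["P1", "p_value"] < 0.001

    def test_missing_side_skipped(self):
        a = [make_fit("P1", 3.0), make_fit("P2", 4.0)]
        b = [make_fit("P1", 3.0)]
        out = hl_difference_test(a, b)
        assert list(out.index) == ["P1"]


class TestBHFDR:
    def test_single_p(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_worked_example(self):
        """Step-up on [0.01, 0.02, 0.03, 0.04] collapses to 0.04 everywhere."""
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_qvalues_monotone_in_p_rank(self, p_list):
        p = np.array(p_list)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


def _abundance_obs(protein, sample, auc, unique=True):
    return PeptideObservation(
        peptide="LAGLK", protein=protein, is_unique=unique, sample=sample,
        cohort="A", time=3.0, intensities=np.array([auc]),
    )


class TestDifferentialAbundance:
    def test_identical_groups_zero_fc(self):
        obs_a = [
            _abundance_obs(f"P{i}", f"a{m}", 100.0 * (i + 1))
            for i in range(4) for m in range(3)
        ]
        obs_b = [
            _abundance_obs(f"P{i}", f"b{m}", 100.0 * (i + 1))
            for i in range(4) for m in range(3)
        ]
        out = differential_abundance(obs_a, obs_b)
        assert np.allclose(out["log2_fc"], 0.0, atol=1e-12)

    def test_global_doubling_normalized_away(self):
        obs_a = [
            _abundance_obs(f"P{i}", f"a{m}", 100.0 * (i + 1) * (1 + 0.01 * m))
            for i in range(5) for m in range(3)
        ]
        obs_b = [
            PeptideObservation(
                "LAGLK", o.protein, True, o.sample.replace("a", "b"), "B",
                3.0, o.intensities * 2.0,
            )
            for o in obs_a
        ]
        out = differential_abundance(obs_a, obs_b)
        assert np.allclose(out["log2_fc"], 0.0, atol=1e-9)

    def test_injected_effect_detected(self):
        rng = np.random.default_rng(3)
        obs_a, obs_b = [], []
        for i in range(40):
            mult = 2.0 if i < 4 else 1.0
            for m in range(12):
                noise_a = rng.lognormal(0, 0.1)
                noise_b = rng.lognormal(0, 0.1)
                obs_a.append(_abundance_obs(f"P{i:02d}", f"a{m}", 100.0 * mult * noise_a))
                obs_b.append(_abundance_obs(f"P{i:02d}", f"b{m}", 100.0 * noise_b))
        out = differential_abundance(obs_a, obs_b)
        hits = set(out.index[out["q_value"] < 0.05])
        assert {f"P{i:02d}" for i in range(4)} <= hits


class TestSelectExtreme:
    def test_shortest_selection(self):
        fits = [make_fit(f"P{i}", float(i + 1)) for i in range(10)]
        assert select_extreme_hl(fits, 0.2, "shortest") == ["P0", "P1"]

    def test_longest_selection(self):
        fits = [make_fit(f"P{i}", float(i + 1)) for i in range(10)]
        assert select_extreme_hl(fits, 0.2, "longest") == ["P9", "P8"]

    def test_tie_break_by_id(self):
        fits = [make_fit(p, 3.0) for p in ("Pb", "Pa", "Pc", "Pd", "Pe")]
        assert select_extreme_hl(fits, 0.4, "shortest") == ["Pa", "Pb"]

    def test_floor_arithmetic_at_study_scale(self):
        fits = [make_fit(f"P{i:04d}", 1.0 + i * 0.01) for i in range(950)]
        assert len(select_extreme_hl(fits, 0.2, "shortest")) == 190


class TestPathwaySummary:
    def mapping(self):
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(20)],
                "pathway_name": ["glycolysis"] * 20,
                "category": ["pathway"] * 20,
            }
        )

    def test_identical_groups_f_zero(self):
        fits = {g: [make_fit(f"P{i}", 2.0 + 0.1 * i, g) for i in range(20)]
                for g in ("A", "B")}
        (s,) = pathway_summary(fits, self.mapping())
        assert s.anova_p == pytest.approx(1.0, abs=1e-9) or s.anova_f == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        fits = {
            "A": [make_fit(f"P{i}", float(rng.normal(3.0, 0.5)), "A") for i in range(20)],
            "B": [make_fit(f"P{i}", float(rng.normal(6.0, 0.5)), "B") for i in range(20)],
        }
        (s,) = pathway_summary(fits, self.mapping())
        assert s.anova_p < 1e-6

    def test_quartile_ordering(self):
        rng = np.random.default_rng(2)
        fits = {"A": [make_fit(f"P{i}", float(rng.lognormal(1, 0.6)), "A") for i in range(20)]}
        (s,) = pathway_summary(fits, self.mapping())
        row = s.per_group.loc["A"]
        assert row["p5"] <= row["q1"] <= row["median"] <= row["q3"] <= row["p95"]

    def test_unmapped_pathway_omitted(self):
        fits = {"A": [make_fit("P0", 3.0, "A")]}
        mapping = pd.DataFrame(
            {"protein_id": ["PX"], "pathway_name": ["orphan"], "category": ["pathway"]}
        )
        assert pathway_summary(fits, mapping) == []


class TestComparisonMatrix:
    def frame(self, proteins, log2, q):
        return pd.DataFrame({"log2_ratio": log2, "q_value": q}, index=proteins)

    def test_single_cell_value(self):
        comp = {"A/B": self.frame(["P1"], [1.0], [0.01])}
        mat = comparison_matrix(comp)
        assert mat.loc["P1", "A/B"] == 1.0

    def test_all_nonsignificant_empty(self):
        comp = {"A/B": self.frame(["P1", "P2"], [1.0, 2.0], [0.5, 0.5])}
        assert comparison_matrix(comp).empty

    def test_matrix_shape(self):
        proteins = [f"P{i}" for i in range(6)]
        comps = {
            label: self.frame(
                proteins, np.linspace(-1, 1, 6), [0.01, 0.5, 0.01, 0.5, 0.5, 0.5]
            )
            for label in ("A/B", "C/D", "E/F")
        }
        mat = comparison_matrix(comps)
        assert mat.shape == (2, 3)


class TestSpearman:
    def test_perfect_agreement(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        res = spearman_comparison(x, x)
        assert res.rho == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        res = spearman_comparison(x, -x)
        assert res.rho == pytest.approx(-1.0)

    def test_closed_form_small_example(self):
        """d = (1, -1, 0): rho = 1 - 6*2/(3*8) = 0.5."""
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        y = pd.Series([2.0, 1.0, 3.0], index=list("abc"))
        res = spearman_comparison(x, y, min_n=3)
        assert res.rho == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=30), index=range(30))
        y = pd.Series(rng.normal(size=30), index=range(30))
        base = spearman_comparison(x, y)
        warped = spearman_comparison(np.exp(x) ** 3, 2 * y + 5)
        assert warped.rho == pytest.approx(base.rho)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_constant_vector_flagged(self):
        x = pd.Series(np.ones(10), index=range(10))
        y = pd.Series(np.arange(10.0), index=range(10))
        res = spearman_comparison(x, y)
        assert res.degenerate
        assert math.isnan(res.rho)

    def test_too_few_shared_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="shared proteins"):
            spearman_comparison(x, x)
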