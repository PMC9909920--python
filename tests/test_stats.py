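import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gliaquant import (
    GroupEffects,
    StudyDesign,
    anova_longitudinal,
    anova_oneway,
    anova_twoway_holm_sidak,
    auc_timecourse,
    delta_delta_ct,
    fit_standard_curve,
    generate_study_tables,
    holm_sidak_adjust,
    percent_of_reference,
    significance_stars,
    standard_curve_interpolate,
)
from gliaquant.stats import _four_pl


def reference_holm_sidak(pvalues):
    """Hand implementation of the step-down formula 1-(1-p)^(m-i+1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order, start=1):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank + 1)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


class TestHolmSidak:
    def test_single_test_unchanged(self):
        assert holm_sidak_adjust([0.05])[0] == pytest.approx(0.05)

    def test_two_equal_ps_hand_formula(self):
        np.testing.assert_allclose(holm_sidak_adjust([0.5, 0.5]), [0.75, 0.75])

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_matches_hand_formula_on_grid(self, m):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9]
        for combo in itertools.product(grid, repeat=m):
            np.testing.assert_allclose(
                holm_sidak_adjust(list(combo)), reference_holm_sidak(combo),
                atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_dominance_and_monotonicity(self, ps):
        adj = holm_sidak_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_equal_ps_reduce_to_single_step_sidak(self):
        p = [0.2] * 4
        np.testing.assert_allclose(holm_sidak_adjust(p), 1 - (1 - 0.2) ** 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.5])

    def test_star_convention(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"
        assert significance_stars(0.2) == "ns"


def _null_table(seed, genotypes=("a", "b", "c")):
    return generate_study_tables(
        StudyDesign(genotypes=genotypes, timepoints=("t0",)),
        GroupEffects(measure="m"), seed=seed)


class TestOneWayAnova:
    def test_identical_groups_null(self):
        tbl = pd.DataFrame({
            "study_id": ["s"] * 8, "animal_id": list("abcdefgh"),
            "genotype": ["x"] * 4 + ["y"] * 4,
            "treatment": ["c"] * 8, "timepoint": ["t0"] * 8,
            "measure": ["m"] * 8,
            "value": [1.0, 2.0, 3.0, 4.0] * 2, "units": ["u"] * 8})
        res = anova_oneway(tbl, "m")
        assert res.f_tests["group"][0] == pytest.approx(0.0, abs=1e-12)
        assert res.comparisons[0].p_adj == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        tbl = _null_table(3, genotypes=("a", "b"))
        res = anova_oneway(tbl, "m")
        va = tbl[tbl.genotype == "a"]["value"]
        vb = tbl[tbl.genotype == "b"]["value"]
        t, p = sps.ttest_ind(va, vb)
        assert res.f_tests["group"][0] == pytest.approx(t ** 2, rel=1e-9)
        assert res.comparisons[0].p_raw == pytest.approx(p, rel=1e-9)

    def test_null_familywise_error_rate_controlled(self):
        rejections = sum(
            any(c.p_adj < 0.05 for c in anova_oneway(_null_table(100 + s), "m").comparisons)
            for s in range(200)
        )
        assert rejections / 200 <= 0.07

    def test_three_sd_effect_high_power(self):
        hits = 0
        for s in range(100):
            tbl = generate_study_tables(
                StudyDesign(genotypes=("wt", "ko"), timepoints=("t0",)),
                GroupEffects(measure="m", noise_sd=0.25,
                             shifts={("ko", "cuprizone", "t0"): 0.75}),
                seed=300 + s)
            res = anova_oneway(tbl, "m")
            hits += any(c.p_adj < 0.05 for c in res.comparisons)
        assert hits / 100 >= 0.9

    def test_small_group_rejected(self):
        tbl = _null_table(1)
        tbl = tbl.drop(tbl[tbl.genotype == "a"].index[1:])
        with pytest.raises(ValueError, match="n="):
            anova_oneway(tbl, "m")

    def test_cross_study_pooling_refused(self):
        t1 = _null_table(1)
        t2 = _null_table(2).assign(study_id="study2")
        with pytest.raises(ValueError, match="stud"):
            anova_oneway(pd.concat([t1, t2]), "m")


class TestTwoWayAnova:
    def _effect_table(self, seed, interaction=0.0):
        shifts = {("ko", "cuprizone", "t1"): interaction}
        return generate_study_tables(
            StudyDesign(genotypes=("wt", "ko"), timepoints=("t0", "t1"),
                        n_per_group=6),
            GroupEffects(measure="m", shifts=shifts), seed=seed)

    def test_balanced_null_familywise_error(self):
        rejections = 0
        for s in range(100):
            res = anova_twoway_holm_sidak(self._effect_table(500 + s), "m")
            rejections += any(c.p_adj < 0.05 for c in res.comparisons)
        assert rejections / 100 <= 0.08

    def test_additive_truth_interaction_p_uniform(self):
        # zero-interaction additive model: interaction p-values ~ U(0,1)
        ps = [
            anova_twoway_holm_sidak(self._effect_table(900 + s), "m")
            .f_tests["interaction"][3]
            for s in range(200)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_interaction_detected_when_present(self):
        res = anova_twoway_holm_sidak(self._effect_table(7, interaction=1.0), "m")
        assert res.f_tests["interaction"][3] < 0.01

    def test_empty_cell_rejected(self):
        tbl = self._effect_table(1)
        tbl = tbl[~((tbl.genotype == "ko") & (tbl.timepoint == "t1"))]
        with pytest.raises(ValueError, match="cell"):
            anova_twoway_holm_sidak(tbl, "m")

    def test_requested_family_only_adjusted(self):
        tbl = self._effect_table(11)
        one = anova_twoway_holm_sidak(
            tbl, "m", comparisons=[(("wt", "t1"), ("ko", "t1"))])
        assert len(one.comparisons) == 1
        # single-contrast family: adjusted equals raw
        assert one.comparisons[0].p_adj == pytest.approx(one.comparisons[0].p_raw)


class TestLongitudinalAnova:
    def test_zero_variance_limit_matches_two_way(self):
        tbl = generate_study_tables(
            StudyDesign(genotypes=("wt", "ko"), timepoints=("t0", "t1", "t2")),
            GroupEffects(measure="m", animal_sd=0.0,
                         shifts={("ko", "cuprizone", "t1"): 1.0}),
            seed=21)
        res = anova_longitudinal(tbl, "m")
        import statsmodels.formula.api as smf

        sub = tbl.assign(_group=tbl.genotype, _time=tbl.timepoint)
        ols = smf.ols("value ~ _group * _time", data=sub).fit()
        np.testing.assert_allclose(np.asarray(res.mixed_fit.fe_params),
                                   ols.params.values, atol=1e-6)

    def test_single_timepoint_falls_back_to_oneway(self):
        tbl = generate_study_tables(
            StudyDesign(genotypes=("wt", "ko"), timepoints=("t0",)),
            GroupEffects(measure="m"), seed=22)
        with pytest.warns(UserWarning, match="one-way"):
            res = anova_longitudinal(tbl, "m")
        assert "group" in res.f_tests

    def test_group_effect_recovered_with_random_intercepts(self):
        eff = 0.5
        tbl = generate_study_tables(
            StudyDesign(genotypes=("wt", "ko"),
                        timepoints=("t0", "t1", "t2"), n_per_group=8),
            GroupEffects(measure="m", noise_sd=0.25, animal_sd=0.25,
                         shifts={("ko", "cuprizone", t): eff
                                 for t in ("t1", "t2")}),
            seed=23)
        res = anova_longitudinal(tbl, "m")
        gaps = {c.contrast: c.estimate for c in res.comparisons}
        assert gaps["ko vs wt @ t1"] == pytest.approx(eff, abs=0.3)

    def test_permuted_group_labels_kill_group_effect(self):
        # permuting genotype labels within timepoint destroys any group
        # signal; rejection should happen at about the nominal rate
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 100
        for s in range(n_sims):
            tbl = generate_study_tables(
                StudyDesign(genotypes=("wt", "ko"),
                            timepoints=("t0", "t1", "t2")),
                GroupEffects(measure="m", noise_sd=0.25, animal_sd=0.25,
                             shifts={("ko", "cuprizone", "t1"): 1.0}),
                seed=700 + s)
            # permute animal-to-genotype assignment
            animals = tbl["animal_id"].unique()
            new_geno = dict(zip(animals,
                                rng.permutation(
                                    tbl.groupby("animal_id")["genotype"]
                                    .first().values)))
            tbl["genotype"] = tbl["animal_id"].map(new_geno)
            res = anova_longitudinal(tbl, "m")
            rejections += res.f_tests["group"][3] < 0.05
        assert rejections / n_sims <= 0.10


class TestDeltaDeltaCt:
    def _records(self):
        return pd.DataFrame({
            "sample": ["c1", "c2", "k1", "k2"],
            "group": ["ctrl", "ctrl", "ko", "ko"],
            "ct_target": [25.0, 25.0, 24.0, 26.0],
            "ct_reference": [20.0, 20.0, 20.0, 20.0],
        })

    def test_control_matching_mean_gives_fold_one(self):
        out = delta_delta_ct(self._records(), "ctrl")
        assert out.loc[0, "fold"] == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        out = delta_delta_ct(self._records(), "ctrl")
        assert out.loc[2, "fold"] == pytest.approx(2.0)
        assert out.loc[3, "fold"] == pytest.approx(0.5)

    def test_control_geometric_mean_is_one(self):
        out = delta_delta_ct(self._records(), "ctrl")
        folds = out[out.group == "ctrl"]["fold"]
        assert sps.gmean(folds) == pytest.approx(1.0)

    def test_missing_ct_rejected(self):
        rec = self._records()
        rec.loc[0, "ct_reference"] = np.nan
        with pytest.raises(ValueError):
            delta_delta_ct(rec, "ctrl")


class TestStandardCurve:
    STANDARDS = np.array([39.0, 78.0, 156.0, 312.0, 625.0, 1250.0, 2500.0])
    TRUE_4PL = (0.04, 1.2, 420.0, 2.6)

    def _curve(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        y = _four_pl(self.STANDARDS, *self.TRUE_4PL)
        y = y * (1 + rng.normal(0, noise, y.size))
        return fit_standard_curve(self.STANDARDS, y)

    def test_inverse_consistency_at_standards(self):
        curve = self._curve()
        for conc in self.STANDARDS:
            resp = curve.predict(conc)
            got, flag = standard_curve_interpolate(curve, resp)
            assert not flag[0]
            assert got[0] == pytest.approx(conc, rel=0.01)

    def test_noisy_recovery_across_working_range(self):
        rng = np.random.default_rng(5)
        curve = self._curve(noise=0.01, seed=5)
        targets = np.array([78.0, 156.0, 312.0, 625.0, 1250.0])
        responses = _four_pl(targets, *self.TRUE_4PL) * (
            1 + rng.normal(0, 0.01, targets.size))
        conc, flags = standard_curve_interpolate(curve, responses)
        assert not flags.any()
        np.testing.assert_allclose(conc, targets, rtol=0.10)

    def test_below_range_flagged_not_extrapolated(self):
        curve = self._curve()
        lo, hi = curve.response_range()
        conc, flags = standard_curve_interpolate(curve, [lo - 0.05])
        assert flags[0] and np.isnan(conc[0])

    def test_non_monotone_standards_rejected(self):
        y = _four_pl(self.STANDARDS, *self.TRUE_4PL)
        y[3] = y[0]  # break monotonicity
        with pytest.raises(ValueError, match="monotone"):
            fit_standard_curve(self.STANDARDS, y)


class TestAssayHelpers:
    def test_auc_hand_example(self):
        assert auc_timecourse([0, 1, 2], [0, 2, 2]) == pytest.approx(3.0)

    def test_auc_constant(self):
        assert auc_timecourse([0, 2, 5], [3, 3, 3]) == pytest.approx(15.0)

    def test_auc_matches_loop_trapezoid(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 12, 20))
        v = rng.uniform(0, 5, 20)
        loop = sum((t[i + 1] - t[i]) * (v[i] + v[i + 1]) / 2
                   for i in range(19))
        assert auc_timecourse(t, v) == pytest.approx(loop, rel=1e-12)

    def test_auc_unordered_times_rejected(self):
        with pytest.raises(ValueError):
            auc_timecourse([0, 2, 1], [1, 1, 1])

    def test_percent_of_reference(self):
        out = percent_of_reference([1000.0], [4000.0, 4000.0])
        assert out[0] == pytest.approx(25.0)

    def test_reference_maps_to_mean_100(self):
        ref = [3.0, 5.0, 4.0]
        assert percent_of_reference(ref, ref).mean() == pytest.approx(100.0)

    def test_percent_scale_invariance(self):
        vals, ref = [2.0, 3.0], [4.0, 6.0]
        np.testing.assert_allclose(
            percent_of_reference(vals, ref),
            percent_of_reference([10 * v for v in vals], [10 * r for r in ref]))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_of_reference([1.0], [0.0, 0.0])
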