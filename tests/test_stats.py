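import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from usvkit.stats import (
    CohortAnova, run_full_analysis, summarize_groups, tukey_posthoc,
    two_way_anova,
)
from usvkit.synth import CohortDesign, simulate_cohort

from conftest import random_unbalanced_table


class TestTwoWayAnova:
    def test_balanced_toy_hand_decomposition(self, balanced_toy):
        a = two_way_anova(balanced_toy, "y")
        assert a.ss["genotype"] == pytest.approx(2.0, abs=1e-10)
        assert a.ss["sex"] == pytest.approx(32.0, abs=1e-10)
        assert a.ss["genotype:sex"] == pytest.approx(0.0, abs=1e-10)
        assert a.ss_resid == pytest.approx(8.0, abs=1e-10)
        assert a.f["genotype"] == pytest.approx(1.0, abs=1e-10)
        assert a.df_resid == 4

    def test_types_coincide_on_balanced_data(self, balanced_toy):
        results = {t: two_way_anova(balanced_toy, "y", ss_type=t)
                   for t in ("I", "II", "III")}
        for term in ("genotype", "sex", "genotype:sex"):
            vals = [r.ss[term] for r in results.values()]
            assert max(vals) - min(vals) < 1e-10

    def test_location_invariance(self, balanced_toy):
        shifted = balanced_toy.assign(y=balanced_toy["y"] + 1000.0)
        a0 = two_way_anova(balanced_toy, "y")
        a1 = two_way_anova(shifted, "y")
        for term in ("genotype", "sex", "genotype:sex"):
            assert a1.ss[term] == pytest.approx(a0.ss[term], abs=1e-6)
            assert a1.f[term] == pytest.approx(a0.f[term], rel=1e-9)

    def test_matches_projection_oracle_on_random_unbalanced_tables(self):
        """Independent check: statsmodels Type III with sum-to-zero coding."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(42)
        for _ in range(25):
            t = random_unbalanced_table(rng)
            a = two_way_anova(t, "y")
            fit = smf.ols("y ~ C(genotype, Sum)*C(sex, Sum)", data=t).fit()
            tab = anova_lm(fit, typ=3)
            ref = {
                "genotype": tab.loc["C(genotype, Sum)"],
                "sex": tab.loc["C(sex, Sum)"],
                "genotype:sex": tab.loc["C(genotype, Sum):C(sex, Sum)"],
            }
            for term, row in ref.items():
                assert a.ss[term] == pytest.approx(row["sum_sq"], rel=1e-8)
                assert a.f[term] == pytest.approx(row["F"], rel=1e-8)
                assert a.p[term] == pytest.approx(row["PR(>F)"], rel=1e-6, abs=1e-12)

    def test_empty_cell_error_names_the_cell(self, balanced_toy):
        broken = balanced_toy[
            ~((balanced_toy["genotype"] == "KO") & (balanced_toy["sex"] == "M"))
        ]
        with pytest.raises(ValueError, match="genotype=KO, sex=M"):
            two_way_anova(broken, "y")

    def test_zero_residual_variance_is_an_error(self, balanced_toy):
        constant = balanced_toy.assign(y=5.0)
        with pytest.raises(ValueError, match="residual variance"):
            two_way_anova(constant, "y")


class TestTukey:
    def test_balanced_toy_q_statistic(self, balanced_toy):
        tk = tukey_posthoc(balanced_toy, "y")
        # WT-F mean 7, KO-M mean 2, MSE 2, n=2 each -> q = 5/1 = 5
        row = tk.pairs[
            (tk.pairs["group1"] == "WT-F") & (tk.pairs["group2"] == "KO-M")
        ].iloc[0]
        assert row["q"] == pytest.approx(5.0, abs=1e-10)
        assert row["p_adj"] == pytest.approx(
            float(sps.studentized_range.sf(5.0, 4, 4)), rel=1e-9
        )

    def test_identical_cells_give_zero_diff_and_p_near_one(self):
        rows = []
        vals = [4.0, 6.0, 8.0]
        for g, s in [("WT", "M"), ("WT", "F"), ("KO", "M"), ("KO", "F")]:
            for v in vals:
                rows.append({"genotype": g, "sex": s, "y": v})
        # tiny per-cell perturbation keeps residual variance positive
        t = pd.DataFrame(rows)
        t["y"] += np.random.default_rng(0).normal(0, 1e-6, len(t))
        tk = tukey_posthoc(t, "y")
        assert np.allclose(tk.pairs["mean_diff"], 0.0, atol=1e-5)
        assert (tk.pairs["p_adj"] > 0.99).all()

    def test_adjusted_p_at_least_pairwise_t_p(self):
        rng = np.random.default_rng(5)
        t = random_unbalanced_table(rng)
        a = two_way_anova(t, "y")
        tk = tukey_posthoc(t, "y")
        cells = {}
        for g, s in [("WT", "F"), ("WT", "M"), ("KO", "F"), ("KO", "M")]:
            v = t[(t["genotype"] == g) & (t["sex"] == s)]["y"].to_numpy()
            cells["-".join((g, s))] = v
        for _, row in tk.pairs.iterrows():
            v1, v2 = cells[row["group1"]], cells[row["group2"]]
            se = np.sqrt(a.mse * (1 / len(v1) + 1 / len(v2)))
            tstat = abs(v1.mean() - v2.mean()) / se
            p_t = 2 * sps.t.sf(tstat, a.df_resid)
            assert row["p_adj"] >= p_t - 1e-12

    def test_matches_statsmodels_tukeyhsd(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(11)
        t = random_unbalanced_table(rng)
        cell = t["genotype"] + "-" + t["sex"]
        res = sm.pairwise_tukeyhsd(t["y"].to_numpy(), cell.to_numpy())
        ref = {
            frozenset((str(row[0]), str(row[1]))): p
            for row, p in zip(res.summary().data[1:], res.pvalues)
        }
        tk = tukey_posthoc(t, "y")
        for _, row in tk.pairs.iterrows():
            key = frozenset((row["group1"], row["group2"]))
            assert row["p_adj"] == pytest.approx(ref[key], abs=1e-6)


class TestSummaries:
    def test_mean_and_sem_closed_form(self):
        t = pd.DataFrame(
            {
                "genotype": ["WT", "WT", "KO", "KO"],
                "sex": ["M", "M", "M", "M"],
                "y": [3.0, 5.0, 1.0, 1.0],
            }
        )
        t = pd.concat(
            [t, pd.DataFrame({"genotype": ["WT", "KO"], "sex": ["F", "F"],
                              "y": [2.0, 2.0]})],
            ignore_index=True,
        )
        summ = summarize_groups(t, ["y"])
        wtm = summ[(summ["genotype"] == "WT") & (summ["sex"] == "M")].iloc[0]
        assert wtm["mean"] == pytest.approx(4.0)
        assert wtm["sem"] == pytest.approx(1.0)  # sd=sqrt(2), n=2
        # n == 1 cells report SEM as missing
        wtf = summ[(summ["genotype"] == "WT") & (summ["sex"] == "F")].iloc[0]
        assert np.isnan(wtf["sem"])

    def test_default_cohort_echoes_design_sizes(self):
        table = simulate_cohort(CohortDesign(seed=1))
        summ = summarize_groups(table, ["total_calls"])
        sizes = {
            (r["genotype"], r["sex"]): r["n"] for _, r in summ.iterrows()
        }
        assert sizes == {("WT", "M"): 13, ("WT", "F"): 26,
                         ("KO", "M"): 7, ("KO", "F"): 9}

    def test_permutation_invariance(self):
        table = simulate_cohort(CohortDesign(seed=6))
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = summarize_groups(table).reset_index(drop=True)
        b = summarize_groups(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestModelObjects:
    def test_fit_returns_results_with_summary(self, balanced_toy):
        res = CohortAnova.from_dataframe(balanced_toy, "y").fit()
        assert res.anova.f["genotype"] == pytest.approx(1.0)
        text = res.summary()
        assert "genotype" in text and "Tukey" in text
        assert res.significant_terms(alpha=0.05) == ["sex"]

    def test_report_deterministic_given_table(self):
        table = simulate_cohort(CohortDesign(seed=14))
        r1 = run_full_analysis(table)
        r2 = run_full_analysis(table)
        pd.testing.assert_frame_equal(r1.anova_frame(), r2.anova_frame())
        assert r1.n_genotype_significant == r2.n_genotype_significant
        assert r1.male_specific_types == r2.male_specific_types

    def test_huge_effect_always_flags_the_affected_types(self):
        # genotype effect in exactly 4 types at overwhelming effect size:
        # every affected type is detected in every replicate cohort, and
        # the modal significant-type count equals 4 (unaffected types can
        # still false-positive at rate alpha)
        from usvkit.taxonomy import CALL_TYPES

        gmult = np.ones(10)
        affected = [1, 3, 5, 8]
        gmult[affected] = 0.05
        expected = {CALL_TYPES[i].value for i in affected}
        rng = np.random.default_rng(19)
        counts = []
        for _ in range(15):
            design = CohortDesign(
                noise_model="gaussian",
                baseline_mean_per_type=np.full(10, 200.0),
                gaussian_sd=5.0,
                genotype_mult=gmult,
                seed=int(rng.integers(2**31)),
            )
            report = run_full_analysis(simulate_cohort(design))
            assert expected <= set(report.genotype_significant_types)
            counts.append(report.n_genotype_significant)
        assert np.bincount(counts).argmax() == len(affected)

    def test_null_cohort_rejects_near_alpha(self):
        # genotype-significant type count under the null stays plausible
        # for Binomial(10, 0.05): not every type significant
        rng = np.random.default_rng(100)
        counts = []
        for _ in range(40):
            design = CohortDesign(
                noise_model="gaussian", seed=int(rng.integers(2**31))
            )
            report = run_full_analysis(simulate_cohort(design))
            counts.append(report.n_genotype_significant)
        # mean of Binomial(10, 0.05) is 0.5; over 40 cohorts the average
        # should be well below 2 (loose 6-sigma bound)
        assert np.mean(counts) < 2.0
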