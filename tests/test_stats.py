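"""Statistics layer: zero-safe log transform, Welch tests, split-plot
ANOVA (against a hand-computed oracle and pingouin), post-hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import aggrebout as ab
from aggrebout.stats import tukey_hsd


# hand-computed split-plot oracle on a fixed 2x2 design:
# genotype g1: subjects with (t1, t2) = (10,12) (11,14) (9,11) (12,13)
# genotype g2: (16,13) (15,11) (17,14) (14,12)
TOY_SS = {"between": 25.0, "subj_err": 18.0, "within": 1.0,
          "interaction": 25.0, "residual": 2.0}
TOY_F = {"between": 25.0 / 3.0, "within": 3.0, "interaction": 75.0}


def toy_table():
    vals = {
        "s1": ("g1", 10, 12), "s2": ("g1", 11, 14),
        "s3": ("g1", 9, 11), "s4": ("g1", 12, 13),
        "s5": ("g2", 16, 13), "s6": ("g2", 15, 11),
        "s7": ("g2", 17, 14), "s8": ("g2", 14, 12),
    }
    rows = []
    for s, (g, y1, y2) in vals.items():
        rows.append({"animal_id": s, "genotype": g, "treatment": "t1", "y": y1})
        rows.append({"animal_id": s, "genotype": g, "treatment": "t2", "y": y2})
    return pd.DataFrame(rows)


class TestZeroSafeLog:
    def test_no_zero_branch_plain_log(self):
        r = ab.zero_safe_log(np.array([1.0, 2.0, 3.0, 4.0]))
        assert r.constant == 0.0
        assert np.allclose(r.values, np.log([1, 2, 3, 4]))

    def test_constant_is_sqrt_q1_over_q3(self):
        # Q1 = 1, Q3 = 4 with a zero present -> c = sqrt(1/4) = 0.5
        x = np.array([0.0, 1.0, 1.0, 4.0, 4.0])
        # force the quartiles: percentile(linear) of this set
        q1, q3 = np.percentile(x, [25, 75])
        r = ab.zero_safe_log(x)
        assert r.constant == pytest.approx(np.sqrt(q1 / q3))

    def test_round_trip(self):
        x = np.array([0.0, 3.0, 10.0, 55.0, 2.0])
        r = ab.zero_safe_log(x)
        assert np.allclose(np.exp(r.values) - r.constant, x)

    def test_degenerate_quartile_fallback(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 8.0])  # Q1 = 0
        with pytest.warns(UserWarning):
            r = ab.zero_safe_log(x)
        assert r.constant == pytest.approx(4.0)

    def test_rejects_negative_and_all_zero(self):
        with pytest.raises(ValueError):
            ab.zero_safe_log(np.array([-1.0, 2.0]))
        with pytest.raises(ValueError):
            ab.zero_safe_log(np.zeros(5))


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        r = ab.welch_t(a, a)
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_matches_direct_formula_and_scipy(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        r = ab.welch_t(a, b)
        # independent oracle: direct formula evaluation
        v1, v2 = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_ref = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
        df_ref = (v1 + v2) ** 2 / (v1**2 / 4 + v2**2 / 4)
        assert r.t == pytest.approx(t_ref)
        assert r.df == pytest.approx(df_ref)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 12)
        r1, r2 = ab.welch_t(a, b), ab.welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.df == pytest.approx(r2.df)
        assert r1.p == pytest.approx(r2.p)

    def test_summary_agrees_with_raw(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(5, 1, 9), rng.normal(4, 3, 14)
        raw = ab.welch_t(a, b)
        summ = ab.welch_t_from_summary(
            a.mean(), a.std(ddof=1), 9, b.mean(), b.std(ddof=1), 14
        )
        assert raw.t == pytest.approx(summ.t)
        assert raw.df == pytest.approx(summ.df)

    def test_equal_means_zero_t(self):
        assert ab.welch_t_from_summary(5, 1, 10, 5, 3, 8).t == 0.0

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            ab.welch_t_from_summary(1, 0, 5, 2, 0, 5)
        with pytest.raises(ValueError):
            ab.welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestMixedAnova:
    def test_matches_hand_oracle(self):
        anova = ab.mixed_rm_anova(
            toy_table(), dv="y", between="genotype", within="treatment"
        )
        eff = anova.effects.set_index("effect")
        assert eff.loc["genotype", "SS"] == pytest.approx(TOY_SS["between"])
        assert eff.loc["treatment", "SS"] == pytest.approx(TOY_SS["within"])
        assert eff.loc["genotype:treatment", "SS"] == pytest.approx(
            TOY_SS["interaction"]
        )
        assert anova.ms_subject_error * anova.df_subject_error == pytest.approx(
            TOY_SS["subj_err"]
        )
        assert anova.ms_residual * anova.df_residual == pytest.approx(
            TOY_SS["residual"]
        )
        assert eff.loc["genotype", "F"] == pytest.approx(TOY_F["between"])
        assert eff.loc["treatment", "F"] == pytest.approx(TOY_F["within"])
        assert eff.loc["genotype:treatment", "F"] == pytest.approx(
            TOY_F["interaction"]
        )

    def test_cross_checks_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for g in ("g1", "g2"):
            for i in range(7):
                base = rng.normal(10 if g == "g1" else 12, 2)
                for trt in ("a", "b"):
                    rows.append(
                        {
                            "animal_id": f"{g}{i}", "genotype": g,
                            "treatment": trt,
                            "y": base + (1.5 if trt == "b" else 0)
                            + rng.normal(0, 1),
                        }
                    )
        df = pd.DataFrame(rows)
        ours = ab.mixed_rm_anova(df, dv="y").effects.set_index("effect")
        ref = pingouin.mixed_anova(
            df, dv="y", between="genotype", within="treatment",
            subject="animal_id",
        ).set_index("Source")
        assert ours.loc["genotype", "F"] == pytest.approx(
            ref.loc["genotype", "F"], rel=1e-6
        )
        assert ours.loc["treatment", "F"] == pytest.approx(
            ref.loc["treatment", "F"], rel=1e-6
        )
        assert ours.loc["genotype:treatment", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_location_invariance(self):
        base = ab.mixed_rm_anova(toy_table(), dv="y")
        shifted_table = toy_table().assign(y=lambda d: d.y + 100)
        shifted = ab.mixed_rm_anova(shifted_table, dv="y")
        assert np.allclose(base.effects.F, shifted.effects.F)

    def test_duplicated_within_levels_kill_treatment_ss(self):
        df = toy_table()
        wide = df[df.treatment == "t1"].copy()
        dup = wide.assign(treatment="t2")
        both = pd.concat([wide, dup])
        anova = ab.mixed_rm_anova(both, dv="y")
        eff = anova.effects.set_index("effect")
        assert eff.loc["treatment", "SS"] == pytest.approx(0.0, abs=1e-10)

    def test_incomplete_subjects_dropped(self):
        df = toy_table()
        df = df[~((df.animal_id == "s1") & (df.treatment == "t2"))]
        anova = ab.mixed_rm_anova(df, dv="y")
        assert anova.n_dropped_subjects == 1
        assert anova.n_complete_subjects == 7

    def test_too_few_subjects_rejected(self):
        df = toy_table()
        df = df[df.animal_id.isin(["s1", "s5"])]
        with pytest.raises(ValueError):
            ab.mixed_rm_anova(df, dv="y")


class TestTukey:
    def test_toy_q_statistics(self):
        # frozen from manual studentized-range arithmetic on the toy set
        anova = ab.mixed_rm_anova(toy_table(), dv="y")
        ph = tukey_hsd(anova).set_index(["group1", "group2"])
        assert ph.loc[("g1/t2", "g2/t2"), "q"] == pytest.approx(0.0)
        assert ph.loc[("g1/t2", "g2/t2"), "p_adj"] == pytest.approx(1.0)
        assert ph.loc[("g1/t1", "g2/t1"), "q"] == pytest.approx(5.7735026919)
        assert ph.loc[("g1/t1", "g1/t2"), "q"] == pytest.approx(6.9282032303)
        assert ph.loc[("g1/t1", "g2/t1"), "p_adj"] == pytest.approx(
            0.0249660, abs=1e-5
        )

    def test_two_cell_design_equals_t_test(self):
        """With only 2 cells the studentized-range p coincides with the
        unadjusted two-sided p of the corresponding t statistic."""
        q, df = 3.1, 10
        p_range = float(sps.studentized_range.sf(q, 2, df))
        p_t = 2 * sps.t.sf(q / np.sqrt(2), df)
        assert p_range == pytest.approx(p_t, rel=1e-6)


class TestSidak:
    def test_examples(self):
        assert ab.sidak_adjust([0.0], 5)[0] == 0.0
        assert ab.sidak_adjust([0.2], 1)[0] == pytest.approx(0.2)
        assert ab.sidak_adjust([0.0253], 2)[0] == pytest.approx(0.0500, abs=5e-5)

    def test_monotone_in_p_and_m(self):
        p = np.linspace(0, 1, 11)
        adj = ab.sidak_adjust(p, 11)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(ab.sidak_adjust(p, 20) >= adj)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ab.sidak_adjust([1.2])
        with pytest.raises(ValueError):
            ab.sidak_adjust([0.1, 0.2], m=1)


class TestPowerCalibration:
    def test_welch_power_matches_normal_approximation(self):
        """With a genotype effect of one within-group SD at n = 18/group,
        simulated Welch power tracks the closed-form normal approximation
        within 5 percentage points."""
        n, n_rep = 18, 2000
        sd = np.sqrt(0.6**2 + 0.5**2)  # subject + residual variation
        params = dict(
            n_per_genotype=n, ages_months=(6,), onset_age_months=5,
            genotype_effect=sd, zero_prob=0.0,
        )
        rej = 0
        for i in range(n_rep):
            df = ab.simulate_cohort(ab.SimCohortParams(**params, seed=i))
            df = df[df.treatment == "vehicle"]  # one session per animal
            logs = np.log(df.attack_duration_s.to_numpy())
            g = df.genotype.to_numpy()
            r = ab.welch_t(logs[g == "SAMP8"], logs[g == "SAMR1"])
            rej += r.p < 0.05
        power = rej / n_rep
        expected = sps.norm.cdf(np.sqrt(n / 2) - sps.norm.ppf(0.975))
        assert abs(power - expected) < 0.05
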