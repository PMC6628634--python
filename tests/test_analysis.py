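"""Group statistics: t tests, Bonferroni, delta-EV optimality, mixed ANOVA,
clinical correlations and curve export."""

import numpy as np
import pandas as pd
import pytest

from mdmcpt import (CPTParams, ChoiceDataset, bonferroni, delta_ev_analysis,
                    delta_ev_long, equal_probability_subset, expected_value,
                    independent_t_test, mixed_anova, one_sample_test_vs_one,
                    parameter_clinical_correlations, plot_functions,
                    group_parameter_tests)
from mdmcpt import value, weight


def sample_with(mean, sd, n, seed=0):
    """Affine-standardised sample with the exact requested mean and SD."""
    x = np.random.default_rng(seed).standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestIndependentT:
    def test_hand_computed_pooled_t(self):
        """Textbook oracle: {1,2,3} vs {4,5,6} -> t = -3/sqrt(2/3), df = 4."""
        r = independent_t_test([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert r.dof == 4
        assert r.cohens_d == pytest.approx(-3.0, abs=1e-12)
        assert r.ci_low < r.mean_diff < r.ci_high

    def test_equal_samples_give_zero_t(self):
        r = independent_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_dof_follows_study_convention(self):
        r = independent_t_test(np.arange(20) + 0.1 * np.random.default_rng(0).random(20),
                               np.arange(10))
        assert r.dof == 28

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            independent_t_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            independent_t_test([1.0], [1.0, 2.0])


class TestOneSampleVsOne:
    def test_near_constant_sample_has_tiny_t(self):
        x = 1.0 + 1e-9 * np.array([1, -1, 2, -2, 0.5])
        r = one_sample_test_vs_one(x)
        assert abs(r.statistic) < 1.0

    def test_matches_closed_form(self):
        x = sample_with(1.255, 0.437, 20)
        r = one_sample_test_vs_one(x)
        assert r.statistic == pytest.approx(0.255 / (0.437 / np.sqrt(20)), abs=1e-9)
        assert r.cohens_d == pytest.approx(0.255 / 0.437, abs=1e-9)
        assert r.dof == 19


class TestBonferroni:
    @pytest.mark.parametrize("family,threshold", [(12, 0.05 / 12), (6, 0.05 / 6),
                                                  (16, 0.05 / 16), (1, 0.05)])
    def test_thresholds(self, family, threshold):
        out = bonferroni([0.004, 0.02, 0.0], family)
        assert out["corrected_alpha"].iloc[0] == pytest.approx(threshold)
        assert bool(out["significant"].iloc[2])  # p = 0 always rejects

    def test_family_size_must_be_positive(self):
        with pytest.raises(ValueError):
            bonferroni([0.01], 0)


class TestDeltaEV:
    @staticmethod
    def agent_records(task, policy, n_subjects=1, seed=0):
        """Build choice records for a deterministic or random policy on the
        equal-probability single-domain subset."""
        rng = np.random.default_rng(seed)
        trials = equal_probability_subset(task, single_domain_only=True)
        rows = []
        for s in range(n_subjects):
            for t in trials:
                ev_a = expected_value(t.gamble_a)
                ev_b = expected_value(t.gamble_b)
                if policy == "ev_max":
                    choice = "A" if ev_a > ev_b else "B"
                else:
                    choice = "A" if rng.random() < 0.5 else "B"
                rows.append((f"s{s}", "HC", t.trial_id, choice, False))
        return pd.DataFrame(rows, columns=["subject_id", "group", "trial_id",
                                           "choice", "timeout"])

    def test_ev_maximizer_attains_recorded_ceiling(self, task):
        rec = self.agent_records(task, "ev_max")
        ds = ChoiceDataset(task=task, records=rec)
        out = delta_ev_analysis(ds)
        assert out["mean_delta_ev"].iloc[0] == pytest.approx(
            task.metadata["optimal_delta_ev_mean"])
        assert out["mean_delta_ev"].iloc[0] == pytest.approx(
            out["max_attainable"].iloc[0])

    def test_no_subject_exceeds_ceiling(self, task, typical_params):
        from mdmcpt import simulate_cohort, GroupSpec
        ds = simulate_cohort([GroupSpec("HC", 10)], task, seed=3)
        out = delta_ev_analysis(ds)
        assert (out["mean_delta_ev"] <= out["max_attainable"] + 1e-9).all()

    def test_random_chooser_centred_on_zero(self, task):
        rec = self.agent_records(task, "random", n_subjects=500, seed=1)
        ds = ChoiceDataset(task=task, records=rec)
        out = delta_ev_analysis(ds)
        se = out["mean_delta_ev"].std(ddof=1) / np.sqrt(len(out))
        assert abs(out["mean_delta_ev"].mean()) < 4 * se

    def test_per_type_means_present(self, task):
        rec = self.agent_records(task, "ev_max")
        out = delta_ev_analysis(ChoiceDataset(task=task, records=rec))
        assert {"mean_delta_ev_gain_only", "mean_delta_ev_loss_only"} \
            <= set(out.columns)


class TestMixedAnova:
    @staticmethod
    def toy_table():
        # 2 groups x 3 trials x 2 subjects each, hand-checkable
        rows = []
        data = {
            ("g1", "s1"): [10, 12, 14], ("g1", "s2"): [11, 13.5, 15],
            ("g2", "s3"): [20, 19, 18], ("g2", "s4"): [22, 21.5, 19],
        }
        for (g, s), ys in data.items():
            for t, y in enumerate(ys):
                rows.append((s, g, t, float(y)))
        return pd.DataFrame(rows, columns=["subject_id", "group", "trial_id",
                                           "delta_ev"])

    @staticmethod
    def hand_ss_decomposition(df):
        """Textbook two-way mixed sums-of-squares oracle (balanced)."""
        k = df["trial_id"].nunique()
        G = df["delta_ev"].mean()
        subj = df.groupby(["subject_id", "group"])["delta_ev"].mean().reset_index()
        N = len(subj)
        ss_subj = k * ((subj["delta_ev"] - G) ** 2).sum()
        gmeans = df.groupby("group")["delta_ev"].mean()
        gsizes = subj.groupby("group").size()
        ss_group = k * sum(gsizes[g] * (gmeans[g] - G) ** 2 for g in gmeans.index)
        ss_between_err = ss_subj - ss_group
        tmeans = df.groupby("trial_id")["delta_ev"].mean()
        ss_trial = N * ((tmeans - G) ** 2).sum()
        cells = df.groupby(["group", "trial_id"])["delta_ev"].mean()
        ss_cells = sum(gsizes[g] * (cells[g, t] - G) ** 2
                       for g in gmeans.index for t in tmeans.index)
        ss_inter = ss_cells - ss_group - ss_trial
        ss_total = ((df["delta_ev"] - G) ** 2).sum()
        ss_within_err = ss_total - ss_subj - ss_trial - ss_inter
        f_group = (ss_group / (len(gmeans) - 1)) / (ss_between_err / (N - 2))
        f_trial = (ss_trial / (k - 1)) / (ss_within_err / ((N - 2) * (k - 1)))
        f_inter = (ss_inter / (k - 1)) / (ss_within_err / ((N - 2) * (k - 1)))
        return f_group, f_trial, f_inter

    def test_matches_hand_ss_oracle(self):
        df = self.toy_table()
        aov = mixed_anova(df)
        f_group, f_trial, f_inter = self.hand_ss_decomposition(df)
        got = {r.Source: r.F for r in aov.itertuples()}
        assert got["group"] == pytest.approx(f_group, rel=1e-9)
        assert got["trial_id"] == pytest.approx(f_trial, rel=1e-9)
        assert got["Interaction"] == pytest.approx(f_inter, rel=1e-9)

    def test_equal_group_mean_profiles_give_zero_f(self):
        # g2 subjects mirror g1 with offsets +/-0.5 that cancel in the
        # group mean, so the between-group effect is exactly zero
        df = self.toy_table()
        remap = df[df.group == "g1"].copy()
        remap["group"] = "g2"
        remap["delta_ev"] += remap["subject_id"].map({"s1": 0.5, "s2": -0.5})
        remap["subject_id"] = remap["subject_id"].map({"s1": "s3", "s2": "s4"})
        df2 = pd.concat([df[df.group == "g1"], remap], ignore_index=True)
        aov = mixed_anova(df2)
        f = aov.loc[aov.Source == "group", "F"].iloc[0]
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_groups(self):
        df = self.toy_table()
        with pytest.raises(ValueError, match="two groups"):
            mixed_anova(df[df.group == "g1"])

    def test_missing_cells_dropped_listwise(self):
        df = self.toy_table().iloc[1:]  # s1 loses trial 0
        with pytest.warns(UserWarning, match="missing cells"):
            aov = mixed_anova(df)
        assert np.isfinite(aov["F"].iloc[0])

    def test_group_effect_direction_low_alpha_less_optimal(self, task):
        """Simulated low-alpha agents are less EV-optimal on the subset."""
        from mdmcpt import GroupSpec, simulate_cohort
        groups = [
            GroupSpec("HC", 12, param_means=CPTParams(alpha=0.85, lam=1.25,
                                                      gamma=0.7, delta=0.9)),
            GroupSpec("OCD", 12, param_means=CPTParams(alpha=0.3, lam=1.25,
                                                       gamma=0.7, delta=0.9)),
        ]
        ds = simulate_cohort(groups, task, seed=21)
        long = delta_ev_long(ds)
        means = long.groupby("group")["delta_ev"].mean()
        assert means["OCD"] < means["HC"]
        aov = mixed_anova(long)
        d = aov.loc[aov.Source == "group", "cohens_d_between"].iloc[0]
        assert d > 0  # ordered (HC, OCD): HC more optimal


class TestCorrelations:
    @staticmethod
    def frames(n, r_true, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        fits = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                             "group": "GAD",
                             "alpha": np.exp(0.1 * rng.standard_normal(n)),
                             "lam": np.exp(0.2 * z),
                             "gamma": np.exp(0.1 * rng.standard_normal(n)),
                             "delta": np.exp(0.1 * rng.standard_normal(n))})
        noise = rng.standard_normal(n)
        wsas = 20 + 5 * (r_true * z + np.sqrt(1 - r_true ** 2) * noise)
        clin = pd.DataFrame({"subject_id": fits["subject_id"], "WSAS": wsas})
        return fits, clin

    def test_perfect_correlation(self):
        fits, clin = self.frames(50, 0.0)
        clin["WSAS"] = fits["lam"]  # y = x exactly
        out = parameter_clinical_correlations(fits, clin, family_size=16)
        r = out[(out.parameter == "lam")].iloc[0]
        assert r.r == pytest.approx(1.0)
        assert bool(r.significant)

    def test_null_correlation_small(self):
        fits, clin = self.frames(5000, 0.0, seed=3)
        out = parameter_clinical_correlations(fits, clin, family_size=16)
        assert (out["r"].abs() < 0.05).all()

    def test_constant_column_skipped_with_warning(self):
        fits, clin = self.frames(20, 0.5)
        clin["WSAS"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            out = parameter_clinical_correlations(fits, clin, family_size=16)
        assert len(out) == 0

    def test_family_threshold(self):
        fits, clin = self.frames(30, 0.2)
        out = parameter_clinical_correlations(fits, clin, family_size=16)
        assert out["corrected_alpha"].iloc[0] == pytest.approx(0.05 / 16)


class TestGroupParameterTests:
    def test_twelve_tests_for_four_groups(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, n in [("HC", 20), ("GAD", 15), ("SAD", 14), ("OCD", 10)]:
            for i in range(n):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             **{p: float(np.exp(0.2 * rng.standard_normal()))
                                for p in ("alpha", "lam", "gamma", "delta")}})
        out = group_parameter_tests(pd.DataFrame(rows), family_size=12)
        assert len(out) == 12
        np.testing.assert_allclose(out["corrected_alpha"], 0.05 / 12)
        hc_ocd = out[out.comparison == "HC-vs-OCD"]
        assert (hc_ocd["dof"] == 28).all()


class TestCurves:
    def test_identity_params_export_straight_lines(self, tmp_path):
        paths = plot_functions({"HC": CPTParams()}, tmp_path)
        vt = pd.read_csv(paths["value_csv"])
        wt = pd.read_csv(paths["weight_csv"])
        np.testing.assert_allclose(vt["HC"], vt["x"], atol=1e-9)
        np.testing.assert_allclose(wt["HC"], wt["p"], atol=1e-9)

    def test_equal_weighting_params_identical_curves(self, tmp_path):
        a = CPTParams(alpha=0.6, lam=2.0, gamma=0.7, delta=0.9)
        b = CPTParams(alpha=1.2, lam=1.1, gamma=0.7, delta=0.9)
        paths = plot_functions({"A": a, "B": b}, tmp_path)
        wt = pd.read_csv(paths["weight_csv"])
        np.testing.assert_array_equal(wt["A"], wt["B"])

    def test_tables_reevaluate_to_model_functions(self, tmp_path, typical_params):
        paths = plot_functions({"G": typical_params}, tmp_path)
        vt = pd.read_csv(paths["value_csv"])
        wt = pd.read_csv(paths["weight_csv"])
        np.testing.assert_allclose(vt["G"], value(vt["x"].to_numpy(), typical_params),
                                   rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(wt["G"], weight(wt["p"].to_numpy(), typical_params),
                                   rtol=1e-12, atol=1e-12)
        import os
        assert os.path.exists(paths["value_png"])
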