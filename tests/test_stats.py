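import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from typeslip import io as kio
from typeslip.stats import (AnalysisError, delong_test, delong_variance,
                            error_iki_regression, exclude_outlier_controls,
                            filter_ikis, fit_updrs_gam, mixed_anova_iki,
                            rank_auc, roc_analysis, summarize, sweep_auc)


def kp_frame(ikis, categories, language="en", group="control", pid="p1"):
    n = len(ikis)
    return pd.DataFrame({
        "participant_id": [pid] * n,
        "sentence_id": 0,
        "typed_index": np.arange(n),
        "iki_ms": np.asarray(ikis, dtype=float),
        "category": pd.Categorical(categories, categories=["correct", "error", "unscored"]),
        "group": group,
        "language": language,
    })


class TestFilterIkis:
    def test_uniform_ikis_percentile_threshold(self):
        kp = kp_frame(np.arange(1, 1001), ["correct"] * 1000)
        out = filter_ikis(kp)
        assert out.thresholds["en"] == pytest.approx(995.005, abs=0.01)
        assert len(out.keypresses) == 995  # 996..1000 removed by the >= rule

    def test_percentile_100_removes_nothing(self):
        kp = kp_frame(np.arange(1, 101), ["correct"] * 100)
        out = filter_ikis(kp, percentile=100)
        assert len(out.keypresses) == 100

    def test_all_equal_ikis_all_removed(self, caplog):
        kp = kp_frame([300.0] * 50, ["correct"] * 50)
        with caplog.at_level("WARNING"):
            out = filter_ikis(kp)
        assert out.thresholds["en"] == 300.0
        assert len(out.keypresses) == 0

    def test_errorful_keypresses_cut_at_the_correct_threshold(self):
        ikis = list(np.arange(1, 1001)) + [100.0, 999.0]
        cats = ["correct"] * 1000 + ["error", "error"]
        err = pd.DataFrame({"participant_id": ["p1", "p1"], "iki_ms": [100.0, 999.0],
                            "label": ["motor", "habit"]})
        out = filter_ikis(kp_frame(ikis, cats), err)
        assert len(out.errors) == 1  # the 999 ms error is above the ~995 threshold
        assert out.errors["iki_ms"].iloc[0] == 100.0

    def test_refiltering_is_idempotent(self, rng):
        kp = kp_frame(rng.lognormal(5.7, 0.5, 2000), ["correct"] * 2000)
        once = filter_ikis(kp)
        twice = filter_ikis(once)
        pd.testing.assert_frame_equal(once.keypresses, twice.keypresses)
        assert once.thresholds == twice.thresholds

    def test_removal_fractions_reported_by_category(self):
        kp = kp_frame(list(np.arange(1, 1001)) + [2000.0], ["correct"] * 1000 + ["error"])
        rep = filter_ikis(kp).report.set_index("category")
        assert rep.at["error", "frac_removed"] == 1.0
        assert rep.at["correct", "n_removed"] == 5


class TestSummarize:
    def test_mean_iki_arithmetic_in_seconds(self):
        kp = kp_frame([300, 300, 400], ["correct", "correct", "error"])
        err = pd.DataFrame({"participant_id": ["p1"], "iki_ms": [400.0],
                            "label": ["motor"]})
        parts = [kio.ParticipantRecord("p1", "control", 0, "en")]
        summ = summarize(filter_ikis(kp, err, percentile=100), parts)
        row = summ.iloc[0]
        assert row["mean_iki_correct"] == pytest.approx(0.3)
        assert row["mean_iki_error"] == pytest.approx(0.4)
        assert row["motor_rate"] == 1.0 and row["n_errors"] == 1

    def test_no_errors_leaves_error_mean_absent(self):
        kp = kp_frame([250, 350], ["correct", "correct"])
        summ = summarize(filter_ikis(kp, percentile=100),
                         [kio.ParticipantRecord("p1", "control", 0, "en")])
        assert np.isnan(summ.iloc[0]["mean_iki_error"])
        assert np.isnan(summ.iloc[0]["motor_rate"])


class TestExcludeOutlierControls:
    def _summ(self, controls, patients):
        rows = [{"participant_id": f"c{i}", "group": "control", "updrs": u}
                for i, u in enumerate(controls)]
        rows += [{"participant_id": f"p{i}", "group": "patient", "updrs": u}
                 for i, u in enumerate(patients)]
        return pd.DataFrame(rows)

    def test_control_in_patient_range_excluded(self):
        out = exclude_outlier_controls(self._summ([0, 1, 14], [5, 9, 13]))
        assert set(out["participant_id"]) == {"c0", "c1", "p0", "p1", "p2"}

    def test_clean_controls_untouched(self):
        summ = self._summ([0, 0, 1], [8, 12])
        assert len(exclude_outlier_controls(summ)) == 5

    def test_infinite_cutoff_disables_exclusion(self):
        summ = self._summ([0, 25], [5])
        assert len(exclude_outlier_controls(summ, cutoff=np.inf)) == 3


def balanced_long(rng, n_per_cell=6, type_shift=0.08):
    rows, pid = [], 0
    for g in ("control", "patient"):
        for lang in ("en", "es"):
            for _ in range(n_per_cell):
                base = rng.normal(0.4, 0.1)
                for typ, shift in (("correct", 0.0), ("error", type_shift)):
                    rows.append({"participant_id": f"p{pid}", "group": g,
                                 "language": lang, "keypress_type": typ,
                                 "mean_iki": base + shift + rng.normal(0, 0.03)})
                pid += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_r_aov_on_balanced_design(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        long = balanced_long(rng)
        tab = mixed_anova_iki(long).set_index("effect")
        csv = tmp_path / "long.csv"
        long.to_csv(csv, index=False)
        script = tmp_path / "anova.R"
        script.write_text(f'''
d <- read.csv("{csv}")
for (v in c("participant_id","group","language","keypress_type")) d[[v]] <- factor(d[[v]])
fit <- aov(mean_iki ~ keypress_type*group*language + Error(participant_id/keypress_type), data=d)
s <- summary(fit)
for (stratum in s) {{
  t <- stratum[[1]]
  for (i in seq_len(nrow(t))) {{
    nm <- trimws(rownames(t)[i])
    if (nm != "Residuals") cat(sprintf("%s %.10f\\n", gsub(":", "_", nm), t[i, "F value"]))
  }}
}}
''')
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        r_f = dict(line.split() for line in out.stdout.strip().splitlines())
        rename = {"keypress_type": "keypress_type", "group": "group",
                  "language": "language", "group_language": "group:language",
                  "keypress_type_group": "keypress_type:group",
                  "keypress_type_language": "keypress_type:language",
                  "keypress_type_group_language": "keypress_type:group:language"}
        for r_name, our_name in rename.items():
            assert tab.at[our_name, "F"] == pytest.approx(float(r_f[r_name]), rel=1e-6)

    def test_worked_two_by_two_example(self):
        # 4 subjects, one language; within effect computable by hand:
        # diffs d = (2, 4, 6, 8); cell means 3 and 7, grand mean 5;
        # per-cell variances 2 each -> MSE = 2, F = n*mean^2-ish via t^2
        long = pd.DataFrame({
            "participant_id": np.repeat(["a", "b", "c", "d"], 2),
            "group": np.repeat(["control", "control", "patient", "patient"], 2),
            "language": "en",
            "keypress_type": ["correct", "error"] * 4,
            "mean_iki": [10, 12, 20, 24, 30, 36, 40, 48],
        })
        tab = mixed_anova_iki(long).set_index("effect")
        d = np.array([2.0, 4.0, 6.0, 8.0])
        mse = (np.var([2, 4], ddof=1) + np.var([6, 8], ddof=1)) / 2
        expected_f_type = np.mean([3.0, 7.0]) ** 2 / (mse * (1 / 2 + 1 / 2) / 4)
        assert tab.at["keypress_type", "F"] == pytest.approx(expected_f_type)
        # group effect is the two-sample F on subject means m = (11, 22 | 33, 44)
        m = np.array([11, 22, 33, 44.0])
        pooled = (np.var(m[:2], ddof=1) + np.var(m[2:], ddof=1)) / 2
        expected_f_group = (m[:2].mean() - m[2:].mean()) ** 2 / (pooled * (1 / 2 + 1 / 2))
        assert tab.at["group", "F"] == pytest.approx(expected_f_group)

    def test_missing_keypress_type_names_participant(self, rng):
        long = balanced_long(rng).iloc[1:]
        with pytest.raises(AnalysisError, match="p0"):
            mixed_anova_iki(long)


class TestErrorIkiRegression:
    def _summ(self, rng, n=40, beta_habit=0.0, sigma=0.05):
        df = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n)],
            "group": rng.choice(["control", "patient"], n),
            "language": rng.choice(["en", "es"], n),
            "habit_rate": rng.uniform(0, 0.5, n),
            "motor_rate": rng.uniform(0.2, 0.8, n),
        })
        df["mean_iki_error"] = 0.4 + beta_habit * df["habit_rate"] \
            + rng.normal(0, sigma, n)
        return df

    def test_drop_one_f_equals_squared_t(self, rng):
        import statsmodels.formula.api as smf
        df = self._summ(rng, beta_habit=0.5)
        tab = error_iki_regression(df).set_index("term")
        fit = smf.ols("mean_iki_error ~ C(group) + habit_rate + motor_rate + C(language)",
                      data=df).fit()
        assert tab.at["habit_rate", "F"] == pytest.approx(
            fit.tvalues["habit_rate"] ** 2, rel=1e-8)
        assert tab.at["habit_rate", "p"] == pytest.approx(
            fit.pvalues["habit_rate"], rel=1e-8)

    def test_strong_signal_dominates_noise_limit(self, rng):
        df = self._summ(rng, beta_habit=2.0, sigma=1e-9)
        tab = error_iki_regression(df).set_index("term")
        assert tab.at["habit_rate", "F"] > 1e10
        assert tab.at["motor_rate", "p"] > 0.001

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(AnalysisError):
            error_iki_regression(self._summ(rng, n=5))


class TestUpdrsGam:
    def test_log_linear_truth_recovers_glm_fit(self, rng):
        import statsmodels.api as sm
        n = 150
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(0.5 + 1.2 * x))
        df = pd.DataFrame({"updrs": y, "x": x, "language": "en",
                           "participant_id": [f"p{i}" for i in range(n)]})
        gam = fit_updrs_gam(df, smooth_terms=("x",), include_language=False)
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert abs(gam.aic - glm.aic) < 4.0
        assert gam.deviance_explained > 0.05

    def test_permuted_response_explains_nothing(self, rng):
        n = 150
        x = rng.uniform(0, 1, n)
        y = rng.permutation(rng.poisson(np.exp(0.5 + 1.2 * x)))
        df = pd.DataFrame({"updrs": y, "x": x, "language": "en",
                           "participant_id": [f"p{i}" for i in range(n)]})
        gam = fit_updrs_gam(df, smooth_terms=("x",), include_language=False)
        assert gam.deviance_explained < 0.1

    def test_non_integer_updrs_rejected(self, rng):
        df = pd.DataFrame({"updrs": [0.5, 1.2, 3.3, 2.2, 1.1, 0.7] * 10,
                           "x": rng.uniform(0, 1, 60), "language": "en",
                           "participant_id": [f"p{i}" for i in range(60)]})
        with pytest.raises(AnalysisError, match="integer"):
            fit_updrs_gam(df, smooth_terms=("x",), include_language=False)


class TestRoc:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1], bool)
        assert rank_auc([1, 2, 3, 4], labels) == 1.0

    def test_four_point_worked_example(self):
        # patients score {3, 5}, controls {1, 4}: 3 of 4 pairs concordant
        scores = np.array([3, 5, 1, 4], float)
        labels = np.array([1, 1, 0, 0], bool)
        assert rank_auc(scores, labels) == 0.75

    def test_sweep_equals_rank_statistic(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.arange(10) / 3.0, size=n)  # ties included
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            *_, auc = sweep_auc(scores, labels)
            assert abs(auc - rank_auc(scores, labels)) < 1e-10

    def test_permuted_labels_centre_on_half(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = np.array([1] * 25 + [0] * 35, bool)
        aucs = [rank_auc(scores, rng.permutation(labels)) for _ in range(200)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_bootstrap_ci_is_deterministic_and_ordered(self, rng):
        scores = rng.normal(0, 1, 40) + np.r_[np.ones(20), np.zeros(20)]
        labels = np.array([1] * 20 + [0] * 20, bool)
        r1 = roc_analysis(scores, labels, n_boot=200, seed=9)
        r2 = roc_analysis(scores, labels, n_boot=200, seed=9)
        assert r1.auc_ci == r2.auc_ci
        assert r1.auc_ci[0] <= r1.auc <= r1.auc_ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            rank_auc([1, 2, 3], np.array([1, 1, 1], bool))


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        labels = np.array([1] * 10 + [0] * 10, bool)
        scores = rng.normal(0, 1, 20)
        diff, p = delong_test(scores, scores.copy(), labels)
        assert diff == 0.0 and p == 1.0

    def test_matches_r_proc(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        n = 40
        labels = np.array([0] * 20 + [1] * 20, bool)
        a = labels * 1.0 + rng.normal(0, 0.9, n)
        b = labels * 0.7 + 0.5 * a + rng.normal(0, 0.8, n)
        _, p = delong_test(a, b, labels)
        csv = tmp_path / "roc.csv"
        pd.DataFrame({"label": labels.astype(int), "a": a, "b": b}).to_csv(csv, index=False)
        script = tmp_path / "roc.R"
        script.write_text(f'''
suppressMessages(library(pROC))
d <- read.csv("{csv}")
r1 <- roc(d$label, d$a, quiet=TRUE); r2 <- roc(d$label, d$b, quiet=TRUE)
t <- roc.test(r1, r2, method="delong", paired=TRUE)
cat(sprintf("%.12f", t$p.value))
''')
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        assert p == pytest.approx(float(out.stdout.strip()), rel=1e-8)

    def test_variance_agrees_with_bootstrap(self, rng):
        n = 60
        labels = np.array([1] * 30 + [0] * 30, bool)
        scores = labels * 0.8 + rng.normal(0, 1, n)
        v_delong = delong_variance(scores, labels)
        boots = []
        for _ in range(3000):
            idx = rng.integers(0, n, n)
            if labels[idx].any() and not labels[idx].all():
                boots.append(rank_auc(scores[idx], labels[idx]))
        assert v_delong == pytest.approx(np.var(boots), rel=0.2)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(AnalysisError):
            delong_test([1, 2, 3], [1, 2], np.array([1, 0, 1], bool))
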