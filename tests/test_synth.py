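import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from typeslip import classify_cohort, filter_ikis, get_profile, simulate_cohort, summarize
from typeslip.synth import ProfileError, TypistProfile, simulate_typist, \
    write_ground_truth, read_ground_truth


def make_profile(**overrides):
    params = dict(
        name="toy", group="control", language="en",
        iki_median_ms=300.0, iki_log_sd=0.4, iki_between_sd=0.0,
        error_slowing=1.3, p_error=0.05,
        mechanism_mix={"motor": 0.3, "habit": 0.3, "uniform": 0.4},
        mix_jitter_sd=0.0, speed_coupling=0.0, updrs_mean=0.85,
    )
    params.update(overrides)
    return TypistProfile(**params)


class TestSimulateTypist:
    def test_error_free_typist_reproduces_stimuli(self, resources, rng):
        prof = make_profile(p_error=0.0)
        stim = resources.stimuli("en")[:3]
        sess, truth = simulate_typist(prof, stim, resources.layout("en"),
                                      resources.lm("en"), rng)
        layout = resources.layout("en")
        for sid, sentence in enumerate(stim):
            assert sess.typed_text(sid) == "".join(layout.normalize(c) for c in sentence)
        assert truth.errors == []

    def test_same_seed_is_byte_identical(self, resources):
        prof = make_profile()
        stim = resources.stimuli("en")[:3]
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            sess, truth = simulate_typist(prof, stim, resources.layout("en"),
                                          resources.lm("en"), rng)
            out.append((sess, truth))
        assert out[0][0] == out[1][0]
        assert out[0][1] == out[1][1]

    def test_motor_errors_are_adjacent_to_previous_key(self, resources, rng):
        prof = make_profile(mechanism_mix={"motor": 1.0, "habit": 0.0, "uniform": 0.0},
                            p_error=0.2)
        layout = resources.layout("en")
        sess, truth = simulate_typist(prof, resources.stimuli("en")[:5], layout,
                                      resources.lm("en"), rng)
        motor = [e for e in truth.errors if e.mechanism == "motor"]
        assert motor
        for e in motor:
            typed = sess.events[e.sentence_id]
            if e.typed_index == 0:
                continue
            prev = typed[e.typed_index - 1].char
            assert layout.distance(prev, e.typed_char) == 1.0

    def test_invalid_mix_rejected(self):
        with pytest.raises(ProfileError):
            make_profile(mechanism_mix={"motor": 0.5, "habit": 0.2, "uniform": 0.2})


@pytest.fixture(scope="module")
def pure_motor_run(resources):
    prof = make_profile(mechanism_mix={"motor": 1.0, "habit": 0.0, "uniform": 0.0},
                        p_error=0.1)
    sessions, parts, truths = simulate_cohort([(prof, 6)], seed=303)
    kp, err = classify_cohort(sessions, {"en": resources.layout("en")},
                              {"en": resources.lm("en")}, parts)
    gt = {(e.participant_id, e.sentence_id, e.typed_index): e
          for t in truths for e in t.errors}
    err["mechanism"] = [gt[k].mechanism if (k := (r.participant_id, r.sentence_id,
                                                  r.typed_index)) in gt else None
                        for r in err.itertuples()]
    return err, resources.layout("en")


class TestMechanismRecoveryInvariants:
    """What the classifier is *forced* to do on generated errors.

    The strict-inequality rules leave a structural floor: when the intended
    key itself sits within grid distance 1 of the previous key, a generated
    motor error ties the comparison and cannot be labelled motor.  Those
    exactly-decidable cases are asserted; the overall agreement is reported
    by the acceptance checks.
    """

    def test_decidable_motor_errors_always_recovered(self, pure_motor_run):
        err, layout = pure_motor_run
        motor = err[(err["mechanism"] == "motor") & err["prev_char"].notna()
                    & err["typed_char"].notna()]
        decidable = motor[motor.apply(
            lambda r: layout.distance(r["prev_char"], r["target_char"]) > 1.0, axis=1)]
        assert len(decidable) > 50
        assert (decidable["label"] == "motor").all()

    def test_tied_motor_errors_never_labelled_motor(self, pure_motor_run):
        err, layout = pure_motor_run
        motor = err[(err["mechanism"] == "motor") & err["prev_char"].notna()
                    & err["typed_char"].notna()]
        tied = motor[motor.apply(
            lambda r: layout.distance(r["prev_char"], r["target_char"]) <= 1.0, axis=1)]
        assert (tied["label"] != "motor").all()


class TestSimulateCohort:
    def test_empty_cohort(self, resources):
        sessions, parts, truths = simulate_cohort([(make_profile(), 0)], seed=1)
        assert sessions == [] and parts == [] and truths == []

    def test_same_seed_identical_cohorts(self):
        a = simulate_cohort([(make_profile(), 3)], seed=5)
        b = simulate_cohort([(make_profile(), 3)], seed=5)
        assert a == b

    def test_control_updrs_mean_matches_configuration(self):
        prof = make_profile(updrs_mean=0.85)
        _, parts, _ = simulate_cohort([(prof, 400)], seed=8)
        updrs = np.array([p.updrs for p in parts])
        se = np.sqrt(0.85 / len(updrs))
        assert abs(updrs.mean() - 0.85) < 4 * se

    def test_patient_updrs_truncated_below_twenty(self):
        prof = make_profile(group="patient", updrs_mean=13.15)
        _, parts, _ = simulate_cohort([(prof, 300)], seed=9)
        assert max(p.updrs for p in parts) < 20

    def test_ground_truth_round_trip(self, tmp_path):
        _, _, truths = simulate_cohort([(make_profile(p_error=0.1), 2)], seed=3)
        path = tmp_path / "gt.tsv"
        write_ground_truth(truths, path)
        back = read_ground_truth(path)
        flat = [e for t in truths for e in t.errors]
        assert back == flat


class TestCohortStatisticalStructure:
    def test_speed_coupling_gives_negative_habit_speed_slope(self, resources):
        # slower typists make fewer habit slips: regression of habit rate on
        # mean IKI across 60 typists has a negative coefficient
        prof = make_profile(iki_between_sd=0.4, speed_coupling=1.5,
                            mechanism_mix={"motor": 0.2, "habit": 0.3, "uniform": 0.5},
                            p_error=0.06)
        sessions, parts, truths = simulate_cohort([(prof, 60)], seed=21)
        kp, err = classify_cohort(sessions, {"en": resources.layout("en")},
                                  {"en": resources.lm("en")}, parts)
        summ = summarize(filter_ikis(kp, err), parts).dropna(subset=["habit_rate"])
        x = sm.add_constant(summ["mean_iki_correct"].to_numpy())
        fit = sm.OLS(summ["habit_rate"].to_numpy(), x).fit()
        assert fit.params[1] < 0
        assert fit.pvalues[1] < 0.05

    def test_habit_weight_monotonically_raises_measured_habit_rate(self, resources):
        measured = []
        for w in (0.05, 0.15, 0.25, 0.35, 0.45):
            prof = make_profile(
                mechanism_mix={"motor": 0.3, "habit": w, "uniform": 0.7 - w},
                p_error=0.06)
            sessions, parts, _ = simulate_cohort([(prof, 10)], seed=101)
            _, err = classify_cohort(sessions, {"en": resources.layout("en")},
                                     {"en": resources.lm("en")}, parts)
            nonmotor = (err["label"] != "motor").sum()
            measured.append((err["label"] == "habit").sum() / nonmotor)
        assert all(b > a for a, b in zip(measured, measured[1:]))
        rho = scipy.stats.spearmanr(measured, range(5)).statistic
        assert rho > 0.9

    def test_error_rates_add_predictive_value_for_updrs(self, resources):
        # UPDRS is coupled to group, and the error rates carry group signal
        # beyond typing speed, so the full GAM should fit better than the
        # speed-only GAM for most cohorts
        from typeslip.pipeline import run_profile_cohort
        from typeslip.stats import fit_updrs_gam
        spec = [(get_profile("english-control"), 15),
                (get_profile("english-patient"), 15)]
        wins = 0
        for seed in (1, 2, 3, 4, 5):
            summ = run_profile_cohort(spec, seed=seed, resources=resources)
            full = fit_updrs_gam(summ, spline_df=6, include_language=False)
            reduced = fit_updrs_gam(summ, smooth_terms=("mean_iki_correct",
                                                        "mean_iki_error"),
                                    spline_df=6, include_language=False)
            wins += full.aic < reduced.aic
        assert wins >= 4, wins

    def test_default_profiles_slow_patients_and_reduce_habit(self, resources):
        spec = [(get_profile("english-control"), 10), (get_profile("english-patient"), 10)]
        sessions, parts, _ = simulate_cohort(spec, seed=55)
        kp, err = classify_cohort(sessions, {"en": resources.layout("en")},
                                  {"en": resources.lm("en")}, parts)
        summ = summarize(filter_ikis(kp, err), parts)
        by_group = summ.groupby("group")[["mean_iki_correct", "mean_iki_error",
                                          "habit_rate"]].mean()
        assert by_group.at["patient", "mean_iki_correct"] > by_group.at["control", "mean_iki_correct"]
        assert by_group.at["patient", "mean_iki_error"] > by_group.at["control", "mean_iki_error"]
        assert by_group.at["patient", "habit_rate"] < by_group.at["control", "habit_rate"]
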