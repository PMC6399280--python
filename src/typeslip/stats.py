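"""Cohort-level statistics: IKI filtering, summaries and the diagnostic models.

The analysis stage mirrors a fixed sequence: long pauses are removed with a
per-language 99.5th-percentile cut on correct-keypress intervals; per
participant the mean interkey interval (IKI) for correct and errorful
keypresses, the motor error rate and the habit slip rate are summarized; a
2 x 2 x 2 mixed ANOVA (keypress type within; group and language between)
tests IKI effects; nested-model F tests relate mean error IKIs to group and
error rates; a Poisson generalized additive model maps the summaries to
UPDRS motor scores; and the GAM's predictions are scored with ROC curves,
bootstrap CIs and DeLong's test for paired AUC differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.gam.api import BSplines, GLMGam

from .io import ParticipantRecord
from .pipeline import CORRECT, ERROR

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# IKI filtering
# ---------------------------------------------------------------------------

@dataclass
class FilteredKeypresses:
    """Keypress and error tables after the percentile cut, plus the report."""

    keypresses: pd.DataFrame
    errors: pd.DataFrame
    thresholds: dict[str, float]
    percentile: float
    report: pd.DataFrame = field(default_factory=pd.DataFrame)


def filter_ikis(
    keypresses: pd.DataFrame | FilteredKeypresses,
    errors: Optional[pd.DataFrame] = None,
    percentile: float = 99.5,
    drop_errors: bool = True,
) -> FilteredKeypresses:
    """Remove long-pause keypresses above a per-language percentile threshold.

    The threshold for each language is the ``percentile`` (linear
    interpolation) of that language's *correct*-keypress IKIs; every
    keypress — correct or errorful — with IKI **greater than or equal to**
    the threshold is removed.  With ``drop_errors`` (default) error-table
    rows whose keypress was removed disappear from all downstream analyses,
    rates included; pass False to retain them for rate computation only.

    Passing a ``FilteredKeypresses`` back in reuses its stored thresholds,
    which makes filtering idempotent.
    """
    if isinstance(keypresses, FilteredKeypresses):
        prior = keypresses
        kp, errors = prior.keypresses, prior.errors
        thresholds = dict(prior.thresholds)
        percentile = prior.percentile
    else:
        kp = keypresses
        if errors is None:
            errors = pd.DataFrame(columns=["participant_id", "iki_ms"])
        thresholds = {}
        for lang, sub in kp.groupby("language", observed=True):
            correct = sub.loc[sub["category"] == CORRECT, "iki_ms"].to_numpy()
            if len(correct) == 0:
                continue
            if len(correct) < 200:
                logger.warning("language %s: only %d correct keypresses; "
                               "percentile threshold unstable", lang, len(correct))
            if percentile >= 100:
                thresholds[lang] = np.inf  # >= at the maximum would always cut it
                continue
            thr = float(np.percentile(correct, percentile))
            if np.all(correct == correct[0]):
                logger.warning("language %s: all correct IKIs equal; the >= rule "
                               "removes every keypress", lang)
            thresholds[lang] = thr

    thr_col = kp["language"].map(thresholds).astype(float)
    keep = ~(kp["iki_ms"] >= thr_col)  # NaN threshold (unknown language) keeps rows
    removed = kp.loc[~keep]
    kp_out = kp.loc[keep].reset_index(drop=True)

    err_out = errors
    if drop_errors and len(errors):
        lang_of = kp[["participant_id", "language"]].drop_duplicates().set_index(
            "participant_id")["language"]
        ethr = errors["participant_id"].map(lang_of).map(thresholds).astype(float)
        ekeep = ~(errors["iki_ms"] >= ethr)
        err_out = errors.loc[ekeep].reset_index(drop=True)

    rep_rows = []
    for lang, thr in thresholds.items():
        sub = kp[kp["language"] == lang]
        rem = removed[removed["language"] == lang]
        for cat in (CORRECT, ERROR):
            n_all = int((sub["category"] == cat).sum())
            n_rem = int((rem["category"] == cat).sum())
            n_rem_pat = int(((rem["category"] == cat) & (rem["group"] == "patient")).sum())
            rep_rows.append({
                "language": lang, "category": cat, "threshold_ms": thr,
                "n": n_all, "n_removed": n_rem,
                "frac_removed": n_rem / n_all if n_all else np.nan,
                "frac_removed_from_patients": n_rem_pat / n_rem if n_rem else np.nan,
            })
    report = pd.DataFrame(rep_rows)
    return FilteredKeypresses(kp_out, err_out, thresholds, percentile, report)


# ---------------------------------------------------------------------------
# participant summaries
# ---------------------------------------------------------------------------

def summarize(
    filtered: FilteredKeypresses,
    participants: Optional[Sequence[ParticipantRecord]] = None,
) -> pd.DataFrame:
    """One row per participant: mean IKIs (seconds), error rates, metadata.

    Correct keypresses are alignment-matched columns; the errorful keypress
    is the extracted first-mismatch keypress; keypresses after an error
    within its token count as neither.  Rates come from the (filtered)
    error table; a participant with no surviving errorful keypresses gets
    an absent error-IKI mean, logged.
    """
    kp, err = filtered.keypresses, filtered.errors
    meta = {p.participant_id: p for p in participants} if participants else {}
    means = (kp[kp["category"].isin([CORRECT, ERROR])]
             .groupby(["participant_id", "category"], observed=True)["iki_ms"]
             .mean().unstack())
    rows = []
    pids = sorted(set(kp["participant_id"]))
    err_by_pid = dict(tuple(err.groupby("participant_id"))) if len(err) else {}
    for pid in pids:
        mc = means.at[pid, CORRECT] if (pid in means.index and CORRECT in means) else np.nan
        me = means.at[pid, ERROR] if (pid in means.index and ERROR in means) else np.nan
        sub = err_by_pid.get(pid)
        if sub is None or not len(sub):
            n = n_motor = n_habit = 0
            motor_rate = habit_rate = np.nan
            logger.info("participant %s: no surviving errors", pid)
        else:
            n = len(sub)
            n_motor = int((sub["label"] == "motor").sum())
            n_habit = int((sub["label"] == "habit").sum())
            motor_rate = n_motor / n
            habit_rate = n_habit / (n - n_motor) if n > n_motor else np.nan
        if np.isnan(me):
            logger.info("participant %s: no surviving errorful keypress IKIs", pid)
        p = meta.get(pid)
        rows.append({
            "participant_id": pid,
            "group": p.group if p else None,
            "language": p.language if p else None,
            "updrs": p.updrs if p else None,
            "mean_iki_correct": mc / 1000.0,
            "mean_iki_error": me / 1000.0,
            "motor_rate": motor_rate,
            "habit_rate": habit_rate,
            "n_errors": n,
            "n_motor": n_motor,
            "n_habit": n_habit,
        })
    return pd.DataFrame(rows)


def exclude_outlier_controls(summaries: pd.DataFrame,
                             cutoff: Optional[float] = None) -> pd.DataFrame:
    """Drop controls whose UPDRS is in the patients' range.

    Default cutoff: the minimum patient UPDRS in the cohort; controls with
    ``updrs >= cutoff`` are excluded (and logged).
    """
    if cutoff is None:
        patients = summaries[summaries["group"] == "patient"]
        if not len(patients):
            return summaries
        cutoff = patients["updrs"].min()
    mask = (summaries["group"] == "control") & (summaries["updrs"] >= cutoff)
    for pid in summaries.loc[mask, "participant_id"]:
        logger.info("excluding control %s (UPDRS in patient range, cutoff %s)", pid, cutoff)
    return summaries.loc[~mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed ANOVA (keypress type within; group, language between)
# ---------------------------------------------------------------------------

def mixed_anova_iki(long: pd.DataFrame) -> pd.DataFrame:
    """2 x 2 x 2 split-plot ANOVA on mean IKI.

    ``long`` has one row per participant x keypress type with columns
    ``participant_id, group, language, keypress_type, mean_iki``.  With a
    two-level within factor the design decomposes exactly: between-subject
    effects are the ANOVA of each subject's mean over the two types, and
    within effects are the ANOVA of each subject's difference (Type II sums
    of squares for the factor terms; the keypress-type main effect is the
    effects-coded intercept test on the differences).
    """
    wide = long.pivot_table(index=["participant_id", "group", "language"],
                            columns="keypress_type", values="mean_iki",
                            observed=True)
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.get_level_values(0).tolist()
        raise AnalysisError(f"participants missing a keypress type: {bad}")
    types = list(wide.columns)
    if len(types) != 2:
        raise AnalysisError(f"expected exactly 2 keypress types, got {types}")
    df = wide.reset_index()
    df["m"] = (df[types[0]] + df[types[1]]) / 2.0
    df["d"] = df[types[1]] - df[types[0]]

    two_lang = df["language"].nunique() > 1
    between = "C(group)" + (" * C(language)" if two_lang else "")
    rows = []

    fit_b = smf.ols(f"m ~ {between}", data=df).fit()
    tab_b = sm.stats.anova_lm(fit_b, typ=2)
    for term in tab_b.index:
        if term == "Residual":
            continue
        rows.append(_anova_row(_clean_term(term), tab_b, term, fit_b))

    sum_between = "C(group, Sum)" + (" * C(language, Sum)" if two_lang else "")
    fit_w = smf.ols(f"d ~ {sum_between}", data=df).fit()
    t_int = fit_w.tvalues["Intercept"]
    rows.insert(0, {
        "effect": "keypress_type",
        "F": float(t_int ** 2), "df1": 1, "df2": int(fit_w.df_resid),
        "p": float(fit_w.pvalues["Intercept"]),
    })
    tab_w = sm.stats.anova_lm(fit_w, typ=2)
    for term in tab_w.index:
        if term == "Residual":
            continue
        rows.append(_anova_row("keypress_type:" + _clean_term(term), tab_w, term, fit_w))
    return pd.DataFrame(rows)


def _clean_term(term: str) -> str:
    return (term.replace("C(group, Sum)", "group").replace("C(language, Sum)", "language")
            .replace("C(group)", "group").replace("C(language)", "language"))


def _anova_row(name, table, term, fit) -> dict:
    return {"effect": name, "F": float(table.at[term, "F"]),
            "df1": int(table.at[term, "df"]), "df2": int(fit.df_resid),
            "p": float(table.at[term, "PR(>F)"])}


# ---------------------------------------------------------------------------
# nested-model regression on error IKIs
# ---------------------------------------------------------------------------

def error_iki_regression(
    summaries: pd.DataFrame,
    response: str = "mean_iki_error",
    terms: Sequence[str] = ("group", "habit_rate", "motor_rate", "language"),
) -> pd.DataFrame:
    """Full-vs-reduced F test for each term of the linear model.

    The full OLS model regresses the response on all terms; each term's F
    compares the full model against the model with that single term removed.
    """
    cols = [response] + [t for t in terms]
    data = summaries.dropna(subset=cols).copy()
    if len(data) <= len(terms) + 1:
        raise AnalysisError("too few complete rows for the regression")

    def fmla(tset):
        parts = [f"C({t})" if data[t].dtype == object else t for t in tset]
        return f"{response} ~ " + " + ".join(parts) if parts else f"{response} ~ 1"

    full = smf.ols(fmla(terms), data=data).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise AnalysisError("design matrix is rank deficient")
    rows = []
    for t in terms:
        reduced = smf.ols(fmla([u for u in terms if u != t]), data=data).fit()
        comp = sm.stats.anova_lm(reduced, full)
        rows.append({"term": t, "F": float(comp["F"].iloc[1]),
                     "df1": int(comp["df_diff"].iloc[1]), "df2": int(full.df_resid),
                     "p": float(comp["Pr(>F)"].iloc[1])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Poisson GAM for UPDRS
# ---------------------------------------------------------------------------

DEFAULT_SMOOTH_TERMS = ("mean_iki_correct", "mean_iki_error", "motor_rate", "habit_rate")


@dataclass
class GamResult:
    terms: tuple[str, ...]
    aic: float
    deviance_explained: float
    predicted: pd.Series  # response-scale prediction per participant_id
    results: object = field(repr=False, default=None)


def fit_updrs_gam(
    summaries: pd.DataFrame,
    smooth_terms: Sequence[str] = DEFAULT_SMOOTH_TERMS,
    include_language: bool = True,
    spline_df: int = 10,
    alpha: Optional[Sequence[float]] = None,
) -> GamResult:
    """Penalized-spline Poisson regression of UPDRS on typing summaries.

    Each continuous term gets a B-spline basis (``spline_df`` columns,
    cubic) with a ridge penalty whose weight is selected per smooth (by
    the estimator's penalty-weight search) unless ``alpha`` is given;
    language enters as a parametric factor.  Reports AIC, percent deviance
    explained against the intercept-only Poisson model, and response-scale
    predictions.
    """
    cols = ["updrs"] + list(smooth_terms) + (["language"] if include_language else [])
    data = summaries.dropna(subset=cols).copy()
    y = data["updrs"].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise AnalysisError("updrs must be non-negative integers (Poisson response)")
    y = y.astype(int)

    exog = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    if include_language and data["language"].nunique() > 1:
        dummies = pd.get_dummies(data["language"], prefix="lang", drop_first=True, dtype=float)
        exog = pd.concat([exog, dummies], axis=1)

    smoother = None
    if smooth_terms:
        x = data[list(smooth_terms)].to_numpy(dtype=float)
        if len(data) <= x.shape[1] * (spline_df - 1) // 2 + exog.shape[1]:
            raise AnalysisError("too few rows for the requested spline bases; "
                                "reduce spline_df or drop terms")
        smoother = BSplines(x, df=[spline_df] * x.shape[1],
                            degree=[3] * x.shape[1], include_intercept=False)
    model = GLMGam(y, exog=exog, smoother=smoother,
                   alpha=np.asarray(alpha) if alpha is not None else
                   (np.ones(len(smooth_terms)) if smooth_terms else None),
                   family=sm.families.Poisson())
    if smooth_terms and alpha is None:
        try:
            best_alpha = model.select_penweight()[0]
        except Exception:  # pragma: no cover - optimizer hiccups on tiny data
            best_alpha = np.ones(len(smooth_terms))
        model = GLMGam(y, exog=exog, smoother=smoother, alpha=best_alpha,
                       family=sm.families.Poisson())
    res = model.fit()

    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
    dev_expl = 1.0 - res.deviance / null.deviance if null.deviance > 0 else 0.0
    predicted = pd.Series(np.asarray(res.predict()), index=data["participant_id"].to_numpy())
    return GamResult(tuple(smooth_terms), float(res.aic), float(dev_expl), predicted, res)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    score_name: str
    sensitivity: np.ndarray
    specificity: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_boot: int
    seed: Optional[int]


def rank_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney rank statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise AnalysisError("both classes must be present")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sweep_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Full threshold sweep; AUC by trapezoidal integration of the curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return tpr, 1.0 - fpr, thr, auc


def roc_analysis(scores, labels, n_boot: int = 2000,
                 seed: Optional[int] = None, score_name: str = "score") -> RocResult:
    """ROC curve with rank-statistic AUC and a percentile bootstrap CI.

    The bootstrap resamples participants with replacement; resamples that
    lose a class are redrawn.  Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    sens, spec, thr, _ = sweep_auc(scores, labels)
    auc = rank_auc(scores, labels)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(scores)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
        boots[b] = rank_auc(scores[idx], lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(score_name, sens, spec, thr, auc, (float(lo), float(hi)),
                     n_boot, seed)


def _delong_components(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], vectorized via midranks
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)  # V10 (per positive), V01 (per negative)


def delong_variance(scores, labels) -> float:
    """DeLong sampling variance of a single AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    v10, v01 = _delong_components(scores, labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for the AUC difference of paired models.

    Returns ``(auc_a - auc_b, p_value)``; identical scores give p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise AnalysisError("paired scores and labels must have identical length")
    auc_a, auc_b = rank_auc(scores_a, labels), rank_auc(scores_b, labels)
    va10, va01 = _delong_components(scores_a, labels)
    vb10, vb01 = _delong_components(scores_b, labels)
    n1, n0 = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(2 * scipy.stats.norm.sf(abs(z)))
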