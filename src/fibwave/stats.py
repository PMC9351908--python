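"""Outcome statistics: univariate screen, logistic models, ROC cutoffs,
and the combined dichotomized predictor.

The analysis pipeline mirrors a standard clinical-outcome workflow on a
cohort table with binary endpoints (procedural AF termination during
ablation; late recurrence of atrial arrhythmia):

1. univariate screen — continuous variables are tested for normality per
   group (Lilliefors-corrected Kolmogorov-Smirnov), then compared with
   Student's t-test (both groups normal) or the Mann-Whitney U-test;
   categorical variables use chi-square, or Fisher's exact test when any
   expected cell count is below 5;
2. variables significant at alpha = .05 enter a multivariate logistic
   regression (maximum likelihood, Wald CIs and p-values, odds ratios per
   unit);
3. ROC analysis per significant predictor, oriented so the score predicts
   the *adverse* outcome; the reported cutoff maximizes the Youden index
   J = sensitivity + specificity - 1; the AUC confidence interval uses the
   DeLong variance estimate;
4. a combined predictor dichotomizes FWA in lead V1 (low) and DF in lead I
   (high) at supplied cutoffs (published values 60.38 uV and 5.70 Hz) and
   refits logistic models for the single indicators and their conjunction.

No multiplicity correction is applied in the default screen-then-fit flow;
its realized type-I error is a measured property, not an assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "UnivariateResult",
    "LogisticFit",
    "RocResult",
    "univariate_screen",
    "fit_logistic",
    "roc_analysis",
    "combined_predictor",
    "run_study",
    "DEFAULT_CUTOFF_FWA_V1",
    "DEFAULT_CUTOFF_DF_I",
]

#: Published dichotomization cutoffs for the combined predictor.
DEFAULT_CUTOFF_FWA_V1 = 60.38  # uV; FWA below this in lead V1 is "low"
DEFAULT_CUTOFF_DF_I = 5.70     # Hz; DF above this in lead I is "high"

ALPHA = 0.05


@dataclass
class UnivariateResult:
    variable: str
    test_name: str
    statistic: float
    p_value: float
    group_summary: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


@dataclass
class LogisticFit:
    outcome: str
    n: int
    predictors: list[str]
    odds_ratio: dict
    ci95: dict
    p_value: dict
    converged: bool
    flags: dict = field(default_factory=dict)


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    orientation: str  # 'higher' or 'lower' score predicts the positive class
    p_value: float = float("nan")


def _is_categorical(x: pd.Series) -> bool:
    vals = pd.unique(x.dropna())
    return len(vals) <= 2 and all(float(v).is_integer() for v in vals)


def univariate_screen(
    cohort: pd.DataFrame, variables: list[str], outcome: str, alpha: float = ALPHA
) -> list[UnivariateResult]:
    """Per-variable two-group comparison with normality-gated test choice."""
    y = cohort[outcome].to_numpy()
    classes = np.unique(y[~pd.isna(y)])
    if len(classes) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary with both classes present")
    out: list[UnivariateResult] = []
    for var in variables:
        x = cohort[var]
        if x.nunique(dropna=True) <= 1:
            out.append(UnivariateResult(var, "none", float("nan"), float("nan"),
                                        flags={"constant": True}))
            continue
        if _is_categorical(x):
            tab = pd.crosstab(x, cohort[outcome]).to_numpy()
            expected = sps.contingency.expected_freq(tab)
            if (expected < 5).any() and tab.shape == (2, 2):
                odds, p = sps.fisher_exact(tab)
                out.append(UnivariateResult(var, "fisher", float(odds), float(p),
                                            {"table": tab.tolist()}))
            else:
                chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
                out.append(UnivariateResult(var, "chi-square", float(chi2), float(p),
                                            {"table": tab.tolist()}))
            continue
        g0 = x[y == classes[0]].dropna().to_numpy(dtype=float)
        g1 = x[y == classes[1]].dropna().to_numpy(dtype=float)
        normal = all(_normal_ok(g, alpha) for g in (g0, g1))
        summary = {
            str(classes[0]): f"{g0.mean():.3f} +/- {g0.std(ddof=1):.3f}",
            str(classes[1]): f"{g1.mean():.3f} +/- {g1.std(ddof=1):.3f}",
        }
        if normal:
            t, p = sps.ttest_ind(g0, g1)
            out.append(UnivariateResult(var, "t", float(t), float(p), summary))
        else:
            u, p = sps.mannwhitneyu(g0, g1, alternative="two-sided")
            out.append(UnivariateResult(var, "mann-whitney", float(u), float(p), summary))
    return out


def _normal_ok(g: np.ndarray, alpha: float) -> bool:
    if g.size < 4 or np.std(g) == 0:
        return False
    _, p = lilliefors(g, dist="norm")
    return p >= alpha


def fit_logistic(
    cohort: pd.DataFrame, predictors: list[str], outcome: str
) -> LogisticFit:
    """Maximum-likelihood logistic regression; ORs with Wald 95% CIs.

    Perfect separation or non-convergence is flagged and no CI is reported
    for the affected fit.
    """
    df = cohort[[outcome, *predictors]].dropna()
    y = df[outcome].to_numpy(dtype=float)
    X = sm.add_constant(df[predictors].to_numpy(dtype=float))
    flags: dict = {}
    if len(df) < 10 * len(predictors):
        flags["small_sample"] = f"n={len(df)} < 10 x {len(predictors)} predictors"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, method="newton", maxiter=100,
                                     tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", False))
        params = res.params[1:]
        if np.any(np.abs(params) > 15):  # |log OR| > 15: numerically separated
            raise PerfectSeparationError("quasi-separation")
        conf = res.conf_int()[1:]
        pvals = res.pvalues[1:]
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return LogisticFit(
            outcome=outcome, n=len(df), predictors=list(predictors),
            odds_ratio={}, ci95={}, p_value={}, converged=False,
            flags={**flags, "separation": str(exc), "non_reportable": True},
        )
    return LogisticFit(
        outcome=outcome,
        n=len(df),
        predictors=list(predictors),
        odds_ratio={p: float(np.exp(b)) for p, b in zip(predictors, params)},
        ci95={p: (float(np.exp(lo)), float(np.exp(hi)))
              for p, (lo, hi) in zip(predictors, conf)},
        p_value={p: float(v) for p, v in zip(predictors, pvals)},
        converged=converged,
        flags=flags,
    )


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (midrank formulation, tie-aware)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_s = np.concatenate([pos, neg])
    r_all = sps.rankdata(all_s)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n        # placement of each positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # placement of each negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_direction: str = "higher",
) -> RocResult:
    """Empirical ROC with Youden-optimal cutoff and DeLong AUC CI.

    ``positive_direction='higher'`` means larger scores predict label 1;
    ``'lower'`` flips the orientation (e.g. low amplitude predicting an
    adverse outcome).  The cutoff is reported on the original score scale;
    for 'higher' a case is called positive when score >= cutoff, for
    'lower' when score <= cutoff.  Youden ties resolve to the cutoff with
    the higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain both classes")
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    s = scores if positive_direction == "higher" else -scores

    fpr, tpr, thr = roc_curve(labels, s)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr  # Youden index per threshold
    best = np.flatnonzero(j == j.max())
    # ties -> higher sensitivity
    k = best[np.argmax(tpr[best])]
    cutoff_t = thr[k]
    # roc_curve's top threshold is max(s)+1; clamp into the observed range
    cutoff_t = min(max(cutoff_t, s.min()), s.max())
    cutoff = float(cutoff_t if positive_direction == "higher" else -cutoff_t)

    _, var = _delong_variance(s, labels)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    z = (auc - 0.5) / se if se > 0 else np.inf
    p = float(2 * sps.norm.sf(abs(z)))
    return RocResult(
        auc=auc, ci95=ci, cutoff=cutoff,
        sensitivity=float(tpr[k]), specificity=float(1 - fpr[k]),
        orientation=positive_direction, p_value=p,
    )


def combined_predictor(
    cohort: pd.DataFrame,
    outcome: str,
    cutoff_fwa_v1: float = DEFAULT_CUTOFF_FWA_V1,
    cutoff_df_i: float = DEFAULT_CUTOFF_DF_I,
    covariates: list[str] | None = None,
    fwa_col: str = "fwa_v1",
    df_col: str = "df_i",
) -> dict[str, LogisticFit]:
    """Dichotomized single and combined predictors of the adverse outcome.

    Builds ``low_fwa_v1`` (FWA_V1 < cutoff), ``high_df_i`` (DF_I > cutoff)
    and their conjunction, then fits a model with the two single indicators
    (plus covariates) and one with the conjunction (plus covariates).
    """
    cov = list(covariates or [])
    df = cohort.copy()
    df["low_fwa_v1"] = (df[fwa_col] < cutoff_fwa_v1).astype(int)
    df["high_df_i"] = (df[df_col] > cutoff_df_i).astype(int)
    df["low_fwa_and_high_df"] = df["low_fwa_v1"] & df["high_df_i"]
    df["low_fwa_and_high_df"] = df["low_fwa_and_high_df"].astype(int)

    fits = {
        "single_indicators": fit_logistic(
            df, ["low_fwa_v1", "high_df_i", *cov], outcome
        ),
        "combined": fit_logistic(df, ["low_fwa_and_high_df", *cov], outcome),
    }
    if df["low_fwa_and_high_df"].nunique() < 2:
        fits["combined"].flags["empty_stratum"] = True
    return fits


def run_study(
    cohort: pd.DataFrame,
    metric_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
    outcomes: tuple[str, str] = ("endpoint_termination", "endpoint_recurrence"),
    cutoff_fwa_v1: float = DEFAULT_CUTOFF_FWA_V1,
    cutoff_df_i: float = DEFAULT_CUTOFF_DF_I,
    alpha: float = ALPHA,
) -> dict:
    """Full statistical pipeline on a cohort table.

    For each endpoint: univariate screen over metrics and covariates;
    variables with p < alpha enter a multivariate logistic model of the
    *adverse* outcome (endpoint == 0 for termination, == 1 for recurrence);
    ROC per significant metric, oriented by the group-mean direction; plus
    the combined dichotomized model for termination failure.  Deterministic
    given the cohort.  Returns a dict of DataFrames and fit objects.
    """
    if metric_columns is None:
        metric_columns = [
            c for c in cohort.columns
            if c.split("_")[0] in {"fwa", "df", "oi", "se", "sampen"}
        ]
    covariate_columns = covariate_columns or [
        c for c in cohort.columns
        if c not in metric_columns and c not in ("id", *outcomes)
    ]
    report: dict = {"alpha": alpha}

    for outcome in outcomes:
        if outcome not in cohort.columns:
            raise ValueError(f"cohort lacks outcome column {outcome!r}")
        adverse = (
            (1 - cohort[outcome]) if outcome == "endpoint_termination"
            else cohort[outcome]
        ).astype(int)
        work = cohort.assign(_adverse=adverse)

        uni = univariate_screen(work, metric_columns + covariate_columns, "_adverse",
                                alpha)
        uni_df = pd.DataFrame(
            [{"variable": u.variable, "test": u.test_name,
              "statistic": u.statistic, "p_value": u.p_value} for u in uni]
        )
        sig = [u.variable for u in uni
               if np.isfinite(u.p_value) and u.p_value < alpha]
        multi = fit_logistic(work, sig, "_adverse") if sig else None

        rocs = {}
        for var in sig:
            if var not in metric_columns and var not in covariate_columns:
                continue
            if _is_categorical(work[var]):
                continue
            direction = (
                "lower"
                if work.loc[adverse == 1, var].mean() < work.loc[adverse == 0, var].mean()
                else "higher"
            )
            rocs[var] = roc_analysis(work[var].to_numpy(), adverse.to_numpy(),
                                     direction)
        report[outcome] = {
            "univariate": uni_df,
            "significant": sig,
            "multivariate": multi,
            "roc": rocs,
        }

    term_adverse = (1 - cohort["endpoint_termination"]).astype(int)
    if {"fwa_v1", "df_i"}.issubset(cohort.columns):
        work = cohort.assign(_failure=term_adverse)
        report["combined_model"] = combined_predictor(
            work, "_failure", cutoff_fwa_v1, cutoff_df_i,
        )
    return report


def report_to_text(report: dict) -> str:
    """Render a run_study report bundle as plain text."""
    lines: list[str] = []
    for outcome in ("endpoint_termination", "endpoint_recurrence"):
        if outcome not in report:
            continue
        r = report[outcome]
        lines.append(f"== {outcome} (adverse-outcome analysis) ==")
        lines.append(r["univariate"].to_string(index=False))
        lines.append(f"significant at alpha={report['alpha']}: {r['significant']}")
        m = r["multivariate"]
        if m is not None and m.odds_ratio:
            for p in m.predictors:
                lo, hi = m.ci95[p]
                lines.append(
                    f"  OR[{p}] = {m.odds_ratio[p]:.3f} "
                    f"(95% CI {lo:.3f}-{hi:.3f}), p = {m.p_value[p]:.4f}"
                )
        for var, roc in r["roc"].items():
            lines.append(
                f"  ROC[{var}]: AUC = {roc.auc:.3f} "
                f"(95% CI {roc.ci95[0]:.3f}-{roc.ci95[1]:.3f}), "
                f"cutoff = {roc.cutoff:.2f} ({roc.orientation} predicts adverse), "
                f"sens = {roc.sensitivity:.3f}, spec = {roc.specificity:.3f}"
            )
        lines.append("")
    cm = report.get("combined_model")
    if cm:
        lines.append("== combined dichotomized predictor (termination failure) ==")
        for name, fit in cm.items():
            if fit.odds_ratio:
                for p in fit.predictors:
                    lo, hi = fit.ci95[p]
                    lines.append(
                        f"  [{name}] OR[{p}] = {fit.odds_ratio[p]:.3f} "
                        f"(95% CI {lo:.3f}-{hi:.3f}), p = {fit.p_value[p]:.4f}"
                    )
            else:
                lines.append(f"  [{name}] non-reportable: {fit.flags}")
    return "\n".join(lines)
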