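"""Group comparison, ROC and collinearity workflow for histogram features.

Continuous features are compared with an independent-sample t-test when
both groups pass Shapiro–Wilk normality (α = 0.05), otherwise with the
Mann–Whitney U test; categorical covariates use the chi-squared test.
Discriminative performance is summarized by the empirical AUC with a
DeLong 95% CI and the Youden-optimal cutoff with its sensitivity and
specificity expressed as "% (k/n)". Features surviving a tolerance/VIF
collinearity screen enter a combined binary logistic model whose in-sample
(apparent) ROC is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RocResult",
    "CombinedModel",
    "IccResult",
    "compare_feature",
    "compare_categorical",
    "roc_analysis",
    "confusion_metrics",
    "delong_ci",
    "collinearity_screen",
    "fit_combined_model",
    "icc_interobserver",
    "format_roc_row",
]


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    test: str                 # "t", "mann_whitney" or "chi_squared"
    statistic: float
    p_value: float
    summary_a: str
    summary_b: str
    normal_a: bool | None = None
    normal_b: bool | None = None
    flag: str | None = None


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}–{q3:.3g})"


def compare_feature(values_a, values_b, feature: str = "",
                    alpha_normality: float = 0.05) -> ComparisonResult:
    """Two-group comparison with normality-dependent test choice.

    Both groups normal by Shapiro–Wilk → independent-sample t-test;
    otherwise Mann–Whitney U (two-sided). A feature constant in both
    groups is reported with p = 1 and a flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a[0] == b[0]
        return ComparisonResult(feature, "t", 0.0, 1.0, f"{a[0]:.3g}", f"{b[0]:.3g}",
                                flag="constant in both groups"
                                if same else "constant within groups")
    norm_a = np.ptp(a) > 0 and sps.shapiro(a).pvalue >= alpha_normality
    norm_b = np.ptp(b) > 0 and sps.shapiro(b).pvalue >= alpha_normality
    if norm_a and norm_b:
        res = sps.ttest_ind(a, b)
        test = "t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return ComparisonResult(feature, test, float(res.statistic), float(res.pvalue),
                            _summary(a, norm_a and norm_b),
                            _summary(b, norm_a and norm_b),
                            normal_a=bool(norm_a), normal_b=bool(norm_b))


def compare_categorical(counts_a, counts_b, feature: str = "") -> ComparisonResult:
    """Chi-squared test on a 2×k contingency table of category counts."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    chi2, p, _, _ = sps.chi2_contingency(table)
    return ComparisonResult(feature, "chi_squared", float(chi2), float(p),
                            str(list(map(int, counts_a))),
                            str(list(map(int, counts_b))))


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    counts: dict = field(default_factory=dict)  # tp, fn, tn, fp
    direction: str = ">="   # predicted positive when value 'direction' cutoff

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("AUC outside its confidence interval")


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """Empirical AUC as the normalized Mann–Whitney U statistic."""
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def delong_ci(values, labels, level: float = 0.95) -> tuple[float, float, float]:
    """Empirical AUC and DeLong confidence interval.

    Uses the structural-component (placement-value) estimator of the AUC
    variance; the interval is truncated to [0, 1].
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = x[y == 1], x[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    zq = sps.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity and specificity (percent, 2 decimals) from raw counts."""
    for v in (tp, fn, tn, fp):
        if v < 0 or v != int(v):
            raise ValueError("counts must be nonnegative integers")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("zero denominator in sensitivity or specificity")
    return {"sensitivity_pct": round(100.0 * tp / (tp + fn), 2),
            "specificity_pct": round(100.0 * tn / (tn + fp), 2)}


def roc_analysis(feature_values, labels) -> RocResult:
    """ROC of one feature against binary labels.

    The orientation (higher or lower values indicating the positive class)
    is chosen so AUC ≥ 0.5, matching how diagnostic tables are reported.
    The cutoff maximizes the Youden index J = sensitivity + specificity − 1;
    sensitivity/specificity and the raw confusion counts are evaluated at
    that cutoff.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (y == y.max()).astype(int)
    auc, lo, hi = delong_ci(x, y)
    direction = ">="
    if auc < 0.5:
        x = -x
        auc, lo, hi = delong_ci(x, y)
        direction = "<="
    pos, neg = x[y == 1], x[y == 0]
    cands = np.unique(x)
    best_j, cutoff, best = -np.inf, cands[0], None
    for t in cands:
        tp = int((pos >= t).sum()); fn = pos.size - tp
        tn = int((neg < t).sum()); fp = neg.size - tn
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, cutoff, best = j, t, (tp, fn, tn, fp)
    tp, fn, tn, fp = best
    cm = confusion_metrics(tp, fn, tn, fp)
    return RocResult(auc=auc, ci_low=lo, ci_high=hi,
                     cutoff=float(cutoff) if direction == ">=" else float(-cutoff),
                     sensitivity_pct=cm["sensitivity_pct"],
                     specificity_pct=cm["specificity_pct"],
                     counts={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
                     direction=direction)


def collinearity_screen(feature_matrix: pd.DataFrame,
                        vif_max: float = 10.0, tol_min: float = 0.1
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Iterative tolerance/VIF screen.

    Each feature is regressed on the others; VIF = 1/(1 − R²), Tol = 1/VIF.
    Features with Tol < 0.1 or VIF > 10 are excluded greedily (worst first,
    recompute) until all pass. On exact collinearity the later-listed
    feature of the offending set is dropped with a warning.

    Returns the final diagnostics table and the retained feature names.
    """
    X = feature_matrix.astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more subjects than features + 1")
    retained = list(X.columns)

    def vifs(cols):
        out = {}
        for c in cols:
            others = [o for o in cols if o != c]
            if not others:
                out[c] = 1.0
                continue
            a = np.column_stack([X[others].to_numpy(),
                                 np.ones(len(X))])
            b = X[c].to_numpy()
            coef, _, _, _ = np.linalg.lstsq(a, b, rcond=None)
            resid = b - a @ coef
            sst = np.sum((b - b.mean()) ** 2)
            r2 = 0.0 if sst == 0 else max(0.0, 1.0 - np.sum(resid ** 2) / sst)
            out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while len(retained) > 1:
        v = vifs(retained)
        worst = max(retained, key=lambda c: (v[c], retained.index(c)))
        if v[worst] <= vif_max and 1.0 / v[worst] >= tol_min:
            break
        if np.isinf(v[worst]):
            warnings.warn(f"feature '{worst}' is perfectly collinear; dropped",
                          stacklevel=2)
        retained.remove(worst)
    v = vifs(retained)
    diag = pd.DataFrame({"feature": retained,
                         "vif": [v[c] for c in retained],
                         "tolerance": [1.0 / v[c] for c in retained]})
    return diag, retained


@dataclass
class CombinedModel:
    features: list[str]
    coefficients: np.ndarray
    intercept: float
    diagnostics: pd.DataFrame
    separation_fallback: bool = False

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = X[self.features].to_numpy() @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


def fit_combined_model(feature_matrix: pd.DataFrame, labels,
                       screen: bool = True) -> tuple[CombinedModel, RocResult]:
    """Binary logistic model over (screened) features, with apparent ROC.

    Maximum-likelihood logistic regression; when complete separation (or
    non-convergence) occurs, a ridge-stabilized fit is used with a warning.
    The ROC is computed on in-sample predicted probabilities — apparent
    performance without cross-validation, as in single-cohort reports.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=int)
    y = (y == y.max()).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")
    if screen:
        diag, retained = collinearity_screen(feature_matrix)
    else:
        retained = list(feature_matrix.columns)
        diag = pd.DataFrame({"feature": retained})
    X = feature_matrix[retained].astype(float)
    Xs = sm.add_constant(X.to_numpy())
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, Xs).fit(disp=0, maxiter=200)
            params = fit.params
            if not np.all(np.isfinite(fit.bse)):
                raise RuntimeError("unstable standard errors")
        except Exception:
            fallback = True
    if fallback:
        warnings.warn("separation or non-convergence detected; using a "
                      "ridge-stabilized logistic fit", stacklevel=2)
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0, max_iter=5000)
        lr.fit(X.to_numpy(), y)
        params = np.concatenate([[lr.intercept_[0]], lr.coef_[0]])
    model = CombinedModel(features=retained, coefficients=np.asarray(params[1:]),
                          intercept=float(params[0]), diagnostics=diag,
                          separation_fallback=fallback)
    roc = roc_analysis(model.predict_proba(X), y)
    return model, roc


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str = "ICC2 (two-way random, absolute agreement, single measure)"
    flagged: bool = False


def icc_interobserver(measurements_rater1, measurements_rater2) -> IccResult:
    """Inter-observer agreement as a two-way random-effects, absolute-
    agreement, single-measure ICC over paired per-subject measurements."""
    import pingouin as pg

    a = np.asarray(measurements_rater1, dtype=float)
    b = np.asarray(measurements_rater2, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need >= 5 paired measurements")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return IccResult(float("nan"), float("nan"), float("nan"), flagged=True)
    df = pd.DataFrame({
        "target": np.tile(np.arange(a.size), 2),
        "rater": np.repeat(["r1", "r2"], a.size),
        "score": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
    # pingouin labels the two-way random, absolute-agreement, single-measure
    # ICC "ICC2" in older releases and "ICC(A,1)" in newer ones
    sel = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return IccResult(float(row["ICC"]), float(lo), float(hi))


def format_roc_row(name: str, roc: RocResult) -> dict[str, str]:
    """One diagnostic-table row: cutoff, '% (k/n)' cells and 'AUC (lo-hi)'."""
    c = roc.counts
    return {
        "feature": name,
        "cutoff": f"{roc.cutoff:.3g}",
        "sensitivity": f"{roc.sensitivity_pct:.2f}% ({c['tp']}/{c['tp'] + c['fn']})",
        "specificity": f"{roc.specificity_pct:.2f}% ({c['tn']}/{c['tn'] + c['fp']})",
        "auc": f"{roc.auc:.2f} ({roc.ci_low:.2f}-{roc.ci_high:.2f})",
    }
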