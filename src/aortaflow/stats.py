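"""Cohort-level statistics for the exercise-capacity analysis.

Covers: Pearson correlation, stepwise (forward selection with backward
elimination) OLS for the determinants of peak oxygen uptake, the published
composite PVO2 model, empirical ROC with the Youden-index threshold and a
Hanley-McNeil AUC confidence interval, the nested logistic likelihood-ratio
test for incremental discriminative value, agreement indices (two-way mixed
consistency average-measures ICC, paired coefficient of variation,
Bland-Altman limits), and small CPET utilities (METs, risk strata, VE/VCO2
slope).  No multiple-comparison adjustment is applied anywhere.

Model fits go through statsmodels; the selection logic, ROC construction and
agreement formulas are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import SeparationError, ValidationError

# Composite model for CMR-derived peak oxygen uptake (mL/kg/min):
# PVO2 = 20.729 + 0.443*FFi - 0.261*FDs_avg - 0.172*LVEF
PVO2_MODEL_INTERCEPT = 20.729
PVO2_MODEL_COEF_FFI = 0.443
PVO2_MODEL_COEF_FDS_AVG = -0.261
PVO2_MODEL_COEF_LVEF = -0.172

ML_O2_PER_MET = 3.5  # mL O2 / kg / min per metabolic equivalent


@dataclass(frozen=True)
class TermStats:
    coef: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LinearModel:
    """A fitted OLS model: named coefficients with 95% CIs and p-values."""

    terms: dict[str, TermStats]
    intercept: TermStats
    r_squared: float
    n: int
    selection_order: list[str] = field(default_factory=list)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        y = np.full(len(df), self.intercept.coef)
        for name, ts in self.terms.items():
            y = y + ts.coef * df[name].to_numpy(dtype=float)
        return y


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    youden_index: float
    direction: str


@dataclass
class AgreementStats:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    cv_pct: float | None = None


# ---------------------------------------------------------------------------
# correlation and regression


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson needs equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("pearson requires finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("pearson undefined for a zero-variance vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _fit_ols(df: pd.DataFrame, response: str, terms: list[str]):
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for t in terms:
        X[t] = df[t].astype(float)
    return sm.OLS(df[response].astype(float), X).fit()


def _model_from_fit(fit, terms: list[str], order: list[str]) -> LinearModel:
    ci = fit.conf_int(alpha=0.05)

    def ts(name: str) -> TermStats:
        return TermStats(
            coef=float(fit.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(fit.pvalues[name]),
        )

    return LinearModel(
        terms={t: ts(t) for t in terms},
        intercept=ts("const"),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        selection_order=order,
    )


def stepwise_ols(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    prescreen: bool = True,
    cond_limit: float = 1e10,
) -> LinearModel:
    """Forward-selection-with-backward-elimination OLS.

    When ``prescreen`` is set, only candidates univariately associated with
    the response at p < 0.05 enter the candidate pool (the convention for the
    peak-oxygen-uptake determinant analysis).  At each forward step the
    candidate with the smallest coefficient p-value enters if it clears
    ``p_enter``; after each entry, included terms with p > ``p_remove`` are
    eliminated.  Ties break on the lower p-value, then alphabetically, so the
    procedure is deterministic.
    """
    df = table.dropna(subset=[response] + list(candidates))
    if len(df) <= len(candidates) + 2:
        raise ValidationError("too few rows for the number of candidates")

    Z = df[list(candidates)].to_numpy(dtype=float)
    Zs = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) == 0, 1.0, Z.std(axis=0))
    if np.linalg.cond(Zs) > cond_limit:
        raise ValidationError("candidate set is (near-)collinear; refusing stepwise fit")

    pool = sorted(candidates)
    if prescreen:
        keep = []
        for c in pool:
            fit = _fit_ols(df, response, [c])
            if fit.pvalues[c] < 0.05:
                keep.append(c)
        pool = keep

    included: list[str] = []
    order: list[str] = []
    changed = True
    while changed:
        changed = False
        # forward step
        best: tuple[float, str] | None = None
        for c in pool:
            if c in included:
                continue
            fit = _fit_ols(df, response, included + [c])
            p = float(fit.pvalues[c])
            if best is None or (p, c) < best:
                best = (p, c)
        if best is not None and best[0] < p_enter:
            included.append(best[1])
            order.append(best[1])
            changed = True
        # backward step
        while len(included) > 0:
            fit = _fit_ols(df, response, included)
            pvals = {t: float(fit.pvalues[t]) for t in included}
            worst = max(pvals, key=lambda t: (pvals[t], t))
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break

    fit = _fit_ols(df, response, included)
    return _model_from_fit(fit, included, order)


def predict_pvo2_published(ffi: float, fds_avg: float, lvef: float) -> float:
    """CMR-derived PVO2 (mL/kg/min) from the published composite model."""
    return (
        PVO2_MODEL_INTERCEPT
        + PVO2_MODEL_COEF_FFI * ffi
        + PVO2_MODEL_COEF_FDS_AVG * fds_avg
        + PVO2_MODEL_COEF_LVEF * lvef
    )


# ---------------------------------------------------------------------------
# ROC / Youden


def roc_auc_youden(scores, labels, direction: str = "greater") -> RocResult:
    """Empirical ROC with Youden-index threshold selection.

    ``direction="greater"`` means higher scores indicate the positive class
    (``"less"`` flips the rule).  AUC is the tie-halved pairwise concordance
    (equivalently, the trapezoidal area under the empirical ROC).  Candidate
    thresholds are midpoints between adjacent distinct scores plus open
    endpoints; the Youden threshold maximises sensitivity + specificity - 1,
    ties resolved toward higher specificity.  The CI is the normal
    approximation AUC +/- 1.96 x Hanley-McNeil standard error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size != labels.size:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")

    s = scores if direction == "greater" else -scores

    ranks = sps.rankdata(s)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.array([(s[labels] >= c).mean() for c in cuts])
    spec = np.array([(s[~labels] < c).mean() for c in cuts])

    j = sens + spec - 1.0
    # max Youden; among ties prefer higher specificity
    best = max(range(cuts.size), key=lambda i: (j[i], spec[i]))
    youden_cut = cuts[best] if direction == "greater" else -cuts[best]

    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se = math.sqrt(
        (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
        / (n_pos * n_neg)
    )
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))

    thresholds = cuts if direction == "greater" else -cuts
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=a,
        auc_ci=ci,
        youden_threshold=float(youden_cut),
        youden_index=float(j[best]),
        direction=direction,
    )


def auc_concordance_oracle(scores, labels, direction: str = "greater") -> float:
    """Brute-force pairwise concordance AUC (exhaustive over pos/neg pairs).

    Independent of :func:`roc_auc_youden`; intended for cross-validation on
    small inputs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    s = scores if direction == "greater" else -scores
    pos = s[labels]
    neg = s[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


# ---------------------------------------------------------------------------
# nested logistic regression


def nested_logistic_lrt(
    table: pd.DataFrame,
    outcome: str,
    base_terms: list[str],
    added_term: str,
) -> tuple[float, int, float]:
    """Likelihood-ratio test for the incremental value of one predictor.

    Fits logistic models ``outcome ~ base_terms`` and
    ``outcome ~ base_terms + added_term``; returns (chi2, df=1, p).
    Non-convergence (e.g. perfect separation) raises
    :class:`SeparationError`.
    """
    df = table.dropna(subset=[outcome] + list(base_terms) + [added_term])
    y = df[outcome].astype(float)
    if y.nunique() != 2:
        raise ValidationError("outcome must be binary with both classes present")

    def fit(terms: list[str]):
        X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
        for t in terms:
            X[t] = df[t].astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                except np.linalg.LinAlgError:
                    # singular Hessian (collinear terms): BFGS still reaches
                    # the (non-unique) maximum likelihood
                    res = sm.Logit(y, X).fit(method="bfgs", disp=0, maxiter=500)
        except Exception as exc:  # PerfectSeparationError and friends
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise SeparationError("logistic fit did not converge (separation?)")
        return res

    base = fit(list(base_terms))
    full = fit(list(base_terms) + [added_term])
    chi2 = max(0.0, 2.0 * (full.llf - base.llf))
    p = float(sps.chi2.sf(chi2, 1))
    return float(chi2), 1, p


# ---------------------------------------------------------------------------
# agreement statistics


def icc_consistency_average(m1, m2, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Two-way mixed, consistency, average-measures ICC (a.k.a. ICC(3,k), k=2).

    ICC = (MS_between - MS_error) / MS_between from the two-way ANOVA
    decomposition; the CI comes from F-distribution bounds on
    MS_between/MS_error.  Fixed offsets between the two measurements do not
    reduce consistency ICC.
    """
    y = np.column_stack([np.asarray(m1, dtype=float), np.asarray(m2, dtype=float)])
    n, k = y.shape
    if n < 5:
        raise ValidationError("icc needs >= 5 paired observations")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    msr = ss_rows / df_rows
    mse = ss_err / df_err
    if msr <= 0:
        raise ValidationError("zero between-subject variance; ICC undefined")
    if mse == 0:
        return 1.0, (1.0, 1.0)
    icc = (msr - mse) / msr
    f_obs = msr / mse
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
    return float(icc), (float(1 - 1 / fl), float(1 - 1 / fu))


def cv_pairs(m1, m2, *, zero_mean_tol: float = 1e-8) -> float | None:
    """Paired coefficient of variation (%).

    ``CV = 100 * sqrt(sum(d^2) / (2n)) / (sum(m1 + m2) / (2n))`` with ``d``
    the paired differences and ``n`` the number of pairs — the within-subject
    SD over the grand mean.  Returns ``None`` (with a warning) when the grand
    mean is near zero, where a ratio-to-mean is meaningless.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValidationError("cv_pairs needs equal-length non-empty vectors")
    n = a.size
    sd = math.sqrt(float(np.sum((a - b) ** 2)) / (2 * n))
    mean = float(np.sum(a + b)) / (2 * n)
    if abs(mean) <= zero_mean_tol:
        warnings.warn("grand mean near zero; CV not calculated", stacklevel=2)
        return None
    return 100.0 * sd / abs(mean)


def bland_altman(m1, m2) -> AgreementStats:
    """Mean difference, SD of differences, and 95% limits of agreement."""
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValidationError("bland_altman needs paired vectors with n >= 3")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return AgreementStats(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
    )


def agreement_stats(m1, m2) -> AgreementStats:
    """Bland-Altman + ICC + CV in one record (the repeatability panel)."""
    out = bland_altman(m1, m2)
    out.icc, out.icc_ci = icc_consistency_average(m1, m2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out.cv_pct = cv_pairs(m1, m2)
    return out


# ---------------------------------------------------------------------------
# CPET utilities


def mets_from_pvo2(pvo2: float) -> float:
    """Metabolic equivalents; 1 MET = 3.5 mL O2/kg/min."""
    if pvo2 < 0:
        raise ValidationError(f"pvo2 must be >= 0, got {pvo2}")
    return pvo2 / ML_O2_PER_MET


def risk_class(pvo2: float) -> str:
    """Exercise-capacity stratum from peak oxygen uptake (mL/kg/min):
    ``high`` for PVO2 <= 14, ``low_intermediate`` for 14 < PVO2 <= 20,
    ``normal`` above 20."""
    if pvo2 < 0:
        raise ValidationError(f"pvo2 must be >= 0, got {pvo2}")
    if pvo2 <= 14:
        return "high"
    if pvo2 <= 20:
        return "low_intermediate"
    return "normal"


def ve_vco2_slope(ve, vco2) -> float:
    """Ventilatory-efficiency slope: OLS slope of VE on VCO2."""
    ve = np.asarray(ve, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if ve.size != vco2.size or ve.size < 3:
        raise ValidationError("need >= 3 paired VE/VCO2 samples")
    if np.var(vco2) == 0:
        raise ValidationError("VCO2 has zero variance; slope undefined")
    res = sps.linregress(vco2, ve)
    return float(res.slope)


# ---------------------------------------------------------------------------
# thin group-comparison wrappers (descriptive only)


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F and p (thin wrapper around scipy)."""
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p (thin wrapper around scipy)."""
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def chi_square_counts(table) -> tuple[float, float]:
    """Chi-square test of a contingency table (thin wrapper around scipy)."""
    res = sps.chi2_contingency(np.asarray(table))
    return float(res.statistic), float(res.pvalue)
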