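"""Statistical machinery for the volumetry analysis.

Correlations (Pearson / Spearman), maximum-likelihood logistic regression
with Wald inference and separation detection, variance-inflation-factor
multicollinearity screening, ROC/AUC with the Mann-Whitney ½-tie
convention, the DeLong test for paired correlated AUCs, and the two-way
random-effects intraclass correlation coefficient for inter-observer
agreement.

Logistic fits go through statsmodels (Newton iterations, score tolerance
1e-8, at most 50 iterations); odds ratios, their Wald 95% CIs and p-values
are derived from the inverse observed information.  "HR" columns of the
clinical literature this mirrors are odds ratios — the endpoint is binary,
there is no time axis.

The DeLong comparison uses the structural-component (placement-value)
estimator of the AUC covariance; nothing installed provides it, so it is
implemented here and validated against a bootstrap oracle in the test
suite.  The ICC defaults to the two-way random-effects, absolute-agreement,
single-measure form ICC(2,1) — readers are a random sample and systematic
reader offsets should count as disagreement — with ICC(3,1) selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DegenerateStatisticError, ParameterError

__all__ = [
    "LogisticFit",
    "RocCurve",
    "RocComparison",
    "correlate",
    "fit_logistic",
    "vif",
    "roc",
    "delong_compare",
    "icc",
    "icc_band",
]


# ---------------------------------------------------------------- correlation


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """(coefficient, two-sided p) by Pearson or Spearman (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1D and of equal length")
    if len(x) < 3:
        raise ParameterError("correlation requires at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateStatisticError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r), float(p)


# ------------------------------------------------------- logistic regression


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``converged=False`` (separation or Newton failure) marks the fit
    unusable; numeric fields are then NaN rather than huge coefficients.
    """

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    n_obs: int
    diagnostic: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            },
            index=self.names,
        )


def fit_logistic(X, y, names: list[str] | None = None, add_intercept: bool = True) -> LogisticFit:
    """Fit P(y=1) = logistic(X @ beta) by Newton iterations.

    ``X`` is the design matrix without intercept unless
    ``add_intercept=False``.  Complete or quasi-complete separation yields
    ``converged=False`` with a diagnostic, never silent huge coefficients;
    a rank-deficient design raises.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ParameterError("X and y have incompatible shapes")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ParameterError("y must be binary 0/1")
    if len(set(y)) < 2:
        raise ParameterError("both outcome classes must be present")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    if X.shape[0] <= X.shape[1]:
        raise ParameterError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ParameterError("design matrix is rank-deficient")

    k = X.shape[1]
    nan = np.full(k, np.nan)

    def _failed(msg: str, n_iter: int = 0) -> LogisticFit:
        return LogisticFit(
            names, nan.copy(), nan.copy(), nan.copy(), nan.copy(), nan.copy(), nan.copy(),
            float("nan"), False, n_iter, len(y), diagnostic=msg,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warning handled below
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=50, tol=1e-8, disp=0, warn_convergence=False
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return _failed(f"separation or singular information: {exc}")

    n_iter = int(res.mle_retvals.get("iterations", 0))
    if not res.mle_retvals.get("converged", False):
        return _failed("Newton iterations did not converge within 50 steps", n_iter)
    se = np.asarray(res.bse)
    coef = np.asarray(res.params)
    # quasi-complete separation can pass statsmodels' check yet blow up the scale
    if not np.all(np.isfinite(se)) or np.any(np.abs(coef) > 1e2):
        return _failed("coefficients diverged (quasi-complete separation)", n_iter)
    ci = np.asarray(res.conf_int())
    return LogisticFit(
        names=names,
        coefficients=coef,
        standard_errors=se,
        odds_ratios=np.exp(coef),
        ci_lower=np.exp(ci[:, 0]),
        ci_upper=np.exp(ci[:, 1]),
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(res.llf),
        converged=True,
        n_iterations=n_iter,
        n_obs=len(y),
    )


# ------------------------------------------------------------------- VIF


def vif(X, names: list[str] | None = None) -> pd.DataFrame:
    """Variance inflation factors 1/(1-R^2_j) with intercepted auxiliary fits.

    Returns a frame with columns ``vif`` and ``flag``; flags follow the
    screening bands used with this analysis: ``high`` for VIF in [2.5, 10)
    and ``extreme`` for VIF >= 10 or exact collinearity (infinite VIF).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("VIF needs a 2D design with at least 2 predictors")
    n, k = X.shape
    if n <= k + 1:
        raise ParameterError("need n > number of predictors + 1")
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out = []
    for j in range(k):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        r2 = sm.OLS(target, others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            out.append((float("inf"), "extreme"))
            continue
        v = 1.0 / (1.0 - r2)
        out.append((v, "extreme" if v >= 10 else "high" if v >= 2.5 else "ok"))
    return pd.DataFrame(out, columns=["vif", "flag"], index=list(names))


# ------------------------------------------------------------------- ROC


@dataclass
class RocCurve:
    """AUC plus the trapezoidal curve; records whether the score was flipped."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    flipped: bool


def roc(scores, labels, orientation: str = "auto") -> RocCurve:
    """ROC curve and AUC (Mann-Whitney statistic; ties count half).

    ``orientation='auto'`` flips the score when its point-biserial
    association with the positive class is negative, so AUC >= 0.5 for any
    informative score; the flip is recorded.  ``as_is`` and ``reversed``
    force the orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = set(np.unique(labels))
    if not classes <= {0, 1} or len(classes) < 2:
        raise ParameterError("labels must contain both classes 0 and 1")
    if orientation not in ("auto", "as_is", "reversed"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    flipped = False
    if orientation == "reversed":
        flipped = True
    elif orientation == "auto" and np.std(scores) > 0:
        if np.corrcoef(scores, labels.astype(float))[0, 1] < 0:
            flipped = True
    use = -scores if flipped else scores
    fpr, tpr, thr = roc_curve(labels, use)
    return RocCurve(float(roc_auc_score(labels, use)), fpr, tpr, thr, flipped)


# ----------------------------------------------------------------- DeLong


@dataclass
class RocComparison:
    """Paired AUC comparison via DeLong's structural components."""

    auc_a: float
    auc_b: float
    auc_difference: float
    variance: float
    z: float
    p: float
    flipped_a: bool
    flipped_b: bool


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-case placement values V10 (positives) and V01 (negatives), and AUC."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rk = sps.rankdata(combined)  # midranks
    rk_pos = sps.rankdata(pos)
    rk_neg = sps.rankdata(neg)
    v10 = (rk[:m] - rk_pos) / n
    v01 = 1.0 - (rk[m:] - rk_neg) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_compare(scores_a, scores_b, labels, orientation: str = "auto") -> RocComparison:
    """DeLong test for the difference of two correlated (paired) AUCs.

    Scores must be paired on identical cases.  Each score is oriented per
    ``orientation`` (see :func:`roc`) before comparison; the z statistic is
    the AUC difference over the DeLong standard error, with a two-sided
    normal p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ParameterError("scores and labels must be paired (equal length)")
    ra = roc(scores_a, labels, orientation)
    rb = roc(scores_b, labels, orientation)
    a = -scores_a if ra.flipped else scores_a
    b = -scores_b if rb.flipped else scores_b
    pos_mask = labels == 1
    v10a, v01a, auc_a = _placements(a[pos_mask], a[~pos_mask])
    v10b, v01b, auc_b = _placements(b[pos_mask], b[~pos_mask])
    m, n = pos_mask.sum(), (~pos_mask).sum()
    s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2, ddof=1
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] - 2 * s10[0, 1] + s10[1, 1]) / m + (
        s01[0, 0] - 2 * s01[0, 1] + s01[1, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) < 1e-12:
            return RocComparison(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0, ra.flipped, rb.flipped)
        raise DegenerateStatisticError(
            "zero variance of the AUC difference with a nonzero difference"
        )
    z = delta / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RocComparison(auc_a, auc_b, delta, float(var), float(z), float(p),
                         ra.flipped, rb.flipped)


# ------------------------------------------------------------------- ICC


def icc_band(value: float) -> str:
    """Agreement band: <0.40 poor, 0.40-0.59 fair, 0.60-0.74 good, >=0.75 excellent."""
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def icc(ratings, variant: str = "icc2") -> tuple[float, str]:
    """Intraclass correlation coefficient of a cases x readers matrix.

    ``icc2``: two-way random effects, absolute agreement, single measure
    (default).  ``icc3``: two-way mixed, consistency, single measure.
    Returns (value, agreement band).
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2 or R.shape[0] < 5:
        raise ParameterError("need a cases x readers matrix with >=5 cases and >=2 readers")
    if np.isnan(R).any():
        raise ParameterError("missing cells are not supported")
    if np.ptp(R) == 0:
        raise DegenerateStatisticError("ICC undefined for a constant ratings matrix")
    n, k = R.shape
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ParameterError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        raise DegenerateStatisticError("ICC undefined (zero denominator)")
    value = float((msr - mse) / denom)
    return value, icc_band(value)
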