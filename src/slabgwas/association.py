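"""Step-2 association testing.

Raw proportional score statistics — (x' y_loco)^2 / (x' x) for quantitative
traits and (x'(y - p))^2 / (x' W x) for binary traits — are rescaled by a
per-trait calibration factor chosen so their mean matches the effective
sample size implied by (i) plain linear/logistic regression on an unrelated
homogeneous calibration subset, (ii) the held-out residual-variance gain of
the Bayesian whole-genome predictor and (iii) a relatedness correction that
discounts duplicated genome shares of relative pairs up to third degree.
Binary traits additionally get an approximate Firth likelihood-ratio re-test
for rare variants or rare traits at nominally significant score P-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFactor",
    "score_stat_quant",
    "score_scan_quant",
    "score_stat_binary",
    "score_scan_binary",
    "linear_reference_chisq",
    "logistic_reference_chisq",
    "logistic_covariate_offset",
    "calibrate",
    "detect_related_pairs",
    "effective_sample_size",
    "firth_lrt",
    "apply_fallback_policy",
    "weighted_score_test",
    "chisq_to_log10p",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "CHR", "SNP", "BP", "A1", "A2", "A1FREQ", "N", "TEST",
    "BETA", "SE", "CHISQ", "LOG10P", "P",
]

# kinship bounds: third-degree relatives down to 2^-4.5, duplicates ~0.5
KINSHIP_THIRD_DEGREE = 2.0 ** -4.5


@dataclass
class CalibrationFactor:
    """Per-trait multiplier mapping raw proportional statistics to chi^2_1."""

    gamma: float
    reference_mean_chisq: float
    raw_mean_chisq: float
    neff_gain: float = 1.0
    relatedness_adjustment: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("calibration factor must be positive")


# ---------------------------------------------------------------------------
# Raw score statistics
# ---------------------------------------------------------------------------


def score_stat_quant(x_test: np.ndarray, ytilde: np.ndarray):
    """Raw quantitative score statistic (x' y)^2 / (x' x) plus effect size.

    Returns (raw_stat, beta_hat); ``beta_hat`` = x'y / x'x.  Zero-variance
    x is the caller's responsibility (see ``score_scan_quant``).
    """
    xx = float(x_test @ x_test)
    if xx <= 0:
        raise ValueError("test dosage vector has zero sum of squares")
    xy = float(x_test @ ytilde)
    return xy * xy / xx, xy / xx


def score_scan_quant(X: np.ndarray, ytilde: np.ndarray):
    """Vectorized raw statistics over the columns of X; NaN where x'x = 0."""
    xx = np.einsum("ij,ij->j", X, X, dtype=np.float64)
    xy = (X.T @ ytilde.astype(X.dtype)).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xx > 0, xy / xx, np.nan)
        raw = np.where(xx > 0, xy * xy / xx, np.nan)
    return raw, beta


def score_stat_binary(x_test, y, phat, W=None):
    """Raw binary score statistic T_B^2 = (x'(y - p))^2 / (x' W x)."""
    phat = np.asarray(phat, float)
    w = phat * (1 - phat) if W is None else np.asarray(W, float)
    xwx = float(np.sum(w * x_test * x_test))
    if xwx <= 0:
        raise ValueError("x' W x is zero; variant cannot be tested")
    num = float(x_test @ (y - phat))
    return num * num / xwx, num / xwx


def score_scan_binary(X, y, phat, W=None):
    """Vectorized binary raw statistics over columns; NaN where x'Wx = 0."""
    phat = np.asarray(phat, float)
    w = phat * (1 - phat) if W is None else np.asarray(W, float)
    resid = (y - phat).astype(X.dtype)
    num = (X.T @ resid).astype(np.float64)
    xwx = np.einsum("ij,i,ij->j", X, w.astype(X.dtype), X, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(xwx > 0, num * num / xwx, np.nan)
        beta = np.where(xwx > 0, num / xwx, np.nan)
    return raw, beta


# ---------------------------------------------------------------------------
# Reference statistics for calibration
# ---------------------------------------------------------------------------


def linear_reference_chisq(X: np.ndarray, y_adj: np.ndarray) -> np.ndarray:
    """Classical per-variant linear-regression score chi^2, N * corr(x, y)^2.

    Both arguments must already be covariate-adjusted within the reference
    subset.
    """
    n = X.shape[0]
    y = np.asarray(y_adj, float)
    yc = y - y.mean()
    xc = X - X.mean(axis=0, keepdims=True)
    num = (xc.T @ yc.astype(xc.dtype)).astype(np.float64) ** 2
    den = np.einsum("ij,ij->j", xc, xc, dtype=np.float64) * float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, n * num / den, np.nan)


def _logistic_irls(C, y, offset=None, max_iter=100, tol=1e-10):
    """Plain Newton–Raphson logistic regression; returns coefficients."""
    C = np.asarray(C, float)
    y = np.asarray(y, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    beta = np.zeros(C.shape[1])
    for _ in range(max_iter):
        eta = off + C @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = C.T @ (y - p)
        H = (C * w[:, None]).T @ C
        H.flat[:: H.shape[0] + 1] += 1e-10
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def logistic_covariate_offset(y: np.ndarray, C: np.ndarray | None):
    """Fixed-effect logit offset from covariate-only logistic regression.

    An intercept is always included; returns the fitted linear predictor,
    held fixed during the step-1 logistic SVI.
    """
    n = len(y)
    ones = np.ones((n, 1))
    Cfull = ones if C is None else np.column_stack([ones, np.asarray(C, float)])
    beta = _logistic_irls(Cfull, y)
    return Cfull @ beta


def logistic_reference_chisq(X, y, C=None) -> np.ndarray:
    """Per-variant efficient-score chi^2 from plain logistic regression.

    The null model is covariate-only; each dosage column is W-orthogonalized
    against the covariates before forming (x'(y-p))^2 / (x' W x).
    """
    n = len(y)
    ones = np.ones((n, 1))
    Cfull = ones if C is None else np.column_stack([ones, np.asarray(C, float)])
    coef = _logistic_irls(Cfull, y)
    p = 1.0 / (1.0 + np.exp(-(Cfull @ coef)))
    w = p * (1 - p)
    CtWC = (Cfull * w[:, None]).T @ Cfull
    proj = Cfull @ np.linalg.solve(CtWC, (Cfull * w[:, None]).T @ X)
    Xt = X - proj.astype(X.dtype)
    resid = (y - p).astype(np.float64)
    num = (Xt.astype(np.float64).T @ resid) ** 2
    den = np.einsum("ij,i,ij->j", Xt, w.astype(Xt.dtype), Xt, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibrate(
    raw_stats: np.ndarray,
    ref_stats: np.ndarray,
    neff_gain: float = 1.0,
    relatedness_adjustment: float = 1.0,
) -> CalibrationFactor:
    """Match mean chi^2 against the reference effective sample size.

    gamma = [(mean ref chi^2 - 1) * neff_gain * relatedness_adjustment + 1]
            / mean raw chi^2,

    where the reference mean comes from plain regression on the unrelated
    homogeneous calibration subset, over the same genome-wide calibration
    variants as the raw mean.
    """
    raw = np.asarray(raw_stats, float)
    ref = np.asarray(ref_stats, float)
    raw_mean = float(np.nanmean(raw))
    ref_mean = float(np.nanmean(ref))
    if raw_mean <= 0:
        raise ValueError("mean raw statistic must be positive")
    target = (ref_mean - 1.0) * neff_gain * relatedness_adjustment + 1.0
    target = max(target, 0.05)  # guard against pathological null noise
    return CalibrationFactor(
        gamma=target / raw_mean,
        reference_mean_chisq=ref_mean,
        raw_mean_chisq=raw_mean,
        neff_gain=neff_gain,
        relatedness_adjustment=relatedness_adjustment,
    )


def detect_related_pairs(
    X_std: np.ndarray, min_kinship: float = KINSHIP_THIRD_DEGREE
):
    """Kinship-flagged sample pairs from standardized genotypes.

    The genomic relationship matrix X X' / M halved approximates the
    kinship coefficient; pairs above ``min_kinship`` (third-degree cutoff
    2^-4.5) are returned as (i, j, phi) with i < j.
    """
    n, m = X_std.shape
    grm = (X_std @ X_std.T).astype(np.float64) / m
    phi = grm / 2.0
    iu = np.triu_indices(n, k=1)
    mask = phi[iu] > min_kinship
    return list(zip(iu[0][mask], iu[1][mask], phi[iu][mask]))


def effective_sample_size(n: int, pairs) -> float:
    """N minus duplicated genome shares, N_eff = N - sum_pairs 2 phi."""
    return float(n - sum(2.0 * phi for _, _, phi in pairs))


# ---------------------------------------------------------------------------
# Approximate Firth logistic regression
# ---------------------------------------------------------------------------


def _firth_penalized_loglik(beta, x, y, eta0):
    eta = eta0 + beta * x
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    info = float(np.sum(p * (1 - p) * x * x))
    return ll + 0.5 * np.log(max(info, 1e-300))


def firth_lrt(
    x_test: np.ndarray,
    y: np.ndarray,
    C: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Approximate Firth logistic regression for a single variant.

    The covariate (+ genetic offset) null model is fitted unpenalized and
    held fixed; only the variant effect is estimated, maximizing the
    Jeffreys-penalized likelihood l(beta) + 0.5 log I(beta) by damped
    Newton.  Returns (beta_hat, se, lrt_chisq, p_value, converged); the
    LRT is 2 [l_pen(beta_hat) - l_pen(0)], referred to chi^2_1.
    """
    x = np.asarray(x_test, float)
    y = np.asarray(y, float)
    n = len(y)
    ones = np.ones((n, 1))
    Cfull = ones if C is None else np.column_stack([ones, np.asarray(C, float)])
    alpha = _logistic_irls(Cfull, y, offset=offset)
    eta0 = Cfull @ alpha + (0.0 if offset is None else np.asarray(offset, float))

    beta = 0.0
    ll_old = _firth_penalized_loglik(beta, x, y, eta0)
    ll0 = ll_old
    converged = False
    for _ in range(max_iter):
        eta = eta0 + beta * x
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        info = float(np.sum(w * x * x))
        if info <= 0:
            break
        score = float(x @ (y - p)) + 0.5 * float(np.sum(x**3 * w * (1 - 2 * p))) / info
        step = score / info
        # damped update: halve until the penalized likelihood improves
        for _ in range(30):
            ll_new = _firth_penalized_loglik(beta + step, x, y, eta0)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta += step
        if abs(step) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    eta = eta0 + beta * x
    p = 1.0 / (1.0 + np.exp(-eta))
    info = float(np.sum(p * (1 - p) * x * x))
    se = 1.0 / np.sqrt(max(info, 1e-300))
    lrt = max(2.0 * (_firth_penalized_loglik(beta, x, y, eta0) - ll0), 0.0)
    pval = float(stats.chi2.sf(lrt, df=1))
    return beta, se, lrt, pval, converged


def apply_fallback_policy(
    results: pd.DataFrame,
    trait_prevalence: float,
    firth_fn=None,
    maf_threshold: float = 0.05,
    prevalence_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Re-test score hits with approximate Firth where asymptotics are fragile.

    Exactly the variants with score P < ``p_threshold`` AND (MAF <
    ``maf_threshold`` OR trait prevalence < ``prevalence_threshold``) are
    re-tested; ``firth_fn(row_index)`` must return the ``firth_lrt`` tuple.
    Rows keep the score result when the Firth fit fails to converge.
    """
    res = results.copy()
    needs = (res["P"] < p_threshold) & (
        (res["A1FREQ"].clip(upper=1 - res["A1FREQ"]) < maf_threshold)
        | (trait_prevalence < prevalence_threshold)
    )
    if firth_fn is None:
        res["NEEDS_FIRTH"] = needs
        return res
    for idx in res.index[needs]:
        beta, se, lrt, pval, conv = firth_fn(idx)
        if not conv:
            continue
        res.loc[idx, ["BETA", "SE", "CHISQ", "P", "TEST"]] = [
            beta, se, lrt, pval, "firth",
        ]
        res.loc[idx, "LOG10P"] = chisq_to_log10p(np.array([lrt]))[0]
    return res


# ---------------------------------------------------------------------------
# Participation-bias weighted testing
# ---------------------------------------------------------------------------


def weighted_scan(X: np.ndarray, ytilde: np.ndarray, weights: np.ndarray):
    """Vectorized weighted least-squares scan with sandwich variances.

    Column-wise version of :func:`weighted_score_test`: returns
    (beta, sandwich_var, chisq) arrays over the columns of X, computed from
    weighted moments so one pass serves every variant.
    """
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("participation weights must be strictly positive")
    y = np.asarray(ytilde, float)
    Xf = np.asarray(X)
    dt = Xf.dtype
    X2 = Xf * Xf
    xwx = X2.T @ w.astype(dt)
    beta = (Xf.T @ (w * y).astype(dt)) / xwx
    # meat = sum w^2 x^2 (y - beta x)^2 expanded in powers of x
    w2 = (w * w).astype(dt)
    a = X2.T @ (w2 * (y * y).astype(dt))
    b = (X2 * Xf).T @ (w2 * y.astype(dt))
    c = (X2 * X2).T @ w2
    meat = a - 2.0 * beta * b + beta * beta * c
    var = np.maximum(meat, 0.0) / (xwx * xwx)
    with np.errstate(divide="ignore", invalid="ignore"):
        chisq = np.where(var > 0, beta * beta / var, np.nan)
    return np.asarray(beta, float), np.asarray(var, float), chisq


def weighted_score_test(x_test: np.ndarray, ytilde: np.ndarray, weights: np.ndarray):
    """Weighted least-squares effect with a Huber–White sandwich variance.

    beta = (x' W y) / (x' W x);   Var = (x'Wx)^-1 [sum w_i^2 x_i^2 r_i^2]
    (x'Wx)^-1 with r the weighted-fit residuals.  Returns
    (beta, robust_se, chisq).
    """
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("participation weights must be strictly positive")
    x = np.asarray(x_test, float)
    y = np.asarray(ytilde, float)
    xwx = float(np.sum(w * x * x))
    if xwx <= 0:
        raise ValueError("x' W x is zero")
    beta = float(np.sum(w * x * y)) / xwx
    r = y - beta * x
    meat = float(np.sum((w * x * r) ** 2))
    var = meat / (xwx * xwx)
    se = float(np.sqrt(var))
    return beta, se, beta * beta / var


# ---------------------------------------------------------------------------
# P-values
# ---------------------------------------------------------------------------


def chisq_to_log10p(chisq: np.ndarray) -> np.ndarray:
    """-log10 upper-tail chi^2_1 probabilities, computed in log space.

    Uses the normal-tail identity P(chi^2_1 > s) = 2 Phi(-sqrt(s)), whose
    log form stays finite far below the float64 underflow limit (1e-300).
    """
    chisq = np.asarray(chisq, float)
    with np.errstate(invalid="ignore"):
        logp = np.log(2.0) + stats.norm.logcdf(-np.sqrt(chisq))
        return -logp / np.log(10.0)
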