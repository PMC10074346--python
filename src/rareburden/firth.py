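"""Maximum-likelihood and Firth-penalized logistic regression.

Implements Newton-Raphson ML fitting with step-halving, Firth's Jeffreys-prior
penalized fits (finite estimates under separation), penalized/plain
likelihood-ratio tests, profile-penalized confidence intervals, and the
conditional burden test that switches from the ML LRT to the Firth LRT when
the ML p-value falls below 0.05.

All fitting routines accept optional non-negative frequency weights so that
aggregated (grouped binomial) data give results identical to the expanded
per-observation data; the 2x2 burden test exploits this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

GRAD_TOL = 1e-8
MAX_ITER = 50
MAX_HALVINGS = 25
P_FLOOR = 1e-300
# separation heuristic: a coefficient drifting past this on the logit scale
# with a still-improving likelihood is treated as diverging
BETA_DIVERGE = 30.0

__all__ = [
    "FitResult",
    "AssocResult",
    "fit_ml",
    "fit_firth",
    "lrt",
    "firth_lrt",
    "profile_ci_firth",
    "burden_test",
    "genomic_lambda",
]


@dataclass
class FitResult:
    """Outcome of one logistic fit."""

    beta: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    penalized: bool
    diverging: np.ndarray | None = None  # boolean mask of runaway coefficients


@dataclass
class AssocResult:
    """Burden-test output for one gene x model x variant-set cell."""

    gene: str = ""
    model: str = ""
    spec_id: str = ""
    n_case_mono: int = 0
    n_case_bi: int = 0
    n_ctrl_mono: int = 0
    n_ctrl_bi: int = 0
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    beta: float = np.nan
    method: str = ""
    skipped: bool = False
    reason: str = ""
    ci_method: str = "profile"
    extra: dict = field(default_factory=dict)


def _validate(y: np.ndarray, X: np.ndarray, weights: np.ndarray | None):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("y and X are misaligned")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative and aligned to y")
    live = w > 0
    if not (np.any((y > 0) & live) and np.any((y < 1) & live)):
        raise ValueError("outcome is constant: need at least one case and one control")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return y, X, w


def _loglik(y, X, w, beta):
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _pinfo(X, w, p):
    """Fisher information X' W X with W = diag(w p (1-p))."""
    wpq = w * p * (1.0 - p)
    return (X * wpq[:, None]).T @ X


def _penalized_loglik(y, X, w, beta):
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    sign, logdet = np.linalg.slogdet(_pinfo(X, w, p))
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_ml(y, X, weights=None) -> FitResult:
    """Plain maximum-likelihood logistic fit by Newton-Raphson.

    Uses step-halving on likelihood decreases; stops at gradient norm
    <= 1e-8 or 50 iterations.  Under complete/quasi-complete separation the
    likelihood has no interior maximum: the fit returns ``converged=False``
    with the runaway coefficients flagged in ``diverging``.
    """
    y, X, w = _validate(y, X, weights)
    beta = np.zeros(X.shape[1])
    ll = _loglik(y, X, w, beta)
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - p))
        if np.linalg.norm(grad) <= GRAD_TOL:
            diverging = np.abs(beta) > BETA_DIVERGE
            if diverging.any():
                # probabilities saturated: gradient vanished at a runaway
                # estimate, i.e. (quasi-)complete separation
                return FitResult(beta, ll, False, it - 1, penalized=False,
                                 diverging=diverging)
            return FitResult(beta, ll, True, it - 1, penalized=False)
        info = _pinfo(X, w, p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + step
            ll_new = _loglik(y, X, w, cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = cand, ll_new
    diverging = np.abs(beta) > BETA_DIVERGE
    return FitResult(beta, ll, False, it, penalized=False, diverging=diverging)


def fit_firth(y, X, weights=None, max_iter: int = MAX_ITER) -> FitResult:
    """Firth-penalized logistic fit (Jeffreys prior).

    Maximizes l(beta) + 0.5 log det I(beta) by modified-score Newton steps
    with hat-diagonal adjustment and step-halving on the penalized
    likelihood.  Estimates are finite even under complete separation; in the
    covariate-free 2x2 case the slope equals the log cross-product ratio of
    the table with 0.5 added to every cell.
    """
    y, X, w = _validate(y, X, weights)
    beta = np.zeros(X.shape[1])
    pll = _penalized_loglik(y, X, w, beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        info = _pinfo(X, w, p)
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise ValueError("information matrix is singular") from None
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        wpq = w * p * (1.0 - p)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * wpq
        score = X.T @ (w * (y - p) + h * (0.5 - p))
        if np.linalg.norm(score) <= GRAD_TOL:
            return FitResult(beta, pll, True, it - 1, penalized=True)
        step = info_inv @ score
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + step
            pll_new = _penalized_loglik(y, X, w, cand)
            if pll_new >= pll - 1e-12:
                break
            step = step / 2.0
        beta, pll = cand, pll_new
    # accept near-stationary points (the modified score can stall in the
    # last decimals when the information is poorly conditioned)
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = _pinfo(X, w, p)
    info_inv = np.linalg.inv(info)
    wpq = w * p * (1.0 - p)
    h = np.einsum("ij,jk,ik->i", X, info_inv, X) * wpq
    score = X.T @ (w * (y - p) + h * (0.5 - p))
    ok = bool(np.linalg.norm(score) <= 1e-5)
    return FitResult(beta, pll, ok, it, penalized=True)


def firth_lrt(y, X, j: int = 1, weights=None, fit: FitResult | None = None):
    """Penalized LRT of beta_j = 0 under the full design's Jeffreys penalty.

    The null value of the penalized likelihood is profiled: beta_j is fixed
    at 0 and the remaining coefficients are re-maximized, with the penalty
    still evaluated on the full design.  Fitting the reduced design with its
    own penalty instead would shift the statistic by the dimension-dependent
    log-determinant offset and break the null calibration.
    Returns ``(p, full_fit)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if fit is None:
        fit = fit_firth(y, X, weights=w)
    start = fit.beta.copy()
    start[j] = 0.0
    pll0 = _profile_pll(y, X, w, j, 0.0, start)
    stat = max(2.0 * (fit.loglik - pll0), 0.0)
    p = float(stats.chi2.sf(stat, 1))
    return min(max(p, P_FLOOR), 1.0), fit


def lrt(full: FitResult, null: FitResult, df: int = 1) -> float:
    """Likelihood-ratio p-value for nested fits of the same flavor."""
    if full.penalized != null.penalized:
        raise ValueError("cannot mix penalized and plain log-likelihoods in one LRT")
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < -1e-8:
        raise ValueError(f"negative LRT statistic ({stat:.3g}): convergence failure")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return min(max(p, P_FLOOR), 1.0)


def _profile_pll(y, X, w, j, value, beta_start):
    """Penalized log-likelihood profiled over all coefficients but column j.

    Fixes beta_j = value and maximizes over the remaining coefficients by
    modified-score Newton steps (the Jeffreys penalty is evaluated on the
    full design), with step-halving on the exact penalized likelihood.
    """
    free = [k for k in range(X.shape[1]) if k != j]
    beta = beta_start.astype(float).copy()
    beta[j] = value
    if not free:
        return _penalized_loglik(y, X, w, beta)
    pll = _penalized_loglik(y, X, w, beta)
    for _ in range(MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        info = _pinfo(X, w, p)
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        wpq = w * p * (1.0 - p)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * wpq
        resid = w * (y - p) + h * (0.5 - p)
        score_free = X[:, free].T @ resid
        if np.linalg.norm(score_free) <= 1e-6:
            break
        try:
            step = np.linalg.solve(info[np.ix_(free, free)], score_free)
        except np.linalg.LinAlgError:
            break
        cand = beta.copy()
        for _ in range(MAX_HALVINGS + 1):
            cand[free] = beta[free] + step
            pll_new = _penalized_loglik(y, X, w, cand)
            if pll_new >= pll - 1e-12:
                break
            step = step / 2.0
        if pll_new < pll + 1e-12 and np.allclose(cand[free], beta[free]):
            break
        beta, pll = cand, pll_new
    return pll


def profile_ci_firth(y, X, j: int = 1, level: float = 0.95, weights=None,
                     fit: FitResult | None = None):
    """Profile-penalized-likelihood CI for one coefficient of a Firth fit.

    Endpoints are where the profiled penalized log-likelihood drops by
    0.5 * chi2_1(level) from its maximum.  Falls back to a Wald interval
    (flagged via the third return element) if bracketing fails.
    Returns ``(low, high, method)`` on the log-odds scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if fit is None:
        fit = fit_firth(y, X, weights=w)
    if level <= 0:
        return float(fit.beta[j]), float(fit.beta[j]), "degenerate"
    target_drop = 0.5 * stats.chi2.ppf(level, 1)
    pll_max = fit.loglik
    bhat = float(fit.beta[j])

    def g(value):
        return _profile_pll(y, X, w, j, value, fit.beta) - (pll_max - target_drop)

    def _bracket(direction):
        step = 0.5
        lo = bhat
        for _ in range(60):
            hi = bhat + direction * step
            if g(hi) < 0:
                return (min(lo, hi), max(lo, hi))
            lo = hi
            step *= 1.6
        return None

    try:
        lo_br = _bracket(-1.0)
        hi_br = _bracket(+1.0)
        if lo_br is None or hi_br is None:
            raise RuntimeError("no bracket")
        low = brentq(g, *lo_br, xtol=1e-6)
        high = brentq(g, *hi_br, xtol=1e-6)
        return float(low), float(high), "profile"
    except Exception:
        # Wald fallback from the penalized information
        eta = X @ fit.beta
        p = 1.0 / (1.0 + np.exp(-eta))
        se = float(np.sqrt(np.linalg.inv(_pinfo(X, w, p))[j, j]))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return bhat - zq * se, bhat + zq * se, "wald"


def _design(score, covariates):
    score = np.asarray(score, dtype=float)
    n = score.shape[0]
    cols = [np.ones(n), score]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates are misaligned with the score vector")
        cols.extend(C[:, k] for k in range(C.shape[1]))
    return np.column_stack(cols)


def _drop_collinear_covariates(X):
    """Drop trailing covariate columns until the design has full rank.

    The intercept (col 0) and the genetic score (col 1) are always kept;
    constant or collinear covariates (e.g. a PC within a uniform stratum)
    are removed.  Returns the reduced design.
    """
    keep = list(range(X.shape[1]))
    while len(keep) > 2 and np.linalg.matrix_rank(X[:, keep]) < len(keep):
        # remove the covariate contributing least new rank, scanning from the end
        for j in range(len(keep) - 1, 1, -1):
            trial = keep[:j] + keep[j + 1:]
            if np.linalg.matrix_rank(X[:, trial]) == np.linalg.matrix_rank(X[:, keep]):
                keep = trial
                break
        else:
            break
    return X[:, keep]


def burden_test(score, status, covariates=None, min_carriers: int = 3,
                ci_level: float = 0.95, weights=None, compute_ci: bool = True,
                **meta) -> AssocResult:
    """Conditional-Firth burden test of a collapsed genetic score.

    Fits plain-ML full (intercept + score + covariates) and null models and
    computes the ML LRT p-value; when that p-value is below 0.05 both models
    are refitted under the Firth penalty and the Firth LRT p, Firth OR, and
    profile-penalized CI are reported instead (``method='Firth-LRT'``).
    Genes with fewer than ``min_carriers`` carriers are skipped.
    """
    score = np.asarray(score, dtype=float)
    status = np.asarray(status, dtype=float)
    res = AssocResult(**meta)
    w = np.ones_like(score) if weights is None else np.asarray(weights, dtype=float)
    n_carriers = float(np.sum(w[score != 0]))
    if n_carriers < min_carriers:
        res.skipped = True
        res.reason = f"carriers={n_carriers:g} < {min_carriers}"
        return res
    if np.std(score) == 0:
        res.skipped = True
        res.reason = "zero-variance score"
        return res
    X = _design(score, covariates)
    X = _drop_collinear_covariates(X)
    try:
        full_ml = fit_ml(status, X, weights=w)
        null_ml = fit_ml(status, X[:, [0] + list(range(2, X.shape[1]))], weights=w)
        p_ml = lrt(full_ml, null_ml)
    except ValueError as exc:
        res.skipped = True
        res.reason = f"ML fit failed: {exc}"
        return res

    if p_ml < 0.05:
        full_f = fit_firth(status, X, weights=w)
        res.p, _ = firth_lrt(status, X, j=1, weights=w, fit=full_f)
        res.beta = float(full_f.beta[1])
        res.method = "Firth-LRT"
        if compute_ci:
            lo, hi, ci_m = profile_ci_firth(status, X, j=1, level=ci_level,
                                            weights=w, fit=full_f)
            res.ci_low, res.ci_high, res.ci_method = np.exp(lo), np.exp(hi), ci_m
        else:
            res.ci_method = "none"
    else:
        res.p = p_ml
        res.beta = float(full_ml.beta[1])
        res.method = "ML-LRT"
        if compute_ci:
            # Wald CI on the ML fit (reported for completeness)
            eta = X @ full_ml.beta
            p = 1.0 / (1.0 + np.exp(-eta))
            try:
                se = float(np.sqrt(np.linalg.inv(_pinfo(X, w, p))[1, 1]))
                zq = stats.norm.ppf(0.5 + ci_level / 2.0)
                with np.errstate(over="ignore"):
                    res.ci_low = float(np.exp(full_ml.beta[1] - zq * se))
                    res.ci_high = float(np.exp(full_ml.beta[1] + zq * se))
                res.ci_method = "wald"
            except np.linalg.LinAlgError:
                res.ci_method = "none"
        else:
            res.ci_method = "none"
    res.odds_ratio = float(np.exp(res.beta))
    return res


def genomic_lambda(pvalues) -> float:
    """Genomic inflation factor: median chi2(1) quantile over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, 1))
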