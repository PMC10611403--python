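"""One-level feature-on-domain analyses on subject-mean panels.

Pairwise Pearson correlations between the two feature blocks, Lasso
regression of each feature on the opposite block with five-fold
cross-validation and the one-standard-error rule, and principal-component
regression of each gait feature on the leading PA components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .errors import ValidationError
from .panel import SubjectMeansMatrix

_STANDARDIZED_ATOL = 1e-6


def _assert_standardized(X: np.ndarray, names=None) -> None:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(np.abs(mu) > _STANDARDIZED_ATOL) or np.any(np.abs(sd - 1) > 1e-3):
        raise ValidationError(
            "predictors must be standardized (mean 0, sample sd 1); "
            f"max |mean| = {np.abs(mu).max():.3g}, max |sd-1| = {np.abs(sd - 1).max():.3g}"
        )


def flip_to_positive(vectors: np.ndarray) -> np.ndarray:
    """Sign convention: flip each column so its max-|.| entry is positive."""
    V = np.array(vectors, dtype=float, copy=True)
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return V


# ---------------------------------------------------------------------------
# Pearson correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Cross-block Pearson correlations with two-sided t-test p-values."""

    r_values: pd.DataFrame          # P x Q (PA rows, gait columns)
    p_values: pd.DataFrame
    alpha: float
    mask: pd.DataFrame              # True where p < alpha
    full_r: pd.DataFrame            # (P+Q) x (P+Q) within+cross matrix
    full_p: pd.DataFrame
    n: int


def _corr_and_p(values: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.corrcoef(values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    return r, p


def pearson_matrix(means: SubjectMeansMatrix, alpha: float = 0.1) -> CorrelationMatrix:
    """Product-moment correlations on subject means, masked at ``alpha``.

    p-values come from the exact t statistic r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom (two-sided), with no multiplicity correction.
    """
    n = means.n
    if n < 3:
        raise ValidationError(f"need at least 3 subjects for p-values, got {n}")
    names = list(means.pa_features) + list(means.gait_features)
    values = means.all_values()
    sds = values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [names[i] for i in np.nonzero(sds == 0)[0]]
        raise ValidationError(f"constant feature column(s): {bad}")
    r, p = _corr_and_p(values, n)
    full_r = pd.DataFrame(r, index=names, columns=names)
    full_p = pd.DataFrame(p, index=names, columns=names)
    cross_r = full_r.loc[means.pa_features, means.gait_features]
    cross_p = full_p.loc[means.pa_features, means.gait_features]
    return CorrelationMatrix(
        r_values=cross_r,
        p_values=cross_p,
        alpha=alpha,
        mask=cross_p < alpha,
        full_r=full_r,
        full_p=full_p,
        n=n,
    )


# ---------------------------------------------------------------------------
# Lasso with 5-fold CV and the one-standard-error rule
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    response_name: str
    predictor_names: list[str]
    lambda_grid: np.ndarray             # decreasing
    coef_path: np.ndarray               # n_lambda x n_predictors
    cv_mean_error: np.ndarray
    cv_se_error: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected_coefs: pd.Series           # nonzero coefficients at lambda_1se
    intercept: float
    coefs_1se: np.ndarray = field(default=None, repr=False)  # full vector


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100) -> np.ndarray:
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    if lam_max <= 0:
        raise ValidationError("response has no correlation with any predictor")
    return np.geomspace(lam_max, 1e-3 * lam_max, n_lambda)


def _solve_path(X, y, lambdas) -> np.ndarray:
    """Coordinate-descent Lasso path for objective (1/2n)||y-b0-Xb||^2 + lam*||b||_1."""
    yc = y - y.mean()
    _, coefs, _ = lasso_path(X, yc, alphas=lambdas, tol=1e-10, max_iter=200_000)
    return coefs.T  # n_lambda x p


def lasso_fit(
    y: np.ndarray,
    X: np.ndarray,
    predictor_names: list[str] | None = None,
    response_name: str = "y",
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
) -> LassoFit:
    """Lasso path + cross-validated one-standard-error model selection.

    Solves min (1/2n)||y - b0 - X b||^2 + lam ||b||_1 over a 100-point log
    grid from lam_max = max|X'(y-ybar)|/n down to 1e-3 lam_max.  Fold
    assignment shuffles the rows (the sampling units) with a fixed seed;
    lambda_1se is the largest lambda whose mean CV error is within one
    standard error of the minimum.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if predictor_names is None:
        predictor_names = [f"x{j + 1}" for j in range(p)]
    _assert_standardized(X, predictor_names)
    if n <= n_folds:
        raise ValidationError(f"need more rows ({n}) than folds ({n_folds})")

    lambdas = _lambda_grid(X, y, n_lambda)
    coef_path = _solve_path(X, y, lambdas)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_errors = np.empty((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(kf.split(X)):
        if len(va) < 2 or len(tr) < 2:
            raise ValidationError("a CV fold has fewer than 2 observations")
        ctr = _solve_path(X[tr], y[tr], lambdas)
        pred = X[va] @ ctr.T + y[tr].mean()
        fold_errors[f] = np.mean((y[va][:, None] - pred) ** 2, axis=0)
    cv_mean = fold_errors.mean(axis=0)
    cv_se = fold_errors.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    # grid is decreasing, so the first index satisfying the rule is the
    # largest qualifying lambda
    i_1se = int(np.nonzero(cv_mean <= threshold)[0][0])

    coefs_1se = coef_path[i_1se]
    nz = np.nonzero(coefs_1se)[0]
    selected = pd.Series(coefs_1se[nz], index=[predictor_names[j] for j in nz])
    return LassoFit(
        response_name=response_name,
        predictor_names=list(predictor_names),
        lambda_grid=lambdas,
        coef_path=coef_path,
        cv_mean_error=cv_mean,
        cv_se_error=cv_se,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        selected_coefs=selected,
        intercept=float(y.mean()),
        coefs_1se=coefs_1se,
    )


def solve_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Single-lambda solution of the same objective (for oracle checks)."""
    coefs = _solve_path(np.asarray(X, float), np.asarray(y, float).ravel(),
                        np.array([max(lam, 1e-15)]))
    return coefs[0]


def kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Max violation of the Lasso stationarity conditions at ``beta``.

    For inactive coordinates |x_j'(y - yhat)|/n must not exceed lam; for
    active ones the gradient must equal lam*sign(beta_j).
    """
    n = X.shape[0]
    resid = (y - y.mean()) - X @ beta
    g = X.T @ resid / n
    viol = 0.0
    for j in range(len(beta)):
        if beta[j] == 0:
            viol = max(viol, abs(g[j]) - lam)
        else:
            viol = max(viol, abs(g[j] - lam * np.sign(beta[j])))
    return viol


def lasso_panel(
    means: SubjectMeansMatrix,
    direction: str = "gait_on_PA",
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, LassoFit]]:
    """Lasso of every feature in one block on all features of the other.

    Returns a sparse coefficient table (responses as rows, predictors as
    columns, NaN where a predictor was not selected — written as blank) and
    the per-response fits.
    """
    if direction == "gait_on_PA":
        responses, predictors = means.gait_features, means.pa_features
        Ymat, Xmat = means.y(), means.x()
    elif direction == "PA_on_gait":
        responses, predictors = means.pa_features, means.gait_features
        Ymat, Xmat = means.x(), means.y()
    else:
        raise ValidationError(f"unknown direction {direction!r}")

    table = pd.DataFrame(np.nan, index=responses, columns=predictors)
    fits: dict[str, LassoFit] = {}
    for i, resp in enumerate(responses):
        fit = lasso_fit(
            Ymat[:, i], Xmat, predictor_names=list(predictors),
            response_name=resp, n_folds=n_folds, seed=seed,
        )
        fits[resp] = fit
        for name, val in fit.selected_coefs.items():
            table.loc[resp, name] = val
    return table, fits


# ---------------------------------------------------------------------------
# principal-component regression
# ---------------------------------------------------------------------------

@dataclass
class PCRFit:
    pc_loadings: pd.DataFrame        # P x k, orthonormal columns
    pc_explained: np.ndarray         # full-length variance fractions
    k: int
    k_elbow: int                     # alternative selection, logged alongside
    coefficients: pd.DataFrame       # Q x k
    p_values: pd.DataFrame           # Q x k
    mask: pd.DataFrame               # True where p < p_alpha
    scores: np.ndarray               # n x k PC scores
    p_alpha: float


def pcr_fit(
    means: SubjectMeansMatrix,
    k: int | str = "auto",
    p_alpha: float = 0.05,
    var_threshold: float = 0.90,
) -> PCRFit:
    """PCA of the scaled PA block, then OLS of each gait feature on the scores.

    k="auto" keeps the smallest k whose cumulative explained variance reaches
    ``var_threshold``; the scree-elbow alternative (maximum second difference
    of the explained fractions) is computed and reported side by side.
    Coefficient p-values use the t distribution with n-k-1 df.
    """
    X = means.x()
    Y = means.y()
    n, P = X.shape
    _assert_standardized(X, means.pa_features)

    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    explained = s**2 / np.sum(s**2)
    cum = np.cumsum(explained)

    k_var = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    if len(explained) >= 3:
        second_diff = np.diff(explained, 2)
        k_elbow = int(np.argmax(second_diff) + 1)
    else:
        k_elbow = 1
    if k == "auto":
        k_use = k_var
    else:
        k_use = int(k)
        if k_use > min(n - 1, P) or k_use < 1:
            raise ValidationError(f"k={k_use} outside [1, min(n-1, P)={min(n - 1, P)}]")

    V = flip_to_positive(Vt.T[:, :k_use])
    T = Xc @ V  # n x k scores, orthogonal columns
    dof = n - k_use - 1
    if dof < 1:
        raise ValidationError("not enough subjects for the requested k")

    coefs = np.empty((Y.shape[1], k_use))
    pvals = np.empty_like(coefs)
    tt2 = np.sum(T**2, axis=0)
    for q in range(Y.shape[1]):
        yq = Y[:, q] - Y[:, q].mean()
        beta = (T.T @ yq) / tt2
        resid = yq - T @ beta
        sigma2 = np.sum(resid**2) / dof
        se = np.sqrt(sigma2 / tt2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf)
        coefs[q] = beta
        pvals[q] = 2 * stats.t.sf(np.abs(tstat), df=dof)

    pc_names = [f"PC{j + 1}" for j in range(k_use)]
    return PCRFit(
        pc_loadings=pd.DataFrame(V, index=means.pa_features, columns=pc_names),
        pc_explained=explained,
        k=k_use,
        k_elbow=k_elbow,
        coefficients=pd.DataFrame(coefs, index=means.gait_features, columns=pc_names),
        p_values=pd.DataFrame(pvals, index=means.gait_features, columns=pc_names),
        mask=pd.DataFrame(pvals < p_alpha, index=means.gait_features, columns=pc_names),
        scores=T,
        p_alpha=p_alpha,
    )
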