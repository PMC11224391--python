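"""Covariate-adjusted genetic association estimation.

Every Mendelian randomization estimate in the package is a ratio of two
regressions fitted here: a linear model of the exposure on the allelic score
and a logistic model of the binary outcome on the score, each adjusted for a
named covariate set.

Covariate-set vocabulary (fixed labels used throughout configuration):

- ``linear_default``      — age, sex, centre indicators, pc1..pc10
- ``nonlinear_expanded``  — linear_default plus age^2, age*sex, age^2*sex
  (age mean-centred in the quadratic/interaction terms for conditioning)
- ``negative_control``    — centre indicators and pc1..pc10 only
- ``none``                — intercept only
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import EstimationError, InputError

COVARIATE_SETS = ("none", "linear_default", "nonlinear_expanded", "negative_control")

__all__ = [
    "GeneticAssociation",
    "COVARIATE_SETS",
    "build_covariates",
    "fit_linear_assoc",
    "fit_logistic_assoc",
]


@dataclass(frozen=True)
class GeneticAssociation:
    """Coefficient of the score from one adjusted regression.

    ``beta`` is in outcome units per unit score: log-odds for logistic
    models, outcome units for linear models.
    """

    beta: float
    se: float
    n: int
    model: str  # "linear" | "logistic"
    covariate_set: str = "custom"
    p: float | None = None

    def __post_init__(self):
        if not (self.se > 0):
            raise EstimationError(f"standard error must be positive (got {self.se})")


def build_covariates(cohort: pd.DataFrame, covariate_set: str) -> pd.DataFrame | None:
    """Materialize a named covariate set as a numeric design block."""
    if covariate_set == "none":
        return None
    if covariate_set not in COVARIATE_SETS:
        raise InputError(f"unknown covariate set {covariate_set!r}; expected one of {COVARIATE_SETS}")
    pcs = [f"pc{j}" for j in range(1, 11)]
    centre = pd.get_dummies(cohort["centre"], prefix="centre", drop_first=True, dtype=float)
    if covariate_set == "negative_control":
        return pd.concat([centre, cohort[pcs].astype(float)], axis=1)
    base = pd.concat(
        [cohort[["age", "sex"]].astype(float), centre, cohort[pcs].astype(float)], axis=1
    )
    if covariate_set == "linear_default":
        return base
    # nonlinear_expanded: quadratic age and age-sex interactions, age centred
    age_c = cohort["age"].astype(float) - cohort["age"].mean()
    sex = cohort["sex"].astype(float)
    extra = pd.DataFrame(
        {"age_sq": age_c**2, "age_sex": age_c * sex, "age_sq_sex": age_c**2 * sex},
        index=cohort.index,
    )
    return pd.concat([base, extra], axis=1)


def _design_matrix(x: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    n = len(x)
    cols = ["const", "score"]
    blocks = [np.ones((n, 1)), np.asarray(x, float).reshape(n, 1)]
    if covariates is not None and covariates.shape[1] > 0:
        blocks.append(covariates.to_numpy(float))
        cols += list(covariates.columns)
    return np.hstack(blocks), cols


def _check_rank(X: np.ndarray, cols: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the redundant columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        redundant = sorted(cols[j] for j in piv[rank:])
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {redundant}")


def fit_linear_assoc(
    y: np.ndarray, x: np.ndarray, covariates: pd.DataFrame | None = None,
    covariate_set: str = "custom",
) -> GeneticAssociation:
    """OLS coefficient and SE of the score in a covariate-adjusted model."""
    y = np.asarray(y, float)
    X, cols = _design_matrix(x, covariates)
    if len(y) <= X.shape[1]:
        raise InputError("n must exceed the number of model parameters")
    _check_rank(X, cols)
    fit = sm.OLS(y, X).fit()
    return GeneticAssociation(
        beta=float(fit.params[1]),
        se=float(max(fit.bse[1], 1e-300)),
        n=len(y),
        model="linear",
        covariate_set=covariate_set,
        p=float(fit.pvalues[1]),
    )


def fit_logistic_assoc(
    y: np.ndarray, x: np.ndarray, covariates: pd.DataFrame | None = None,
    covariate_set: str = "custom", firth: bool = False,
) -> GeneticAssociation:
    """Maximum-likelihood log-odds coefficient and SE of the score.

    ``firth=True`` switches to Jeffreys-prior penalized likelihood, which
    remains finite under separation — useful for rare outcomes inside small
    strata.  The default is plain ML; separation or non-convergence raises
    with a hint to enable the fallback.
    """
    y = np.asarray(y, float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise InputError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise InputError("outcome has a single class; association is undefined")
    X, cols = _design_matrix(x, covariates)
    if len(y) <= X.shape[1]:
        raise InputError("n must exceed the number of model parameters")
    _check_rank(X, cols)
    if firth:
        beta, se = _firth_logistic(X, y)
        b, s = float(beta[1]), float(se[1])
    else:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
            except Exception as exc:  # PerfectSeparationError and kin
                raise EstimationError(
                    f"logistic fit failed ({exc}); consider firth=True"
                ) from exc
        if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
            raise EstimationError(
                "logistic fit did not converge (possible separation); consider firth=True"
            )
        b, s = float(fit.params[1]), float(fit.bse[1])
    from scipy.stats import norm

    return GeneticAssociation(
        beta=b, se=s, n=len(y), model="logistic", covariate_set=covariate_set,
        p=float(2.0 * norm.sf(abs(b) / s)),
    )


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Jeffreys-prior penalized logistic regression (bias-reduced IRLS)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtWX = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("Firth information matrix singular") from exc
        # hat diagonal h_i = w_i * x_i' (X'WX)^-1 x_i
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise EstimationError("Firth logistic did not converge")
    se = np.sqrt(np.diag(info_inv))
    return beta, se
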