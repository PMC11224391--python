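"""Whole-population ratio-method MR estimates and power calculation.

The ratio (Wald) estimate divides the genetic association with the outcome
by the genetic association with the exposure and rescales to a 10 nmol/L
difference in genetically-predicted exposure:

    beta_MR = scale * beta_GY / beta_GX,   se_MR = scale * se_GY / |beta_GX|

using the first-order delta method (uncertainty in beta_GX is ignored; with
instrument F statistics in the hundreds the second-order term is
negligible, but it is available behind a flag).  Confidence intervals and
p-values use the normal reference, appropriate at biobank sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .assoc import GeneticAssociation, build_covariates, fit_linear_assoc, fit_logistic_assoc
from .exceptions import ConfigurationError, InputError, WeakInstrumentError
from .scores import ScoreSpec, build_score

__all__ = [
    "RatioEstimate",
    "PowerInput",
    "ratio_estimate",
    "mr_power",
    "run_linear_analysis",
    "LinearMR",
]


@dataclass(frozen=True)
class RatioEstimate:
    """Causal log-OR per ``scale`` nmol/L genetically-predicted exposure."""

    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    outcome: str = ""

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome, "n": self.n, "beta": self.beta, "se": self.se,
            "or": self.or_point, "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        }


@dataclass(frozen=True)
class PowerInput:
    """Inputs for the analytic power approximation (binary outcome MR)."""

    n: int
    r2: float
    case_fraction: float
    or_per_10: float
    exposure_sd: float = 19.3
    alpha: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.r2 < 1.0):
            raise ConfigurationError("r2 must lie in (0, 1)")
        if not (0.0 < self.case_fraction < 1.0):
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if self.or_per_10 <= 0:
            raise ConfigurationError("or_per_10 must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")


def ratio_estimate(
    assoc_gy: GeneticAssociation,
    assoc_gx: GeneticAssociation,
    scale: float = 10.0,
    alpha: float = 0.05,
    outcome: str = "",
    second_order: bool = False,
) -> RatioEstimate:
    """Form the ratio-method estimate from the two genetic associations.

    ``second_order=True`` adds the delta-method term for uncertainty in the
    exposure association:
    se^2 = scale^2 * (se_GY^2 / b_GX^2 + b_GY^2 * se_GX^2 / b_GX^4).
    """
    if abs(assoc_gx.beta) < 2.0 * assoc_gx.se:
        raise WeakInstrumentError(
            "genetic association with the exposure is within 2 SE of zero; "
            "a ratio estimate would be unreliable"
        )
    beta = scale * assoc_gy.beta / assoc_gx.beta
    se = scale * assoc_gy.se / abs(assoc_gx.beta)
    if second_order:
        var = (scale**2) * (
            assoc_gy.se**2 / assoc_gx.beta**2
            + assoc_gy.beta**2 * assoc_gx.se**2 / assoc_gx.beta**4
        )
        se = float(np.sqrt(var))
    z = norm.ppf(1.0 - alpha / 2.0)
    return RatioEstimate(
        beta=float(beta),
        se=float(se),
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(2.0 * norm.sf(abs(beta) / se)),
        n=assoc_gy.n,
        outcome=outcome,
    )


def mr_power(power_input: PowerInput) -> float:
    """Analytic power of the binary-outcome MR test.

    Converts the odds ratio per 10 nmol/L to a log-OR per SD of exposure,
    b_sd = ln(OR) * sd / 10, approximates the SE of the MR log-OR as
    1 / sqrt(n * r2 * K * (1-K)), and returns
    Phi(|b_sd| / se - z_(1-alpha/2)).
    """
    pi = power_input
    b_sd = np.log(pi.or_per_10) * pi.exposure_sd / 10.0
    se = 1.0 / np.sqrt(pi.n * pi.r2 * pi.case_fraction * (1.0 - pi.case_fraction))
    z = norm.ppf(1.0 - pi.alpha / 2.0)
    return float(norm.cdf(abs(b_sd) / se - z))


def run_linear_analysis(
    cohort: pd.DataFrame,
    spec: ScoreSpec,
    outcomes: list[str],
    covariate_set: str = "linear_default",
    exposure_col: str = "exposure_adj",
    scale: float = 10.0,
    alpha: float = 0.05,
    firth: bool = False,
) -> pd.DataFrame:
    """Whole-population ratio estimates, one row per outcome."""
    est = LinearMR(
        score_spec=spec, outcomes=outcomes, covariate_set=covariate_set,
        exposure_col=exposure_col, scale=scale, alpha=alpha, firth=firth,
    ).fit(cohort)
    return est.estimates_


class LinearMR(BaseEstimator):
    """Whole-population ratio-method MR as a fit-style estimator.

    After ``fit(cohort)``: ``estimates_`` is a DataFrame with one row per
    outcome (columns outcome, n, beta, se, or, ci_low, ci_high, p) and
    ``exposure_assoc_`` holds the shared genetic association with the
    exposure.
    """

    def __init__(
        self,
        score_spec: ScoreSpec = None,
        outcomes: list[str] = None,
        covariate_set: str = "linear_default",
        exposure_col: str = "exposure_adj",
        scale: float = 10.0,
        alpha: float = 0.05,
        firth: bool = False,
    ):
        self.score_spec = score_spec
        self.outcomes = outcomes
        self.covariate_set = covariate_set
        self.exposure_col = exposure_col
        self.scale = scale
        self.alpha = alpha
        self.firth = firth

    def fit(self, cohort: pd.DataFrame, y=None):
        if self.score_spec is None or not self.outcomes:
            raise ConfigurationError("score_spec and outcomes are required")
        missing = [o for o in self.outcomes if o not in cohort.columns]
        if missing:
            raise InputError(f"outcome columns missing from cohort: {missing}")
        score = build_score(cohort, self.score_spec).to_numpy()
        cov = build_covariates(cohort, self.covariate_set)
        x = cohort[self.exposure_col].to_numpy(float)
        self.exposure_assoc_ = fit_linear_assoc(
            x, score, cov, covariate_set=self.covariate_set
        )
        rows = []
        for outcome in self.outcomes:
            yv = cohort[outcome].to_numpy(float)
            gy = fit_logistic_assoc(
                yv, score, cov, covariate_set=self.covariate_set, firth=self.firth
            )
            est = ratio_estimate(
                gy, self.exposure_assoc_, scale=self.scale, alpha=self.alpha, outcome=outcome
            )
            rows.append(est.as_dict())
        self.estimates_ = pd.DataFrame(rows)
        return self
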