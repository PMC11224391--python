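"""Stratum-specific MR, bootstrap averaging with Rubin's rules, diagnostics.

Within each exposure stratum the ratio estimate is refit exactly as in the
whole-population analysis (with an expanded covariate set adding age^2,
age*sex and age^2*sex).  Because stratum boundaries sit on rank ties, the
stratum estimates can be unstable to the inclusion of a handful of
individuals; to stabilize them, a small number of participants (default 12)
is removed at random, the doubly-ranked stratification and estimation are
repeated (default 100 replicates), and replicate estimates are combined on
the log-OR scale with Rubin's rules:

    point       = mean(points)
    within_var  = mean(variances)
    between_var = sample variance of points (divisor B-1)
    total_var   = within_var + (1 + 1/B) * between_var

Negative-control analyses estimate the stratum-specific association of the
score with age (linear) and sex (logistic) — traits the exposure cannot
cause — scaled to 10 nmol/L genetically-predicted exposure.  Non-null
results flag instrument invalidity or selection bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .assoc import build_covariates, fit_linear_assoc, fit_logistic_assoc
from .exceptions import ConfigurationError, EstimationError, InputError
from .linear import RatioEstimate, ratio_estimate
from .scores import ScoreSpec, build_score
from .strata import StratumAssignment, doubly_ranked_strata, stratum_summaries

__all__ = [
    "BootstrapSettings",
    "CombinedStratumResult",
    "stratum_estimates",
    "rubin_combine",
    "bootstrap_average",
    "negative_control",
    "bonferroni_threshold",
    "NonlinearMR",
]


@dataclass(frozen=True)
class BootstrapSettings:
    """Replication settings for bootstrap-averaged stratification."""

    n_reps: int = 100
    n_remove: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.n_remove < 0:
            raise ConfigurationError("n_remove must be >= 0")


@dataclass(frozen=True)
class CombinedStratumResult:
    """Rubin's-rules combination of replicate stratum estimates."""

    stratum: int
    point: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    n_replicates: int

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum, "point": self.point, "se": self.se,
            "within_var": self.within_var, "between_var": self.between_var,
            "total_var": self.total_var, "or": self.or_point,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
            "n_replicates": self.n_replicates,
        }


def stratum_estimates(
    cohort: pd.DataFrame,
    assignment: StratumAssignment,
    spec: ScoreSpec,
    outcome: str,
    covariate_set: str = "nonlinear_expanded",
    exposure_col: str = "exposure_adj",
    scale: float = 10.0,
    alpha: float = 0.05,
    firth: bool = False,
) -> list[RatioEstimate | None]:
    """Ratio estimate refit within each stratum (None where estimation fails).

    A stratum whose outcome column is single-class (possible for rare
    outcomes in small cohorts) is flagged with a warning and its entry is
    None rather than aborting the whole analysis.
    """
    if len(assignment.labels) != len(cohort):
        raise InputError("assignment and cohort are not aligned")
    score = build_score(cohort, spec).to_numpy()
    out: list[RatioEstimate | None] = []
    for s in range(1, assignment.n_strata + 1):
        mask = assignment.labels == s
        sub = cohort.loc[mask]
        cov = build_covariates(sub.reset_index(drop=True), covariate_set)
        try:
            gx = fit_linear_assoc(
                sub[exposure_col].to_numpy(float), score[mask], cov, covariate_set=covariate_set
            )
            gy = fit_logistic_assoc(
                sub[outcome].to_numpy(float), score[mask], cov,
                covariate_set=covariate_set, firth=firth,
            )
            out.append(ratio_estimate(gy, gx, scale=scale, alpha=alpha, outcome=outcome))
        except (InputError, EstimationError) as exc:
            warnings.warn(f"stratum {s} estimate omitted: {exc}", stacklevel=2)
            out.append(None)
    return out


def rubin_combine(
    points, variances, stratum: int = 0, alpha: float = 0.05
) -> CombinedStratumResult:
    """Combine replicate (point, variance) pairs with Rubin's rules."""
    points = np.asarray(points, float)
    variances = np.asarray(variances, float)
    if len(points) != len(variances):
        raise InputError("points and variances must have equal length")
    B = len(points)
    if B < 2:
        raise InputError("Rubin's rules require at least 2 replicates")
    point = float(points.mean())
    within = float(variances.mean())
    between = float(points.var(ddof=1))
    total = within + (1.0 + 1.0 / B) * between
    se = float(np.sqrt(total))
    z = norm.ppf(1.0 - alpha / 2.0)
    return CombinedStratumResult(
        stratum=stratum, point=point, within_var=within, between_var=between,
        total_var=total, se=se, or_point=float(np.exp(point)),
        ci_low=float(np.exp(point - z * se)), ci_high=float(np.exp(point + z * se)),
        p=float(2.0 * norm.sf(abs(point) / se)), n_replicates=B,
    )


def bootstrap_average(
    cohort: pd.DataFrame,
    spec: ScoreSpec,
    outcome: str,
    n_strata: int = 5,
    pre_stratum_size: int = 50,
    settings: BootstrapSettings = BootstrapSettings(),
    covariate_set: str = "nonlinear_expanded",
    exposure_col: str = "exposure_adj",
    scale: float = 10.0,
    alpha: float = 0.05,
    firth: bool = False,
) -> list[CombinedStratumResult]:
    """Bootstrap-averaged doubly-ranked stratum estimates.

    Each replicate removes ``settings.n_remove`` participants uniformly at
    random without replacement (fresh seeded substream per replicate),
    re-runs the doubly-ranked stratification and the stratum estimation, and
    the replicate log-ORs are combined per stratum with Rubin's rules.
    Strata are matched across replicates by index (stratum 1 = lowest
    exposure).  Replicates where a stratum failed are recorded as missing
    for that stratum; combination runs over the available replicates and
    reports their count.
    """
    n = len(cohort)
    if settings.n_remove >= n:
        raise ConfigurationError("n_remove must be smaller than the cohort")
    B = settings.n_reps
    pts = np.full((B, n_strata), np.nan)
    vrs = np.full((B, n_strata), np.nan)
    for b in range(B):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(settings.seed), spawn_key=(8, b))
        )
        if settings.n_remove > 0:
            drop = rng.choice(n, size=settings.n_remove, replace=False)
            keep = np.setdiff1d(np.arange(n), drop)
            sub = cohort.iloc[keep].reset_index(drop=True)
        else:
            sub = cohort.reset_index(drop=True)
        assignment = doubly_ranked_strata(
            build_score(sub, spec).to_numpy(),
            sub[exposure_col].to_numpy(float),
            n_strata=n_strata,
            pre_stratum_size=pre_stratum_size,
            seed=int(settings.seed),
        )
        ests = stratum_estimates(
            sub, assignment, spec, outcome, covariate_set=covariate_set,
            exposure_col=exposure_col, scale=scale, alpha=alpha, firth=firth,
        )
        for s, est in enumerate(ests):
            if est is not None:
                pts[b, s] = est.beta
                vrs[b, s] = est.se**2
    results = []
    for s in range(n_strata):
        ok = ~np.isnan(pts[:, s])
        if ok.sum() < 2:
            raise EstimationError(
                f"stratum {s + 1}: fewer than 2 successful replicates; cannot combine"
            )
        results.append(
            rubin_combine(pts[ok, s], vrs[ok, s], stratum=s + 1, alpha=alpha)
        )
    return results


def negative_control(
    cohort: pd.DataFrame,
    spec: ScoreSpec,
    n_strata: int = 5,
    pre_stratum_size: int = 50,
    control: str = "age",
    seed: int = 0,
    exposure_col: str = "exposure_adj",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stratum-specific score association with a negative-control trait.

    The exposure cannot causally affect age or sex, so any non-null
    stratum-specific association signals instrument invalidity or selection
    into the sample.  Estimates are scaled to 10 nmol/L genetically-predicted
    exposure via the stratum exposure association; adjustment is for centre
    and principal components only.  For age the estimate is in years (null
    value 0); for sex it is a log-OR (null OR 1).
    """
    if control not in ("age", "sex"):
        raise InputError("control must be 'age' or 'sex'")
    if control not in cohort.columns:
        raise InputError(f"control column {control!r} absent from cohort")
    score = build_score(cohort, spec).to_numpy()
    assignment = doubly_ranked_strata(
        score, cohort[exposure_col].to_numpy(float),
        n_strata=n_strata, pre_stratum_size=pre_stratum_size, seed=seed,
    )
    z = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for s in range(1, n_strata + 1):
        mask = assignment.labels == s
        sub = cohort.loc[mask].reset_index(drop=True)
        ctrl = sub[control].to_numpy(float)
        if np.ptp(ctrl) == 0:
            raise EstimationError(f"control {control!r} is constant in stratum {s}")
        cov = build_covariates(sub, "negative_control")
        gx = fit_linear_assoc(
            sub[exposure_col].to_numpy(float), score[mask], cov, covariate_set="negative_control"
        )
        if control == "age":
            gc = fit_linear_assoc(ctrl, score[mask], cov, covariate_set="negative_control")
        else:
            gc = fit_logistic_assoc(ctrl, score[mask], cov, covariate_set="negative_control")
        if abs(gx.beta) < 2.0 * gx.se:
            raise EstimationError(f"weak stratum-{s} exposure association; cannot scale")
        est = 10.0 * gc.beta / gx.beta
        se = 10.0 * gc.se / abs(gx.beta)
        rows.append(
            {
                "stratum": s, "control": control, "estimate": est, "se": se,
                "ci_low": est - z * se, "ci_high": est + z * se,
                "p": float(2.0 * norm.sf(abs(est) / se)), "n": int(mask.sum()),
                "mean_exposure": float(sub[exposure_col].mean()),
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, n_outcomes: int, n_strata: int) -> float:
    """Multiplicity-corrected significance threshold alpha / outcomes / strata."""
    if alpha <= 0 or n_outcomes < 1 or n_strata < 1:
        raise ConfigurationError("alpha must be positive and counts >= 1")
    return alpha / n_outcomes / n_strata


class NonlinearMR(BaseEstimator):
    """Bootstrap-averaged doubly-ranked stratified MR as a fit-style estimator.

    After ``fit(cohort)``: ``results_`` is a DataFrame of combined stratum
    estimates (one row per outcome x stratum) and ``summaries_`` the
    per-stratum sizes and mean exposures from the full-cohort
    stratification.
    """

    def __init__(
        self,
        score_spec: ScoreSpec = None,
        outcomes: list[str] = None,
        n_strata: int = 5,
        pre_stratum_size: int = 50,
        n_reps: int = 100,
        n_remove: int = 12,
        random_state: int = 0,
        covariate_set: str = "nonlinear_expanded",
        exposure_col: str = "exposure_adj",
        alpha: float = 0.05,
        firth: bool = False,
    ):
        self.score_spec = score_spec
        self.outcomes = outcomes
        self.n_strata = n_strata
        self.pre_stratum_size = pre_stratum_size
        self.n_reps = n_reps
        self.n_remove = n_remove
        self.random_state = random_state
        self.covariate_set = covariate_set
        self.exposure_col = exposure_col
        self.alpha = alpha
        self.firth = firth

    def fit(self, cohort: pd.DataFrame, y=None):
        if self.score_spec is None or not self.outcomes:
            raise ConfigurationError("score_spec and outcomes are required")
        settings = BootstrapSettings(
            n_reps=self.n_reps, n_remove=self.n_remove, seed=self.random_state
        )
        score = build_score(cohort, self.score_spec).to_numpy()
        assignment = doubly_ranked_strata(
            score, cohort[self.exposure_col].to_numpy(float),
            n_strata=self.n_strata, pre_stratum_size=self.pre_stratum_size,
            seed=self.random_state,
        )
        self.summaries_ = stratum_summaries(
            assignment, cohort[self.exposure_col].to_numpy(float)
        )
        rows = []
        for outcome in self.outcomes:
            combined = bootstrap_average(
                cohort, self.score_spec, outcome,
                n_strata=self.n_strata, pre_stratum_size=self.pre_stratum_size,
                settings=settings, covariate_set=self.covariate_set,
                exposure_col=self.exposure_col, alpha=self.alpha, firth=self.firth,
            )
            for res in combined:
                row = {"outcome": outcome, **res.as_dict()}
                row["mean_exposure"] = float(
                    self.summaries_.loc[
                        self.summaries_["stratum"] == res.stratum, "mean_exposure"
                    ].iloc[0]
                )
                rows.append(row)
        self.results_ = pd.DataFrame(rows)
        return self
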