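"""Allelic score construction: stepwise variant selection, weighting, strength.

An allelic score is a weighted sum of effect-allele dosages used as a single
genetic instrument.  Instrument variants are chosen per gene region by
forward stepwise regression of the exposure on candidate variants (plus the
analysis covariates): at each step the candidate with the smallest
conditional p-value enters if it falls below ``p_enter``; weights are the
conditional coefficients of the final joint model.  This admits moderately
correlated variants so long as each predicts independent variation in the
exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, EstimationError, InputError

__all__ = [
    "ScoreSpec",
    "InstrumentStrength",
    "StepwiseScoreSelector",
    "stepwise_select",
    "build_score",
    "instrument_strength",
]


@dataclass(frozen=True)
class ScoreSpec:
    """Variant ids and weights defining one allelic score."""

    name: str
    variant_ids: list[str]
    weights: np.ndarray
    provenance: str = "file"

    def __post_init__(self):
        ids = list(self.variant_ids)
        w = np.asarray(self.weights, float)
        if len(ids) != len(set(ids)):
            raise ConfigurationError("score variant_ids must be unique")
        if len(ids) != len(w):
            raise ConfigurationError("weights must align one-to-one with variant_ids")
        object.__setattr__(self, "variant_ids", ids)
        object.__setattr__(self, "weights", w)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"variant_id": self.variant_ids, "weight": self.weights}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, name: str = "custom") -> "ScoreSpec":
        tab = pd.read_csv(path, sep="\t")
        return cls(
            name=name,
            variant_ids=tab["variant_id"].tolist(),
            weights=tab["weight"].to_numpy(float),
            provenance="file",
        )


@dataclass(frozen=True)
class InstrumentStrength:
    """Incremental variance explained and partial F for the score (1 df)."""

    r2: float
    f_stat: float
    n: int
    k: int = 1


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    X = np.column_stack([np.ones(n), covariates.to_numpy(float)])
    return X


def stepwise_select(
    dosages: pd.DataFrame,
    exposure: np.ndarray,
    candidate_ids: list[str] | None = None,
    p_enter: float = 1e-6,
    covariates: pd.DataFrame | None = None,
) -> tuple[list[str], np.ndarray]:
    """Forward stepwise selection within one candidate pool (one gene region).

    Returns the selected variant ids (in entry order) and their conditional
    weights from the final joint model.  Candidates are scanned in
    lexicographic order, so p-value ties resolve deterministically.
    Perfectly collinear candidates are skipped with a warning.
    """
    if not (0.0 < p_enter < 1.0):
        raise ConfigurationError("p_enter must lie in (0, 1)")
    if candidate_ids is None:
        candidate_ids = list(dosages.columns)
    missing = [v for v in candidate_ids if v not in dosages.columns]
    if missing:
        raise InputError(f"candidate variants absent from dosage table: {missing}")
    y = np.asarray(exposure, float)
    n = len(y)
    base = _design(covariates, n)
    remaining = sorted(candidate_ids)
    selected: list[str] = []

    while remaining:
        best = None  # (pvalue, id, coef)
        sel_mat = dosages[selected].to_numpy(float) if selected else np.empty((n, 0))
        current = np.column_stack([base, sel_mat])
        for vid in remaining:
            cand = dosages[vid].to_numpy(float)
            # skip candidates with no independent variation given current design
            resid = cand - current @ np.linalg.lstsq(current, cand, rcond=None)[0]
            if np.var(resid) < 1e-10 * max(np.var(cand), 1e-30):
                warnings.warn(
                    f"variant {vid} is collinear with the current model; skipped",
                    stacklevel=2,
                )
                remaining = [v for v in remaining if v != vid]
                continue
            X = np.column_stack([current, cand])
            fit = sm.OLS(y, X).fit()
            pv = fit.pvalues[-1]
            if best is None or pv < best[0]:
                best = (pv, vid)
        if best is None or best[0] >= p_enter:
            break
        selected.append(best[1])
        remaining = [v for v in remaining if v != best[1]]

    if not selected:
        return [], np.array([])
    X = np.column_stack([base, dosages[selected].to_numpy(float)])
    fit = sm.OLS(y, X).fit()
    weights = fit.params[-len(selected):]
    return selected, np.asarray(weights, float)


class StepwiseScoreSelector(BaseEstimator):
    """Stepwise instrument selection as a fit/transform estimator.

    ``fit(X, y, regions=...)`` runs forward selection separately within each
    gene region (pooling all candidates when ``regions`` is None) and stores
    the resulting :class:`ScoreSpec`; ``transform(X)`` returns the weighted
    allelic score.

    Parameters
    ----------
    p_enter : float
        Conditional p-value below which a candidate enters the model.
        The stringent default mimics conditional genome-wide practice.
    """

    def __init__(self, p_enter: float = 1e-6):
        self.p_enter = p_enter

    def fit(self, X: pd.DataFrame, y, regions=None, covariates: pd.DataFrame | None = None):
        if regions is None:
            pools = {"all": list(X.columns)}
        else:
            region_of = regions if isinstance(regions, dict) else dict(zip(X.columns, list(regions)))
            pools = {}
            for vid in X.columns:
                pools.setdefault(region_of[vid], []).append(vid)
        selected_ids: list[str] = []
        weights: list[float] = []
        self.per_region_ = {}
        for region in sorted(pools):
            ids, w = stepwise_select(
                X, y, candidate_ids=pools[region], p_enter=self.p_enter, covariates=covariates
            )
            self.per_region_[region] = (ids, w)
            selected_ids.extend(ids)
            weights.extend(w)
        self.variant_ids_ = selected_ids
        self.weights_ = np.asarray(weights, float)
        self.score_spec_ = ScoreSpec(
            name="focused",
            variant_ids=selected_ids,
            weights=self.weights_,
            provenance="stepwise_selected",
        )
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return build_score(X, self.score_spec_).to_numpy()


def build_score(dosages: pd.DataFrame, spec: ScoreSpec) -> pd.Series:
    """score_i = sum_v dosage_iv * weight_v (nmol/L-equivalent units)."""
    missing = [v for v in spec.variant_ids if v not in dosages.columns]
    if missing:
        raise InputError(f"score variants missing from dosage table: {missing}")
    if len(spec.variant_ids) == 0:
        return pd.Series(np.zeros(len(dosages)), index=dosages.index, name=spec.name)
    vals = dosages[spec.variant_ids].to_numpy(float) @ spec.weights
    return pd.Series(vals, index=dosages.index, name=spec.name)


def instrument_strength(
    score: np.ndarray, exposure: np.ndarray, covariates: pd.DataFrame | None = None
) -> InstrumentStrength:
    """Incremental R^2 and 1-df partial F of the score in the exposure model.

    r2 is the gain in R^2 when the score is added to the covariate-only
    model; f_stat = (n - p - 1) * r2_partial / (1 - r2_partial) where
    r2_partial conditions on the covariates.
    """
    score = np.asarray(score, float)
    y = np.asarray(exposure, float)
    n = len(y)
    if np.std(score) == 0:
        raise EstimationError("score is constant; instrument strength undefined")
    base = _design(covariates, n)
    if n <= base.shape[1] + 2:
        raise InputError("too few observations for the covariate model")
    fit0 = sm.OLS(y, base).fit()
    fit1 = sm.OLS(y, np.column_stack([base, score])).fit()
    r2 = float(fit1.rsquared - fit0.rsquared)
    r2_partial = r2 / (1.0 - fit0.rsquared)
    p = fit1.df_model  # regressors excluding intercept
    f = (n - p - 1) * r2_partial / (1.0 - r2_partial)
    return InstrumentStrength(r2=r2, f_stat=float(f), n=n, k=1)
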