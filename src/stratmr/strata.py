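"""Exposure stratification for non-linear Mendelian randomization.

Stratum-specific MR is only valid if stratum membership is (approximately)
independent of the genetic instrument; naively stratifying on the exposure
itself would induce collider bias because the exposure is downstream of the
instrument.  Two stratification schemes are provided:

- **Doubly-ranked** (primary): individuals are first ordered by the genetic
  score and chunked into pre-strata of ``pre_stratum_size`` consecutive
  individuals; within each pre-stratum they are ordered by exposure and the
  individual with within-rank r (of m) goes to stratum ceil(r*S/m).  With
  pre-strata of 50 and 5 strata, each pre-stratum contributes exactly ten
  individuals to each stratum.  Valid under a rank-preserving assumption
  even when the genetic effect on the exposure is not constant.

- **Residual** (secondary): strata are quantile groups of the exposure
  residual after regressing out the score (and covariates), on the
  untransformed or log scale.  Valid only under a constant genetic effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import substream
from .exceptions import ConfigurationError, InputError

__all__ = [
    "StratumAssignment",
    "DoublyRankedStratifier",
    "ResidualStratifier",
    "doubly_ranked_strata",
    "residual_strata",
    "stratum_summaries",
]


@dataclass(frozen=True)
class StratumAssignment:
    """Per-participant stratum labels (1..S) plus method metadata."""

    labels: np.ndarray
    method: str  # "doubly_ranked" | "residual"
    n_strata: int
    pre_stratum_size: int | None = None
    transform: str | None = None
    seed: int | None = None


def _rank_allocate(ranks: np.ndarray, m: int, n_strata: int) -> np.ndarray:
    """Stratum of each 1-based rank r in a block of size m: ceil(r*S/m)."""
    return np.ceil(ranks * n_strata / m).astype(int)


def doubly_ranked_strata(
    score: np.ndarray,
    exposure: np.ndarray,
    n_strata: int = 5,
    pre_stratum_size: int = 50,
    seed: int = 0,
) -> StratumAssignment:
    """Assign exposure strata by the doubly-ranked method.

    Score ties are broken by adding a seeded uniform perturbation smaller
    than the smallest nonzero score gap, preserving the order of distinct
    values while making tied ranks deterministic given the seed.  The final
    pre-stratum may be smaller than ``pre_stratum_size``; its members are
    allocated by the same ceil(r*S/m) rule so nobody is dropped.
    """
    score = np.asarray(score, float)
    exposure = np.asarray(exposure, float)
    n = len(score)
    if len(exposure) != n:
        raise InputError("score and exposure must have equal length")
    S, P = int(n_strata), int(pre_stratum_size)
    if n < S:
        raise ConfigurationError(f"need at least {S} individuals for {S} strata")
    if P < S:
        raise ConfigurationError("pre_stratum_size must be >= n_strata")
    if np.ptp(exposure) == 0:
        warnings.warn("exposure is constant; within-pre-stratum ranks are arbitrary", stacklevel=2)

    uniq = np.unique(score)
    gaps = np.diff(uniq)
    eps = gaps.min() if gaps.size else 1.0
    pert = substream(seed, "tiebreak").uniform(0.0, 0.999 * eps, size=n)
    order = np.argsort(score + pert, kind="stable")

    labels = np.empty(n, dtype=int)
    for start in range(0, n, P):
        idx = order[start:start + P]
        m = len(idx)
        # within-pre-stratum exposure ranks, ties broken by score order (stable)
        r = np.empty(m, dtype=int)
        r[np.argsort(exposure[idx], kind="stable")] = np.arange(1, m + 1)
        labels[idx] = _rank_allocate(r, m, S)
    return StratumAssignment(
        labels=labels, method="doubly_ranked", n_strata=S, pre_stratum_size=P, seed=seed
    )


def residual_strata(
    exposure: np.ndarray,
    score: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_strata: int = 5,
    transform: str = "identity",
) -> StratumAssignment:
    """Quantile strata of the exposure residual given the score.

    ``transform="log"`` stratifies residuals of log-exposure (requires
    strictly positive exposure).
    """
    exposure = np.asarray(exposure, float)
    score = np.asarray(score, float)
    n = len(exposure)
    S = int(n_strata)
    if n < S:
        raise ConfigurationError(f"need at least {S} individuals for {S} strata")
    if transform not in ("identity", "log"):
        raise ConfigurationError(f"unknown transform {transform!r}")
    if transform == "log":
        if np.any(exposure <= 0):
            raise InputError("log transform requires strictly positive exposure")
        yv = np.log(exposure)
    else:
        yv = exposure
    blocks = [np.ones((n, 1)), score.reshape(n, 1)]
    if covariates is not None and covariates.shape[1] > 0:
        blocks.append(covariates.to_numpy(float))
    X = np.hstack(blocks)
    resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
    r = np.empty(n, dtype=int)
    r[np.argsort(resid, kind="stable")] = np.arange(1, n + 1)
    labels = _rank_allocate(r, n, S)
    return StratumAssignment(labels=labels, method="residual", n_strata=S, transform=transform)


def stratum_summaries(assignment: StratumAssignment, exposure: np.ndarray) -> pd.DataFrame:
    """Per-stratum size and mean exposure (nmol/L)."""
    exposure = np.asarray(exposure, float)
    if len(exposure) != len(assignment.labels):
        raise InputError("assignment and exposure are not aligned")
    df = pd.DataFrame({"stratum": assignment.labels, "exposure": exposure})
    out = (
        df.groupby("stratum")["exposure"]
        .agg(size="size", mean_exposure="mean")
        .reset_index()
        .sort_values("stratum")
        .reset_index(drop=True)
    )
    return out


class DoublyRankedStratifier(BaseEstimator):
    """Doubly-ranked stratification as a clustering-style estimator.

    ``fit(X)`` expects X of shape (n, 2) with columns (score, exposure);
    ``labels_`` holds stratum indices 1..n_strata.
    """

    def __init__(self, n_strata: int = 5, pre_stratum_size: int = 50, random_state: int = 0):
        self.n_strata = n_strata
        self.pre_stratum_size = pre_stratum_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.assignment_ = doubly_ranked_strata(
            X[:, 0], X[:, 1], self.n_strata, self.pre_stratum_size, seed=self.random_state
        )
        self.labels_ = self.assignment_.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ResidualStratifier(BaseEstimator):
    """Residual-method stratification as a clustering-style estimator.

    ``fit(X, covariates=...)`` expects X of shape (n, 2) with columns
    (score, exposure).
    """

    def __init__(self, n_strata: int = 5, transform: str = "identity"):
        self.n_strata = n_strata
        self.transform = transform

    def fit(self, X, y=None, covariates: pd.DataFrame | None = None):
        X = np.asarray(X, float)
        self.assignment_ = residual_strata(
            X[:, 1], X[:, 0], covariates, self.n_strata, self.transform
        )
        self.labels_ = self.assignment_.labels
        return self

    def fit_predict(self, X, y=None, covariates: pd.DataFrame | None = None):
        return self.fit(X, covariates=covariates).labels_
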