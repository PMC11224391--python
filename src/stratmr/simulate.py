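"""Synthetic cohort generation for one-sample Mendelian randomization.

The generator emulates a large population cohort in which circulating
25-hydroxyvitamin D [25(OH)D, nmol/L] is partly determined by common genetic
variants in four gene regions with known roles in vitamin D transport,
synthesis and catabolism (*GC*, *DHCR7*, *CYP2R1*, *CYP24A1*), partly by
season of measurement, and partly by unmodelled environment.  Rare binary
disease outcomes are drawn from logistic models whose dependence on 25(OH)D
can be null, linear, or threshold-shaped (risk responds to the exposure only
below a deficiency threshold).  Age and sex are drawn independently of
genotype so they act as negative-control outcomes by construction.

Generative model for the exposure of individual *i*::

    X_i = mu + s_i * (G_i - E[G]) + A * cos(2*pi*(month_i - 7)/12) + e_i

where ``G_i = sum_v dosage_iv * w_v`` is the weighted allelic score, ``s_i``
is a positive per-individual effect multiplier (lognormal, mean 1,
coefficient of variation ``effect_heterogeneity``) that makes the genetic
effect on the exposure non-constant in the population — the regime that the
doubly-ranked stratification method is designed for — and ``e_i`` is
Gaussian noise.  The weights are rescaled once so the score's variance
equals ``score_r2_target * exposure_sd**2``, and the noise variance is then
chosen so the total SD matches ``exposure_sd``; both calibration targets are
therefore met simultaneously.

Genotypes are drawn as two independent Bernoulli haplotypes per variant
(Hardy–Weinberg marginals).  Within-region linkage disequilibrium is induced
by a shared latent Gaussian threshold model whose latent correlation is
numerically inverted so that the realized *dosage* correlation matches the
requested value (thresholding attenuates correlation, so the latent value
must exceed the target).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from ._utils import substream
from .exceptions import AdjustmentError, CalibrationError, ConfigurationError, InputError

REGIONS = ("GC", "DHCR7", "CYP2R1", "CYP24A1", "other")

__all__ = [
    "VariantSet",
    "EffectSpec",
    "SelectionSpec",
    "GeneratorConfig",
    "CohortSimulator",
    "default_variants",
    "default_effects",
    "generate_genotypes",
    "generate_exposure",
    "generate_covariates",
    "calibrate_intercept",
    "generate_outcomes",
    "season_adjust",
]


# ---------------------------------------------------------------------------
# Variant panel


@dataclass(frozen=True)
class VariantSet:
    """A panel of biallelic variants with regions, frequencies and weights.

    ``weight`` is the per-effect-allele association with the exposure in
    nmol/L; ``causal_flag`` records generator truth (a variant can be carried
    in the panel with weight 0 to act as a null candidate for selection).
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"variant_id", "region", "allele_freq", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"variant table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        if "causal_flag" not in tab.columns:
            tab["causal_flag"] = tab["weight"] != 0.0
        if tab["variant_id"].duplicated().any():
            dup = tab.loc[tab["variant_id"].duplicated(), "variant_id"].tolist()
            raise ConfigurationError(f"duplicate variant ids: {dup}")
        freqs = tab["allele_freq"].to_numpy(float)
        if not np.all((freqs > 0) & (freqs < 1)):
            raise ConfigurationError("allele frequencies must lie strictly in (0, 1)")
        if not np.all(np.isfinite(tab["weight"].to_numpy(float))):
            raise ConfigurationError("variant weights must be finite")
        bad = set(tab["region"]) - set(REGIONS)
        if bad:
            raise ConfigurationError(f"unknown gene regions: {sorted(bad)}; expected one of {REGIONS}")
        object.__setattr__(self, "table", tab.reset_index(drop=True))

    # -- accessors ----------------------------------------------------------
    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.table["allele_freq"].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def with_weights(self, weights: np.ndarray) -> "VariantSet":
        tab = self.table.copy()
        tab["weight"] = np.asarray(weights, float)
        return VariantSet(tab)

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantSet":
        return cls(pd.read_csv(path, sep="\t"))


def default_variants() -> VariantSet:
    """The default 21-variant panel: four vitamin-D gene regions.

    Frequencies and relative weights are illustrative (the *GC* region
    carries the strongest associations); absolute weights are rescaled at
    generation time to hit the configured score R^2.
    """
    rows = [
        # region, allele_freq, raw weight (nmol/L per allele)
        ("GC", 0.28, 3.5), ("GC", 0.45, 2.0), ("GC", 0.61, 1.5), ("GC", 0.15, 1.2),
        ("GC", 0.52, 1.0), ("GC", 0.33, 0.8), ("GC", 0.70, 0.6),
        ("DHCR7", 0.24, 2.3), ("DHCR7", 0.41, 1.1), ("DHCR7", 0.55, 0.9), ("DHCR7", 0.12, 0.7),
        ("CYP2R1", 0.38, 2.6), ("CYP2R1", 0.60, 1.4), ("CYP2R1", 0.22, 1.0),
        ("CYP2R1", 0.47, 0.8), ("CYP2R1", 0.31, 0.6), ("CYP2R1", 0.66, 0.5),
        ("CYP24A1", 0.35, 1.2), ("CYP24A1", 0.50, 0.9), ("CYP24A1", 0.20, 0.7), ("CYP24A1", 0.58, 0.5),
    ]
    tab = pd.DataFrame(
        {
            "variant_id": [f"{r.lower()}_{i + 1:02d}" for i, (r, _, _) in enumerate(rows)],
            "region": [r for r, _, _ in rows],
            "allele_freq": [p for _, p, _ in rows],
            "weight": [w for _, _, w in rows],
        }
    )
    return VariantSet(tab)


# ---------------------------------------------------------------------------
# Genotypes


@lru_cache(maxsize=4096)
def _latent_corr(p1: float, p2: float, rho: float) -> float:
    """Latent bivariate-normal correlation giving allele correlation ``rho``.

    Alleles are indicators ``Z < Phi^-1(p)``; the orthant probability
    P(Z1<z1, Z2<z2; r) is inverted by root-finding so the induced Bernoulli
    (and hence dosage) correlation equals the target.  Targets beyond the
    Frechet bound for the pair's frequencies (binary variables with unequal
    frequencies cannot be arbitrarily correlated) are capped at 95% of the
    bound, as real LD between variants of disparate frequency is likewise
    limited.
    """
    if rho == 0.0:
        return 0.0
    sd_prod = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    rho_max = (hi - p1 * p2) / sd_prod
    rho = min(rho, 0.95 * rho_max)
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    target_p11 = p1 * p2 + rho * sd_prod
    if not (lo < target_p11 < hi):
        raise ConfigurationError(
            f"dosage correlation {rho} unreachable for allele frequencies {p1}, {p2}"
        )

    def f(r):
        cov = [[1.0, r], [r, 1.0]]
        return stats.multivariate_normal.cdf([z1, z2], mean=[0, 0], cov=cov) - target_p11

    return optimize.brentq(f, -0.9999, 0.9999, xtol=1e-10)


@lru_cache(maxsize=64)
def _latent_cholesky(freqs: tuple, regions: tuple, ld_r: float) -> np.ndarray:
    """Cholesky factor of the latent correlation matrix (block by region)."""
    v = len(freqs)
    R = np.eye(v)
    for i in range(v):
        for j in range(i + 1, v):
            if regions[i] == regions[j]:
                r = _latent_corr(freqs[i], freqs[j], ld_r)
                R[i, j] = R[j, i] = r
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        # repair tiny negative eigenvalues from pairwise construction
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        return np.linalg.cholesky(R)


def generate_genotypes(
    n: int, variants: VariantSet, ld_r: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Draw an ``n`` x V table of dosages in {0, 1, 2}.

    Variants within the same gene region have pairwise dosage correlation
    approximately ``ld_r``; variants in different regions are independent.
    Marginals are Hardy–Weinberg at the panel's allele frequencies.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not (0.0 <= ld_r < 1.0):
        raise ConfigurationError("ld_r must lie in [0, 1)")
    rng = substream(seed, "genotypes")
    p = variants.allele_freqs
    if ld_r == 0.0:
        dos = rng.binomial(2, p, size=(n, variants.n_variants))
    else:
        L = _latent_cholesky(tuple(p), tuple(variants.regions), float(ld_r))
        z = stats.norm.ppf(p)
        hap1 = rng.standard_normal((n, variants.n_variants)) @ L.T < z
        hap2 = rng.standard_normal((n, variants.n_variants)) @ L.T < z
        dos = hap1.astype(np.int8) + hap2.astype(np.int8)
    return pd.DataFrame(dos, columns=variants.variant_ids)


# ---------------------------------------------------------------------------
# Exposure


def _theoretical_score_moments(variants: VariantSet, ld_r: float) -> tuple[float, float]:
    """(mean, variance) of the weighted allelic score under the LD model."""
    p, w, reg = variants.allele_freqs, variants.weights, variants.regions
    sd_dos = np.sqrt(2.0 * p * (1.0 - p))
    same_region = reg[:, None] == reg[None, :]
    corr = np.where(same_region, ld_r, 0.0)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sd_dos, sd_dos)
    return float(2.0 * p @ w), float(w @ cov @ w)


def calibrated_weights(config: "GeneratorConfig") -> tuple[np.ndarray, float]:
    """Rescale variant weights to hit the score-R^2 target; return noise SD.

    Raises :class:`CalibrationError` when the target is unreachable (zero
    weights with a positive R^2 target, or a residual variance that would be
    negative once the genetic, heterogeneity and seasonal components are
    accounted for).
    """
    sd2 = config.exposure_sd**2
    _, var_g_raw = _theoretical_score_moments(config.variants, config.ld_r)
    target_var_g = config.score_r2_target * sd2
    if target_var_g > 0 and var_g_raw <= 0:
        raise CalibrationError(
            "score_r2_target > 0 but variant weights carry no variance; "
            "supply nonzero weights or set score_r2_target = 0"
        )
    scale = math.sqrt(target_var_g / var_g_raw) if var_g_raw > 0 else 0.0
    weights = config.variants.weights * scale
    h2 = config.effect_heterogeneity**2
    # exposure_mean / exposure_sd / score_r2_target describe the
    # season-adjusted exposure (the analysis variable); the seasonal term only
    # inflates the raw measurement and is removed again by season_adjust, so
    # it does not enter the variance budget.
    var_noise = sd2 - (1.0 + h2) * target_var_g
    if var_noise < 0:
        raise CalibrationError(
            "exposure variance budget exceeded: genetic + heterogeneity "
            f"components need {sd2 - var_noise:.1f} but exposure_sd^2 = {sd2:.1f}; "
            "reduce effect_heterogeneity or score_r2_target"
        )
    return weights, math.sqrt(var_noise)


def generate_exposure(
    dosages: pd.DataFrame, config: "GeneratorConfig", seed: int = 0
) -> pd.DataFrame:
    """Exposure (nmol/L) and measurement month for each individual.

    Columns returned: ``exposure_raw``, ``month``.  Months are uniform over
    1..12; the seasonal term is a sinusoid peaking in July.  Exposure is
    floored at 0.5 nmol/L (assay detection-limit analogue) so positivity
    holds; under the default configuration <0.3% of draws are affected.
    """
    if list(dosages.columns) != config.variants.variant_ids:
        raise InputError("dosage columns do not match the configured variant panel")
    n = len(dosages)
    weights, noise_sd = calibrated_weights(config)
    mu_g, _ = _theoretical_score_moments(config.variants.with_weights(weights), config.ld_r)
    g_centred = dosages.to_numpy(float) @ weights - mu_g

    month = substream(seed, "months").integers(1, 13, size=n)
    season = config.seasonal_amplitude * np.cos(2.0 * np.pi * (month - 7) / 12.0)

    h = config.effect_heterogeneity
    if h > 0:
        sig2 = math.log1p(h**2)
        s = substream(seed, "heterogeneity").lognormal(-sig2 / 2.0, math.sqrt(sig2), size=n)
    else:
        s = 1.0
    noise = substream(seed, "noise").normal(0.0, noise_sd, size=n)
    x = config.exposure_mean + s * g_centred + season + noise
    return pd.DataFrame({"exposure_raw": np.maximum(x, 0.5), "month": month})


# ---------------------------------------------------------------------------
# Covariates, outcomes


def generate_covariates(n: int, seed: int = 0, n_centres: int = 22) -> pd.DataFrame:
    """Age, sex, assessment centre and ten genetic principal components.

    Age ~ Normal(57.1, 8.1) truncated to the recruitment window [40, 70];
    sex is Bernoulli(0.534) coded 1 = female; centre is uniform categorical;
    PCs are standard normal.  All are drawn independently of genotype, which
    is what makes age and sex valid negative-control outcomes.
    """
    rng = substream(seed, "covariates")
    age = np.clip(rng.normal(57.1, 8.1, size=n), 40.0, 70.0)
    sex = rng.binomial(1, 0.534, size=n)
    centre = np.array([f"c{k:02d}" for k in rng.integers(1, n_centres + 1, size=n)])
    cols = {"age": age, "sex": sex, "centre": centre}
    pcs = rng.standard_normal((n, 10))
    for j in range(10):
        cols[f"pc{j + 1}"] = pcs[:, j]
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class EffectSpec:
    """Causal shape of one binary outcome's dependence on the exposure.

    ``beta`` is the log odds ratio per 10 nmol/L.  Under ``shape="threshold"``
    the effect applies only below ``threshold`` nmol/L:
    f(X) = beta * min(X - threshold, 0) / 10, so higher exposure within the
    deficient range changes risk while the curve is flat above the threshold.
    """

    name: str
    shape: str = "null"
    beta: float = 0.0
    threshold: float | None = None
    target_prevalence: float = 0.05
    covariate_coefs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape not in ("null", "linear", "threshold"):
            raise ConfigurationError(f"unknown effect shape {self.shape!r}")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if self.shape == "threshold" and (self.threshold is None or self.threshold <= 0):
            raise ConfigurationError("threshold shape requires threshold > 0")

    def linear_predictor_term(self, exposure: np.ndarray) -> np.ndarray:
        if self.shape == "null":
            return np.zeros_like(exposure, dtype=float)
        if self.shape == "linear":
            return self.beta * exposure / 10.0
        return self.beta * np.minimum(exposure - self.threshold, 0.0) / 10.0


def default_effects() -> list[EffectSpec]:
    """The four default outcomes with cohort-realistic prevalences, all null."""
    prev = {
        "fibromyalgia": 0.007,
        "clinical_fatigue": 0.020,
        "chronic_widespread_pain": 0.013,
        "depression": 0.039,
    }
    return [EffectSpec(name=k, shape="null", target_prevalence=v) for k, v in prev.items()]


def calibrate_intercept(
    effect: EffectSpec, exposure: np.ndarray, covariates: pd.DataFrame | None = None
) -> float:
    """Logistic intercept such that mean risk equals the target prevalence.

    Root-finding on the sample: solves mean(expit(c + lp)) = target to 1e-10.
    """
    lp = effect.linear_predictor_term(np.asarray(exposure, float))
    if covariates is not None:
        for col, coef in effect.covariate_coefs.items():
            lp = lp + coef * covariates[col].to_numpy(float)

    def f(c):
        return float(np.mean(expit(c + lp))) - effect.target_prevalence

    lo, hi = -40.0, 20.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"intercept for outcome {effect.name!r} not bracketable in [{lo}, {hi}]"
        )
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def generate_outcomes(
    exposure: np.ndarray,
    covariates: pd.DataFrame | None,
    effect: EffectSpec,
    seed: int = 0,
    index: int = 0,
) -> np.ndarray:
    """Bernoulli outcome draws from the calibrated logistic model."""
    exposure = np.asarray(exposure, float)
    lp = effect.linear_predictor_term(exposure)
    if covariates is not None:
        for col, coef in effect.covariate_coefs.items():
            lp = lp + coef * covariates[col].to_numpy(float)
    c = calibrate_intercept(effect, exposure, covariates)
    prob = expit(c + lp)
    rng = substream(seed, "outcomes", index=index)
    return (rng.random(len(exposure)) < prob).astype(np.int8)


# ---------------------------------------------------------------------------
# Seasonal adjustment


def season_adjust(
    exposure_raw: np.ndarray, month: np.ndarray, reference_month: int = 10
) -> np.ndarray:
    """Mean-shift the exposure to the reference measurement month (October).

    adjusted_i = raw_i - mean(raw | month_i) + mean(raw | reference_month),
    with month-group means computed on the input sample.  After adjustment
    every month group has the same mean, removing seasonal variability from
    between-individual comparisons.
    """
    x = np.asarray(exposure_raw, float)
    m = np.asarray(month)
    if not np.all((m >= 1) & (m <= 12)):
        raise InputError("months must lie in 1..12")
    means = pd.Series(x).groupby(pd.Series(m)).mean()
    if reference_month not in means.index:
        raise AdjustmentError(f"no observations in reference month {reference_month}")
    return x - means.reindex(m).to_numpy() + means.loc[reference_month]


# ---------------------------------------------------------------------------
# Selection into the sample (optional, for negative-control diagnostics)


@dataclass(frozen=True)
class SelectionSpec:
    """Non-random participation model on the log-odds scale.

    Participation probability = expit(logit(base_rate) + score_coef * z_G
    + sex_coef * sex + interaction_coef * z_G * (2*sex - 1)) where ``z_G`` is
    the standardized allelic score.  A nonzero interaction induces a
    score–sex association *within the selected sample*, the mechanism that
    makes a sex negative-control analysis light up.
    """

    base_rate: float = 0.6
    score_coef: float = 0.0
    sex_coef: float = 0.0
    interaction_coef: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.base_rate < 1.0):
            raise ConfigurationError("base_rate must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Whole-cohort simulator


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the calibration of a large UK population cohort:
    exposure 55.4 +/- 19.3 nmol/L, score explaining 4.7% of exposure
    variance, four rare outcomes with prevalences 0.7/2.0/1.3/3.9%.
    """

    n: int = 100_000
    variants: VariantSet = field(default_factory=default_variants)
    exposure_mean: float = 55.4
    exposure_sd: float = 19.3
    score_r2_target: float = 0.047
    effect_heterogeneity: float = 0.2
    seasonal_amplitude: float = 10.0
    ld_r: float = 0.3
    n_centres: int = 22
    effects: tuple = field(default_factory=lambda: tuple(default_effects()))
    selection: SelectionSpec | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0.0 <= self.score_r2_target < 1.0):
            raise ConfigurationError("score_r2_target must lie in [0, 1)")
        if self.effect_heterogeneity < 0:
            raise ConfigurationError("effect_heterogeneity must be >= 0")
        if not (0.0 <= self.ld_r < 1.0):
            raise ConfigurationError("ld_r must lie in [0, 1)")
        names = [e.name for e in self.effects]
        if len(names) != len(set(names)):
            raise ConfigurationError("outcome names must be unique")
        object.__setattr__(self, "effects", tuple(self.effects))


class CohortSimulator:
    """Generate complete analysis-ready cohorts from a :class:`GeneratorConfig`.

    ``generate(seed)`` returns one cohort table with columns: participant_id,
    one dosage column per variant, exposure_raw, month, exposure_adj
    (season-adjusted to October), age, sex, centre, pc1..pc10, and one binary
    column per configured outcome.
    """

    def __init__(self, config: GeneratorConfig):
        self.config = config

    def calibrated_variants(self) -> VariantSet:
        """Variant panel with the generative (rescaled) weights."""
        weights, _ = calibrated_weights(self.config)
        return self.config.variants.with_weights(weights)

    def score_spec(self):
        """ScoreSpec built from generator-truth weights (for oracle analyses)."""
        from .scores import ScoreSpec

        vs = self.calibrated_variants()
        return ScoreSpec(
            name="generator_truth",
            variant_ids=vs.variant_ids,
            weights=vs.weights,
            provenance="generator",
        )

    def generate(self, seed: int | None = None) -> pd.DataFrame:
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        if seed is None:
            raise ConfigurationError("a seed must be given (no silent defaults)")
        if cfg.selection is None:
            return self._draw(cfg.n, seed)
        # oversample, then keep participants by the selection model
        pool_n = int(math.ceil(cfg.n / cfg.selection.base_rate * 1.35)) + 100
        pool = self._draw(pool_n, seed)
        sel = cfg.selection
        score = pool[cfg.variants.variant_ids].to_numpy(float) @ self.calibrated_variants().weights
        z = (score - score.mean()) / score.std()
        sex = pool["sex"].to_numpy(float)
        lp = (
            logit(sel.base_rate)
            + sel.score_coef * z
            + sel.sex_coef * sex
            + sel.interaction_coef * z * (2.0 * sex - 1.0)
        )
        keep = substream(seed, "selection").random(pool_n) < expit(lp)
        kept = pool.loc[keep]
        if len(kept) < cfg.n:
            raise CalibrationError("selection model kept too few participants; lower base_rate oversampling assumption")
        out = kept.iloc[: cfg.n].reset_index(drop=True)
        out["participant_id"] = np.arange(cfg.n)
        return out

    def _draw(self, n: int, seed: int) -> pd.DataFrame:
        cfg = self.config
        dosages = generate_genotypes(n, cfg.variants, ld_r=cfg.ld_r, seed=seed)
        expo = generate_exposure(dosages, cfg, seed=seed)
        cov = generate_covariates(n, seed=seed, n_centres=cfg.n_centres)
        cohort = pd.concat(
            [pd.DataFrame({"participant_id": np.arange(n)}), dosages, expo, cov], axis=1
        )
        cohort["exposure_adj"] = season_adjust(
            cohort["exposure_raw"].to_numpy(), cohort["month"].to_numpy()
        )
        for k, eff in enumerate(cfg.effects):
            cohort[eff.name] = generate_outcomes(
                cohort["exposure_raw"].to_numpy(), cov, eff, seed=seed, index=k
            )
        return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
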