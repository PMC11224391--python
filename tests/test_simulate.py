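"""Generator calibration, outcome models and seasonal adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from stratmr import (
    CohortSimulator,
    EffectSpec,
    GeneratorConfig,
    VariantSet,
    calibrate_intercept,
    generate_exposure,
    generate_genotypes,
    generate_outcomes,
    season_adjust,
)
from stratmr._utils import substream
from stratmr.exceptions import (
    AdjustmentError,
    CalibrationError,
    ConfigurationError,
)
from stratmr.simulate import calibrated_weights

from conftest import make_variants


class TestGenotypes:
    def test_hardy_weinberg_moments(self):
        vs = make_variants([0.5, 0.2, 0.7])
        dos = generate_genotypes(50000, vs, ld_r=0.0, seed=1).to_numpy()
        for j, p in enumerate([0.5, 0.2, 0.7]):
            mean, var = 2 * p, 2 * p * (1 - p)
            se_mean = np.sqrt(var / 50000)
            assert abs(dos[:, j].mean() - mean) < 3 * se_mean
            assert abs(dos[:, j].var() - var) < 0.05 * var
            # genotype class frequencies match binomial(2, p) within 3 SE
            for g in (0, 1, 2):
                from scipy.stats import binom

                f = binom.pmf(g, 2, p)
                se = np.sqrt(f * (1 - f) / 50000)
                assert abs((dos[:, j] == g).mean() - f) < 3 * se

    def test_within_region_ld_hits_target(self):
        vs = make_variants([0.5, 0.5])
        dos = generate_genotypes(50000, vs, ld_r=0.8, seed=2).to_numpy()
        r = np.corrcoef(dos.T)[0, 1]
        assert abs(r - 0.8) < 0.05

    def test_across_region_independence(self):
        vs = make_variants([0.4, 0.4], region=["GC", "DHCR7"])
        dos = generate_genotypes(50000, vs, ld_r=0.8, seed=3).to_numpy()
        assert abs(np.corrcoef(dos.T)[0, 1]) < 0.03

    def test_single_individual(self):
        vs = make_variants([0.3, 0.6])
        dos = generate_genotypes(1, vs, ld_r=0.5, seed=4)
        assert dos.shape == (1, 2)
        assert set(np.unique(dos.to_numpy())) <= {0, 1, 2}

    def test_invalid_ld_rejected(self):
        vs = make_variants([0.5])
        with pytest.raises(ConfigurationError):
            generate_genotypes(100, vs, ld_r=1.0, seed=0)
        with pytest.raises(ConfigurationError):
            generate_genotypes(0, vs, ld_r=0.0, seed=0)

    def test_degenerate_allele_freq_rejected(self):
        with pytest.raises(ConfigurationError):
            make_variants([0.0, 0.5])


class TestExposure:
    def test_null_genetic_effect_independent_of_dosages(self):
        vs = make_variants([0.5, 0.3], weights=[0.0, 0.0])
        cfg = GeneratorConfig(n=20000, variants=vs, score_r2_target=0.0, ld_r=0.0)
        dos = generate_genotypes(20000, vs, seed=5)
        expo = generate_exposure(dos, cfg, seed=5)
        X = np.column_stack([np.ones(20000), dos.to_numpy(float)])
        y = expo["exposure_raw"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        assert r2 < 1e-3

    def test_r2_target_unreachable_raises(self):
        vs = make_variants([0.5], weights=[0.0])
        cfg = GeneratorConfig(n=100, variants=vs, score_r2_target=0.05)
        with pytest.raises(CalibrationError):
            calibrated_weights(cfg)

    def test_variance_budget_overflow_raises(self):
        cfg = GeneratorConfig(n=100, score_r2_target=0.9, effect_heterogeneity=1.0)
        with pytest.raises(CalibrationError):
            calibrated_weights(cfg)

    def test_constant_effect_is_exact_linear_function_of_score(self):
        # with effect_heterogeneity = 0, reconstructing the seasonal and
        # noise components from their documented substreams must leave an
        # exact linear function of the weighted score
        cfg = GeneratorConfig(n=2000, effect_heterogeneity=0.0)
        dos = generate_genotypes(2000, cfg.variants, ld_r=cfg.ld_r, seed=11)
        expo = generate_exposure(dos, cfg, seed=11)
        w, noise_sd = calibrated_weights(cfg)
        from stratmr.simulate import _theoretical_score_moments

        mu_g, _ = _theoretical_score_moments(cfg.variants.with_weights(w), cfg.ld_r)
        month = expo["month"].to_numpy()
        season = cfg.seasonal_amplitude * np.cos(2 * np.pi * (month - 7) / 12)
        noise = substream(11, "noise").normal(0.0, noise_sd, size=2000)
        g = dos.to_numpy(float) @ w - mu_g
        expected = np.maximum(cfg.exposure_mean + g + season + noise, 0.5)
        np.testing.assert_allclose(expo["exposure_raw"].to_numpy(), expected, atol=1e-10)


class TestOutcomes:
    def test_intercept_closed_form_null_shape(self):
        eff = EffectSpec(name="o", shape="null", target_prevalence=0.039)
        c = calibrate_intercept(eff, np.full(100, 55.0))
        assert abs(c - logit(0.039)) < 1e-8

    @pytest.mark.parametrize(
        "eff",
        [
            EffectSpec(name="o", shape="null", target_prevalence=0.039),
            EffectSpec(name="o", shape="linear", beta=-0.1, target_prevalence=0.039),
            EffectSpec(name="o", shape="threshold", beta=-0.3, threshold=25.0, target_prevalence=0.007),
            EffectSpec(
                name="o", shape="linear", beta=0.1, target_prevalence=0.02,
                covariate_coefs={"age": 0.02, "sex": 0.3},
            ),
        ],
        ids=["null", "linear", "threshold", "covariates"],
    )
    def test_prevalence_matches_target(self, eff):
        rng = np.random.default_rng(0)
        n = 100000
        x = np.maximum(rng.normal(55.4, 19.3, n), 0.5)
        cov = pd.DataFrame({"age": rng.normal(57, 8, n), "sex": rng.binomial(1, 0.5, n)})
        y = generate_outcomes(x, cov, eff, seed=1)
        K = eff.target_prevalence
        assert abs(y.mean() - K) < 3 * np.sqrt(K * (1 - K) / n)

    def test_threshold_shape_raises_risk_below_threshold_only(self):
        rng = np.random.default_rng(1)
        n = 100000
        x = np.maximum(rng.normal(55.4, 19.3, n), 0.5)
        eff = EffectSpec(name="o", shape="threshold", beta=-0.3, threshold=25.0, target_prevalence=0.039)
        y = generate_outcomes(x, None, eff, seed=2)
        assert y[x < 25].mean() > y[x > 50].mean()

    def test_zero_beta_threshold_identical_to_null(self):
        rng = np.random.default_rng(2)
        x = np.maximum(rng.normal(55.4, 19.3, 5000), 0.5)
        null = EffectSpec(name="o", shape="null", target_prevalence=0.02)
        thr = EffectSpec(name="o", shape="threshold", beta=0.0, threshold=25.0, target_prevalence=0.02)
        np.testing.assert_array_equal(
            generate_outcomes(x, None, null, seed=3), generate_outcomes(x, None, thr, seed=3)
        )

    def test_null_shape_gives_null_logistic_coefficient(self):
        rng = np.random.default_rng(3)
        n = 100000
        x = np.maximum(rng.normal(55.4, 19.3, n), 0.5)
        y = generate_outcomes(x, None, EffectSpec(name="o", target_prevalence=0.039), seed=4)
        import statsmodels.api as sm

        fit = sm.Logit(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        assert abs(fit.params[1] / fit.bse[1]) < 3

    def test_invalid_effect_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            EffectSpec(name="o", shape="threshold", target_prevalence=0.05)  # no threshold
        with pytest.raises(ConfigurationError):
            EffectSpec(name="o", target_prevalence=1.5)
        with pytest.raises(ConfigurationError):
            EffectSpec(name="o", shape="quadratic")


class TestSeasonAdjust:
    def test_identity_when_all_measured_in_reference_month(self):
        x = np.array([40.0, 55.0, 70.0])
        np.testing.assert_array_equal(season_adjust(x, np.full(3, 10)), x)

    def test_two_month_hand_case(self):
        # months with means 50 and 60, reference = the first: second-month
        # values shift by -10
        x = np.array([45.0, 55.0, 55.0, 65.0])
        m = np.array([10, 10, 6, 6])
        adj = season_adjust(x, m, reference_month=10)
        np.testing.assert_allclose(adj, [45.0, 55.0, 45.0, 55.0])

    def test_month_group_means_equalized(self):
        rng = np.random.default_rng(4)
        m = rng.integers(1, 13, 5000)
        x = 55 + 10 * np.cos(2 * np.pi * (m - 7) / 12) + rng.normal(0, 5, 5000)
        adj = season_adjust(x, m)
        means = pd.Series(adj).groupby(pd.Series(m)).mean()
        assert means.max() - means.min() < 1e-9

    def test_missing_reference_month_raises(self):
        with pytest.raises(AdjustmentError, match="10"):
            season_adjust(np.array([50.0, 60.0]), np.array([1, 2]), reference_month=10)

    def test_invalid_month_raises(self):
        with pytest.raises(Exception):
            season_adjust(np.array([50.0]), np.array([13]))


class TestCohortSimulator:
    def test_schema_and_no_missing_values(self, small_cohort, small_config):
        cols = set(small_cohort.columns)
        assert {"participant_id", "exposure_raw", "exposure_adj", "month",
                "age", "sex", "centre", "depression"} <= cols
        assert {f"pc{j}" for j in range(1, 11)} <= cols
        assert set(small_config.variants.variant_ids) <= cols
        assert not small_cohort.isna().any().any()
        assert small_cohort["exposure_raw"].min() > 0
        assert set(small_cohort["depression"].unique()) <= {0, 1}

    def test_seed_reproducibility(self, small_config):
        a = CohortSimulator(small_config).generate(seed=9)
        b = CohortSimulator(small_config).generate(seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = CohortSimulator(small_config).generate(seed=10)
        assert not a["exposure_raw"].equals(c["exposure_raw"])

    def test_seed_required(self, small_config):
        with pytest.raises(ConfigurationError):
            CohortSimulator(small_config).generate()

    def test_tsv_round_trip(self, small_cohort, tmp_path):
        from stratmr.simulate import read_cohort, write_cohort

        p = tmp_path / "cohort.tsv"
        write_cohort(small_cohort, p)
        back = read_cohort(p)
        np.testing.assert_allclose(
            back["exposure_adj"].to_numpy(), small_cohort["exposure_adj"].to_numpy()
        )
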