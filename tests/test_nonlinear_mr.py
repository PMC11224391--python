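"""Stratum-specific estimation, Rubin's rules, bootstrap averaging, controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratmr import (
    BootstrapSettings,
    NonlinearMR,
    bonferroni_threshold,
    bootstrap_average,
    build_score,
    doubly_ranked_strata,
    negative_control,
    rubin_combine,
    run_linear_analysis,
    stratum_estimates,
)
from stratmr.exceptions import ConfigurationError, EstimationError, InputError


class TestRubinCombine:
    def test_identical_replicates_have_zero_between_variance(self):
        res = rubin_combine([0.2, 0.2, 0.2], [0.01, 0.01, 0.01])
        assert res.point == pytest.approx(0.2, abs=1e-15)
        assert res.between_var == pytest.approx(0.0, abs=1e-30)
        assert res.total_var == pytest.approx(0.01)

    def test_hand_evaluated_two_replicate_example(self):
        res = rubin_combine([0.0, 1.0], [1.0, 1.0])
        assert res.point == 0.5
        assert res.within_var == 1.0
        assert res.between_var == 0.5
        assert res.total_var == pytest.approx(1.75)

    @given(c=st.floats(0.1, 5.0))
    def test_scaling_homogeneity(self, c):
        base = rubin_combine([0.1, 0.3, -0.2], [0.02, 0.05, 0.01])
        scaled = rubin_combine(np.array([0.1, 0.3, -0.2]) * c,
                               np.array([0.02, 0.05, 0.01]) * c**2)
        assert scaled.point == pytest.approx(c * base.point, rel=1e-12)
        assert scaled.total_var == pytest.approx(c**2 * base.total_var, rel=1e-12)

    @given(
        pts=st.lists(st.floats(-2, 2), min_size=2, max_size=30),
        seed=st.integers(0, 10_000),
    )
    def test_matches_spelled_out_oracle(self, pts, seed):
        rng = np.random.default_rng(seed)
        variances = rng.uniform(0.001, 1.0, size=len(pts)).tolist()
        res = rubin_combine(pts, variances)
        # independent oracle: formulas written out longhand
        B = len(pts)
        point = sum(pts) / B
        within = sum(variances) / B
        between = sum((p - point) ** 2 for p in pts) / (B - 1)
        total = within + (1 + 1 / B) * between
        assert abs(res.point - point) < 1e-12
        assert abs(res.within_var - within) < 1e-12
        assert abs(res.between_var - between) < 1e-12
        assert abs(res.total_var - total) < 1e-12
        assert res.total_var >= res.within_var
        assert res.total_var >= res.between_var

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(InputError):
            rubin_combine([0.1], [0.01])


class TestBonferroni:
    def test_published_thresholds(self):
        assert bonferroni_threshold(0.05, 4, 5) == pytest.approx(0.0025, abs=1e-15)
        assert bonferroni_threshold(0.05, 4, 3) == pytest.approx(0.05 / 12, abs=1e-15)
        assert bonferroni_threshold(0.05, 1, 1) == pytest.approx(0.05)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(0.05, 0, 5)


class TestStratumEstimates:
    def test_single_stratum_reproduces_linear_analysis(self, small_cohort, small_score_spec):
        score = build_score(small_cohort, small_score_spec).to_numpy()
        a = doubly_ranked_strata(
            score, small_cohort["exposure_adj"].to_numpy(), 1, 50, seed=0
        )
        ests = stratum_estimates(
            small_cohort, a, small_score_spec, "depression", covariate_set="linear_default"
        )
        tab = run_linear_analysis(small_cohort, small_score_spec, ["depression"])
        assert ests[0].beta == pytest.approx(tab["beta"].iloc[0], abs=1e-10)
        assert ests[0].se == pytest.approx(tab["se"].iloc[0], abs=1e-10)

    def test_single_class_stratum_flagged_not_fatal(self, small_cohort, small_score_spec):
        cohort = small_cohort.copy()
        score = build_score(cohort, small_score_spec).to_numpy()
        a = doubly_ranked_strata(score, cohort["exposure_adj"].to_numpy(), 5, 50, seed=0)
        rare = np.zeros(len(cohort), dtype=int)
        rare[a.labels != 1] = np.random.default_rng(0).binomial(
            1, 0.05, (a.labels != 1).sum()
        )
        cohort["rare"] = rare  # stratum 1 has no cases
        with pytest.warns(UserWarning, match="stratum 1"):
            ests = stratum_estimates(cohort, a, small_score_spec, "rare")
        assert ests[0] is None
        assert sum(e is not None for e in ests[1:]) >= 3


class TestBootstrapAverage:
    def test_zero_removal_idempotent_with_single_run(self, small_cohort, small_score_spec):
        score = build_score(small_cohort, small_score_spec).to_numpy()
        a = doubly_ranked_strata(
            score, small_cohort["exposure_adj"].to_numpy(), 3, 50, seed=3
        )
        single = stratum_estimates(
            small_cohort, a, small_score_spec, "depression", covariate_set="linear_default"
        )
        combined = bootstrap_average(
            small_cohort, small_score_spec, "depression", n_strata=3,
            settings=BootstrapSettings(n_reps=3, n_remove=0, seed=3),
            covariate_set="linear_default",
        )
        for res, est in zip(combined, single):
            assert res.between_var == pytest.approx(0.0, abs=1e-20)
            assert res.point == pytest.approx(est.beta, abs=1e-12)
            assert res.total_var == pytest.approx(est.se**2, rel=1e-10)

    def test_same_seed_reproducible_and_total_var_dominates_within(
        self, small_cohort, small_score_spec
    ):
        kwargs = dict(
            n_strata=3,
            settings=BootstrapSettings(n_reps=4, n_remove=12, seed=5),
            covariate_set="linear_default",
        )
        a = bootstrap_average(small_cohort, small_score_spec, "depression", **kwargs)
        b = bootstrap_average(small_cohort, small_score_spec, "depression", **kwargs)
        for ra, rb in zip(a, b):
            assert ra == rb
            assert ra.total_var >= ra.within_var
            assert ra.se > 0
            assert ra.n_replicates == 4

    def test_estimator_interface_and_row_counts(self, small_cohort, small_score_spec):
        est = NonlinearMR(
            score_spec=small_score_spec, outcomes=["depression"], n_strata=3,
            n_reps=3, n_remove=6, random_state=1, covariate_set="linear_default",
        ).fit(small_cohort)
        assert len(est.results_) == 3
        assert list(est.results_["stratum"]) == [1, 2, 3]
        assert (est.summaries_["size"] > 0).all()
        means = est.results_["mean_exposure"].to_numpy()
        assert (np.diff(means) > 0).all()

    def test_remove_entire_cohort_rejected(self, small_cohort, small_score_spec):
        with pytest.raises(ConfigurationError):
            bootstrap_average(
                small_cohort, small_score_spec, "depression",
                settings=BootstrapSettings(n_reps=2, n_remove=len(small_cohort)),
            )


class TestNegativeControl:
    def test_constant_control_rejected(self, small_cohort, small_score_spec):
        cohort = small_cohort.copy()
        cohort["age"] = 57.0
        with pytest.raises(EstimationError):
            negative_control(cohort, small_score_spec, 3, 50, control="age", seed=0)

    def test_age_and_sex_estimates_returned_per_stratum(self, small_cohort, small_score_spec):
        for ctrl in ("age", "sex"):
            tab = negative_control(small_cohort, small_score_spec, 3, 50, control=ctrl, seed=0)
            assert list(tab["stratum"]) == [1, 2, 3]
            assert (tab["se"] > 0).all()
            # genotype-independent controls: estimates should be modest
            assert tab["estimate"].abs().max() < 5.0

    def test_unknown_control_rejected(self, small_cohort, small_score_spec):
        with pytest.raises(InputError):
            negative_control(small_cohort, small_score_spec, 3, 50, control="height", seed=0)
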