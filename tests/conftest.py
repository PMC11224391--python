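import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stratmr import CohortSimulator, EffectSpec, GeneratorConfig, VariantSet

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_variants(freqs, region="GC", weights=None, prefix="v"):
    """Small ad-hoc variant panel for targeted tests."""
    k = len(freqs)
    if weights is None:
        weights = [1.0] * k
    regions = [region] * k if isinstance(region, str) else list(region)
    return VariantSet(
        pd.DataFrame(
            {
                "variant_id": [f"{prefix}{i + 1}" for i in range(k)],
                "region": regions,
                "allele_freq": list(freqs),
                "weight": list(weights),
            }
        )
    )


@pytest.fixture(scope="session")
def small_config():
    """Cheap cohort conditions: one common outcome, few centres."""
    return GeneratorConfig(
        n=6000,
        n_centres=3,
        effects=(EffectSpec(name="depression", shape="null", target_prevalence=0.039),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return CohortSimulator(small_config).generate(seed=42)


@pytest.fixture(scope="session")
def small_score_spec(small_config):
    return CohortSimulator(small_config).score_spec()


@pytest.fixture(scope="session")
def midsize_cohort():
    """Default-conditions cohort shared by the slower statistical checks."""
    cfg = GeneratorConfig(n=50000)
    sim = CohortSimulator(cfg)
    return sim.generate(seed=7), sim.score_spec()
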