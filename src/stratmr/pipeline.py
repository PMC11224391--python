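"""Pipeline orchestration: one configuration file in, paper-shaped tables out.

A run executes the requested stages in dependency order — simulate (or load
a cohort), build the allelic score, whole-population linear MR, non-linear
MR in five and/or three doubly-ranked strata, negative controls, and a
power curve — writing plain CSV outputs plus a JSON manifest (config hash,
seed, versions, row counts, per-file checksums) and a text log.  Identical
configuration and seed yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .linear import PowerInput, mr_power, run_linear_analysis
from .nonlinear import NonlinearMR, negative_control
from .scores import ScoreSpec, StepwiseScoreSelector, build_score, instrument_strength
from .simulate import (
    CohortSimulator,
    EffectSpec,
    GeneratorConfig,
    SelectionSpec,
    VariantSet,
    default_variants,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger("stratmr")

ANALYSES = ("linear", "nonlinear_5", "nonlinear_3", "negative_controls", "power")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a full run needs; the seed must be set explicitly."""

    seed: int
    output_dir: str
    analyses: list[str] = field(default_factory=lambda: ["linear"])
    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    score_source: str = "generator"  # "generator" | "stepwise" | path to a weight TSV
    outcomes: list[str] | None = None
    alpha: float = 0.05
    pre_stratum_size: int = 50
    bootstrap_reps: int = 100
    bootstrap_remove: int = 12
    p_enter: float = 1e-6
    power_or_grid: list[float] = field(default_factory=lambda: [round(x, 2) for x in np.arange(0.7, 1.31, 0.05)])
    firth: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("seed must be set explicitly")
        if not self.analyses:
            raise ConfigurationError("at least one analysis must be requested")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ConfigurationError(f"unknown analyses {sorted(unknown)}; expected {ANALYSES}")
        if self.generator is None and self.cohort_path is None:
            raise ConfigurationError("either a generator config or a cohort path is required")

    # -- plain-text (YAML) configuration ------------------------------------
    @classmethod
    def from_yaml(cls, path, seed: int | None = None, output_dir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = None
        if "generator" in raw:
            g = dict(raw["generator"])
            if "variants_path" in g:
                g["variants"] = VariantSet.from_tsv(g.pop("variants_path"))
            effects = []
            for e in g.pop("effects", []):
                e = dict(e)
                if e.get("shape") in (None, "null"):
                    e["shape"] = "null"
                effects.append(EffectSpec(**e))
            if effects:
                g["effects"] = tuple(effects)
            if "selection" in g and g["selection"] is not None:
                g["selection"] = SelectionSpec(**g["selection"])
            gen = GeneratorConfig(**g)
        kwargs = {k: v for k, v in raw.items() if k != "generator"}
        if seed is not None:
            kwargs["seed"] = seed
        if output_dir is not None:
            kwargs["output_dir"] = output_dir
        return cls(generator=gen, **kwargs)

    def config_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "generator"}
        if self.generator is not None:
            g = dict(self.generator.__dict__)
            g["variants"] = self.generator.variants.table.to_dict("list")
            g["effects"] = [e.__dict__ for e in self.generator.effects]
            g["selection"] = None if self.generator.selection is None else self.generator.selection.__dict__
            d["generator"] = g
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest (also written)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    files: dict[str, Path] = {}
    manifest = {
        "seed": config.seed,
        "config": config.config_dict(),
        "versions": _versions(),
        "stages": {},
        "files": {},
    }
    # hash the scientific configuration only: where outputs land must not
    # change what they contain
    hashable = {k: v for k, v in manifest["config"].items() if k != "output_dir"}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()
    ).hexdigest()

    def record(name: str, path: Path, n_rows: int | None):
        files[name] = path
        manifest["files"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "n_rows": n_rows,
        }

    stage = "setup"
    try:
        # --- cohort ---------------------------------------------------------
        stage = "cohort"
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
            sim = None
            logger.info("loaded cohort from %s: n=%d", config.cohort_path, len(cohort))
        else:
            sim = CohortSimulator(config.generator)
            cohort = sim.generate(seed=config.seed)
            logger.info("generated cohort: n=%d", len(cohort))
            cohort_path = out / "cohort.tsv"
            write_cohort(cohort, cohort_path)
            record("cohort", cohort_path, len(cohort))
        outcomes = config.outcomes
        if outcomes is None:
            if config.generator is not None:
                outcomes = [e.name for e in config.generator.effects]
            else:
                raise ConfigurationError("outcomes must be listed when loading an external cohort")
        manifest["stages"]["cohort"] = "ok"

        # --- score ----------------------------------------------------------
        stage = "score"
        if config.score_source == "generator":
            if sim is None:
                raise ConfigurationError("score_source='generator' requires a generator config")
            spec = sim.score_spec()
        elif config.score_source == "stepwise":
            variants = (
                config.generator.variants if config.generator is not None else default_variants()
            )
            dosage_cols = [v for v in variants.variant_ids if v in cohort.columns]
            sel = StepwiseScoreSelector(p_enter=config.p_enter).fit(
                cohort[dosage_cols],
                cohort["exposure_adj"].to_numpy(float),
                regions={v: r for v, r in zip(variants.variant_ids, variants.regions)},
                covariates=None,
            )
            spec = sel.score_spec_
        else:
            spec = ScoreSpec.from_tsv(config.score_source, name="custom")
        score = build_score(cohort, spec)
        strength = instrument_strength(
            score.to_numpy(), cohort["exposure_adj"].to_numpy(float)
        )
        logger.info(
            "score %s: %d variants, r2=%.4f, F=%.1f",
            spec.name, len(spec.variant_ids), strength.r2, strength.f_stat,
        )
        spec_path = out / "score_spec.tsv"
        spec.to_tsv(spec_path)
        record("score_spec", spec_path, len(spec.variant_ids))
        manifest["stages"]["score"] = "ok"
        manifest["instrument_strength"] = {
            "r2": strength.r2, "f_stat": strength.f_stat, "n": strength.n,
        }

        # --- analyses -------------------------------------------------------
        if "linear" in config.analyses:
            stage = "linear"
            tab = run_linear_analysis(
                cohort, spec, outcomes, alpha=config.alpha, firth=config.firth
            )
            p = out / "linear.csv"
            tab.to_csv(p, index=False)
            record("linear", p, len(tab))
            manifest["stages"]["linear"] = "ok"
            logger.info("linear MR done: %d outcomes", len(tab))

        for S in (5, 3):
            key = f"nonlinear_{S}"
            if key in config.analyses:
                stage = key
                est = NonlinearMR(
                    score_spec=spec, outcomes=outcomes, n_strata=S,
                    pre_stratum_size=config.pre_stratum_size,
                    n_reps=config.bootstrap_reps, n_remove=config.bootstrap_remove,
                    random_state=config.seed, alpha=config.alpha, firth=config.firth,
                ).fit(cohort)
                p = out / f"{key}.csv"
                est.results_.to_csv(p, index=False)
                record(key, p, len(est.results_))
                manifest["stages"][key] = "ok"
                logger.info("%s done", key)

        if "negative_controls" in config.analyses:
            stage = "negative_controls"
            tabs = []
            for S in (5, 3):
                for ctrl in ("age", "sex"):
                    t = negative_control(
                        cohort, spec, n_strata=S,
                        pre_stratum_size=config.pre_stratum_size,
                        control=ctrl, seed=config.seed, alpha=config.alpha,
                    )
                    t.insert(0, "n_strata", S)
                    tabs.append(t)
            nc = pd.concat(tabs, ignore_index=True)
            p = out / "negative_controls.csv"
            nc.to_csv(p, index=False)
            record("negative_controls", p, len(nc))
            manifest["stages"]["negative_controls"] = "ok"
            logger.info("negative controls done")

        if "power" in config.analyses:
            stage = "power"
            exposure_sd = (
                config.generator.exposure_sd if config.generator is not None
                else float(cohort["exposure_adj"].std())
            )
            case_fracs = {o: float(cohort[o].mean()) for o in outcomes}
            rows = []
            for o in outcomes:
                for orr in config.power_or_grid:
                    if orr == 1.0:
                        continue
                    rows.append(
                        {
                            "outcome": o, "or_per_10": orr,
                            "power": mr_power(PowerInput(
                                n=len(cohort), r2=strength.r2,
                                case_fraction=case_fracs[o], or_per_10=orr,
                                exposure_sd=exposure_sd, alpha=config.alpha,
                            )),
                        }
                    )
            p = out / "power.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            record("power", p, len(rows))
            manifest["stages"]["power"] = "ok"
            logger.info("power curve done")

    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.removeHandler(handler)
        handler.close()
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.removeHandler(handler)
    handler.close()
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "stratmr": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
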