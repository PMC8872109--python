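"""Config-driven orchestration of the analysis stages into a report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import descriptive, genotox, risk, sources
from .core import SampleSet, load_samples, total_pah, write_samples
from .risk import DistributionSpec, mc_ilcr, sensitivity
from .synth import ScenarioConfig, gen_children, gen_school_samples, scenario_from_paper, with_seed

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

log = logging.getLogger("schoolpah")

#: Candidate predictors screened for the DNA-damage regression.
DEFAULT_CANDIDATES = [
    "indoor_tpah", "outdoor_tpah", "age_band", "gender", "bmi_category",
    "dist_main_road", "dist_highway", "transport_mode", "grilled_food",
    "supplement", "fruit", "ets", "bw_kg",
]

GROUP_COMPARISON_VARIABLES = [
    "traffic_group", "age_band", "gender", "bmi_category", "dist_main_road",
    "dist_highway", "transport_mode", "grilled_food", "supplement", "fruit", "ets",
]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    samples_csv: Path | None = None  # generated from the scenario when None
    cohort_csv: Path | None = None
    scenario: ScenarioConfig | None = None  # default: scenario_from_paper()
    lod_policy: str = "half_lod"
    n_iterations: int = 10_000
    seed: int = 0
    logistic_scale: float | None = None  # None -> 0.3 x TEQ mean
    p_enter: float = 0.05
    p_remove: float = 0.10
    equal_var: bool = True
    stages: tuple[str, ...] = ("describe", "sources", "risk", "genotox")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages and write per-stage CSVs plus report.json."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario or with_seed(scenario_from_paper(), config.seed)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "lod_policy": config.lod_policy,
            "logistic_scale": config.logistic_scale,
            "p_enter": config.p_enter,
            "p_remove": config.p_remove,
            "equal_var": config.equal_var,
            "stages": list(config.stages),
            "samples_csv": str(config.samples_csv) if config.samples_csv else None,
            "cohort_csv": str(config.cohort_csv) if config.cohort_csv else None,
        },
    }

    samples: SampleSet | None = None
    if any(s in config.stages for s in ("describe", "sources", "genotox")):
        stage = "load_samples"
        try:
            if config.samples_csv is not None:
                log.info("[%s] reading %s", stage, config.samples_csv)
                samples = load_samples(config.samples_csv, lod_policy=config.lod_policy)
            else:
                log.info("[%s] generating synthetic samples (seed=%d)", stage, config.seed)
                samples = gen_school_samples(scenario, seed=config.seed)
                write_samples(samples, out_dir / "samples.csv")
        except Exception as e:  # noqa: BLE001 - tag and re-raise
            raise PipelineError(stage, e) from e

    if "describe" in config.stages:
        try:
            log.info("[describe] site summaries and I/O ratios")
            descriptive.write_descriptive_outputs(samples, out_dir)
            report["descriptive"] = {
                "site_totals": [vars(s) for s in descriptive.summarize_sites(samples)],
                "io_ratios": [vars(r) for r in descriptive.site_io_ratios(samples)],
            }
        except Exception as e:
            raise PipelineError("describe", e) from e
    else:
        report["descriptive"] = {"skipped": True}

    if "sources" in config.stages:
        try:
            log.info("[sources] diagnostic ratios and source calls")
            sources.write_source_outputs(samples, out_dir)
            report["sources"] = {
                "site_summary": sources.site_source_summary(samples).to_dict(orient="records")
            }
        except Exception as e:
            raise PipelineError("sources", e) from e
    else:
        report["sources"] = {"skipped": True}

    if "risk" in config.stages:
        try:
            log.info("[risk] Monte-Carlo ILCR (seed=%d, n=%d)", config.seed, config.n_iterations)
            reg = None
            teq_by_group = {}
            if samples is not None:
                from .core import species_registry

                reg = species_registry()
                for group in ("HT", "LT"):
                    vals = [risk.teq(p, reg) for p in samples if p.traffic_group == group]
                    if vals:
                        teq_by_group[group] = float(np.mean(vals))
            risk_section = {"teq_group_means": teq_by_group}
            for group, scen_fn in (("HT", risk.ht_scenario), ("LT", risk.lt_scenario)):
                specs = scen_fn(config.logistic_scale)
                res = mc_ilcr(specs, n_iterations=config.n_iterations, seed=config.seed)
                risk_section[group] = risk.write_risk_summary(
                    res, specs, out_dir / f"ilcr_summary_{group}.json"
                )
            report["risk"] = risk_section
        except Exception as e:
            raise PipelineError("risk", e) from e
    else:
        report["risk"] = {"skipped": True}

    if "genotox" in config.stages:
        try:
            log.info("[genotox] group comparisons and stepwise regression")
            if config.cohort_csv is not None:
                cohort = genotox.load_cohort(config.cohort_csv)
            else:
                cohort = gen_children(scenario, samples, seed=config.seed)
                genotox.write_cohort(cohort, out_dir / "cohort.csv")
            comparisons = [
                vars(genotox.compare_groups(cohort, v, equal_var=config.equal_var))
                for v in GROUP_COMPARISON_VARIABLES
                if cohort[v].nunique() >= 2 and cohort[v].value_counts().min() >= 2
            ]
            screen = genotox.simple_lr_screen(cohort, DEFAULT_CANDIDATES)
            screen.to_csv(out_dir / "simple_lr_screen.csv", index=False)
            significant = list(screen.loc[screen["significant"], "predictor"])
            model = genotox.stepwise_mlr(
                cohort, significant or DEFAULT_CANDIDATES,
                p_enter=config.p_enter, p_remove=config.p_remove,
            )
            report["genotox"] = {
                "group_comparisons": comparisons,
                "screen_significant": significant,
                "regression_model": model.to_json(out_dir / "regression_model.json"),
            }
            import pandas as pd

            pd.DataFrame(
                [
                    {"variable": c["variable"], "test": c["test"],
                     "statistic": c["statistic"], "p_value": c["p_value"]}
                    for c in comparisons
                ]
            ).to_csv(out_dir / "group_comparisons.csv", index=False)
        except Exception as e:
            raise PipelineError("genotox", e) from e
    else:
        report["genotox"] = {"skipped": True}

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    )
    return report
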