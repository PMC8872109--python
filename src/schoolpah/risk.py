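"""Toxicity-equivalent concentration (TEQ) and probabilistic inhalation
cancer risk (ILCR) with Monte-Carlo uncertainty and sensitivity analysis.

The TEQ re-expresses a PAH mixture as the benzo[a]pyrene concentration of
equal carcinogenic potency:

    TEQ = sum_s TEF(s) * C(s)        [ng m^-3]

The incremental lifetime cancer risk for chronic inhalation is

    ILCR = TEQ * cf * CSF * (BW/70)^(1/3) * IR * ED * EF / (BW * AT)

with CSF the benzo[a]pyrene inhalation cancer slope factor
((mg kg^-1 day^-1)^-1), body-weight-adjusted by the cube-root rule, IR the
inhalation rate (m^3 day^-1), ED the exposure duration (years), EF the
exposure frequency (days year^-1), AT the averaging time (days), BW the
body weight (kg) and cf = 1e-6 the ng->mg conversion.

The Monte-Carlo stage draws each symbol from a configured distribution
(constant, logistic, or lognormal parameterised by arithmetic mean/SD) and
summarises the risk draws by mean, median and 95th percentile; sensitivity
is the Spearman rank correlation between each varying input and the risk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .core import PAHProfile, SpeciesRegistry, species_registry

__all__ = [
    "RiskParameters",
    "DistributionSpec",
    "ILCRResult",
    "teq",
    "ilcr_point",
    "sample_distribution",
    "mc_ilcr",
    "sensitivity",
    "ht_scenario",
    "lt_scenario",
]

#: Reference adult body weight (kg) in the slope-factor adjustment.
REFERENCE_BW = 70.0

#: Default fraction of the mean used as the logistic scale when a scenario
#: gives only the arithmetic mean.  The MC mean is unaffected by this choice
#: (up to the truncation shift); percentiles depend on it.
DEFAULT_LOGISTIC_SCALE_FRACTION = 0.3

ILCR_VARIABLES = ("teq", "csf", "bw", "ir", "ed", "ef", "at", "cf")


@dataclass(frozen=True)
class RiskParameters:
    """Deterministic ILCR inputs (exposure-scenario defaults for children)."""

    bw: float  # body weight, kg
    csf: float = 3.85  # inhalation cancer slope factor, (mg/kg/day)^-1
    ir: float = 12.0  # inhalation rate, m^3/day
    ed: float = 6.0  # exposure duration, years
    ef: float = 250.0  # exposure frequency, days/year
    at: float = 25550.0  # averaging time, days (70 y x 365 d)
    cf: float = 1e-6  # ng -> mg conversion

    def __post_init__(self) -> None:
        for name in ("bw", "csf", "ir", "ed", "ef", "at", "cf"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def teq(profile: PAHProfile, registry: SpeciesRegistry | None = None) -> float:
    """TEF-weighted toxicity-equivalent concentration (ng m^-3)."""
    reg = registry or species_registry()
    return float(sum(reg.tef(code) * conc for code, conc in profile.concentrations.items()))


def ilcr_point(teq_value: float, params: RiskParameters) -> float:
    """Deterministic incremental lifetime cancer risk for a TEQ exposure."""
    if teq_value < 0:
        raise ValueError("TEQ must be >= 0")
    return (
        teq_value
        * params.cf
        * params.csf
        * (params.bw / REFERENCE_BW) ** (1.0 / 3.0)
        * params.ir
        * params.ed
        * params.ef
        / (params.bw * params.at)
    )


@dataclass(frozen=True)
class DistributionSpec:
    """Monte-Carlo distribution assignment for one ILCR symbol.

    kind ``constant``: params ``{"value": v}``.
    kind ``logistic``: params ``{"mean": m, "scale": s}`` (location = arithmetic mean).
    kind ``lognormal``: params ``{"mean": m, "sd": s}`` — arithmetic moments,
    moment-matched internally to (mu, sigma).
    ``truncate_low`` resamples draws below the bound (rejection sampling).
    """

    name: str
    kind: str
    params: Mapping[str, float]
    truncate_low: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "logistic", "lognormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        p = self.params
        if self.kind == "constant" and "value" not in p:
            raise ValueError("constant needs params['value']")
        if self.kind == "logistic":
            if p.get("scale", 0) <= 0:
                raise ValueError("logistic scale must be > 0")
        if self.kind == "lognormal":
            if p.get("mean", 0) <= 0 or p.get("sd", 0) <= 0:
                raise ValueError("lognormal arithmetic mean and SD must be > 0")

    @property
    def is_constant(self) -> bool:
        return self.kind == "constant"


def lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match arithmetic (mean, SD) to the underlying normal (mu, sigma)."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_distribution(
    spec: DistributionSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``spec``; identical (spec, n, seed) -> identical draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(k: int) -> np.ndarray:
        if spec.kind == "constant":
            return np.full(k, float(spec.params["value"]))
        if spec.kind == "logistic":
            return rng.logistic(spec.params["mean"], spec.params["scale"], size=k)
        mu, sigma = lognormal_mu_sigma(spec.params["mean"], spec.params["sd"])
        return rng.lognormal(mu, sigma, size=k)

    out = draw(n)
    if spec.truncate_low is not None:
        # rejection resampling keeps the in-bound distribution shape intact
        for _ in range(1000):
            bad = out < spec.truncate_low
            if not bad.any():
                break
            out[bad] = draw(int(bad.sum()))
        else:
            raise RuntimeError(f"{spec.name}: truncation rejection did not converge")
    return out


@dataclass
class ILCRResult:
    """Monte-Carlo ILCR draws with summary statistics and input draws."""

    draws: np.ndarray
    mean: float
    median: float
    p95: float
    n_iterations: int
    seed: int
    variable_draws: dict[str, np.ndarray] = field(default_factory=dict)

    def percentile(self, q: float) -> float:
        """Linear-interpolation percentile of the stored draws."""
        return float(np.percentile(self.draws, q))


def mc_ilcr(
    specs: Mapping[str, DistributionSpec], n_iterations: int = 10_000, seed: int = 0
) -> ILCRResult:
    """Monte-Carlo ILCR: draw every symbol per iteration and evaluate the model."""
    missing = [v for v in ILCR_VARIABLES if v not in specs]
    if missing:
        raise ValueError(f"missing distribution spec(s) for: {missing}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {v: sample_distribution(specs[v], n_iterations, rng) for v in ILCR_VARIABLES}
    ilcr = (
        draws["teq"]
        * draws["cf"]
        * draws["csf"]
        * (draws["bw"] / REFERENCE_BW) ** (1.0 / 3.0)
        * draws["ir"]
        * draws["ed"]
        * draws["ef"]
        / (draws["bw"] * draws["at"])
    )
    return ILCRResult(
        draws=ilcr,
        mean=float(ilcr.mean()),
        median=float(np.median(ilcr)),
        p95=float(np.percentile(ilcr, 95)),
        n_iterations=n_iterations,
        seed=seed,
        variable_draws=draws,
    )


def sensitivity(result: ILCRResult, specs: Mapping[str, DistributionSpec]) -> dict[str, float]:
    """Spearman rank correlation of each non-constant input with the ILCR draws."""
    varying = [v for v in result.variable_draws if not specs[v].is_constant]
    if not varying:
        raise ValueError("sensitivity undefined: all inputs are constant")
    out = {}
    for v in varying:
        rho = stats.spearmanr(result.variable_draws[v], result.draws).statistic
        out[v] = float(rho)
    return out


def _scenario(
    teq_mean: float, bw_mean: float, bw_sd: float, logistic_scale: float | None
) -> dict[str, DistributionSpec]:
    scale = logistic_scale if logistic_scale is not None else DEFAULT_LOGISTIC_SCALE_FRACTION * teq_mean
    return {
        "teq": DistributionSpec("teq", "logistic", {"mean": teq_mean, "scale": scale}, truncate_low=0.0),
        "bw": DistributionSpec("bw", "lognormal", {"mean": bw_mean, "sd": bw_sd}),
        "csf": DistributionSpec("csf", "constant", {"value": 3.85}),
        "ir": DistributionSpec("ir", "constant", {"value": 12.0}),
        "ed": DistributionSpec("ed", "constant", {"value": 6.0}),
        "ef": DistributionSpec("ef", "constant", {"value": 250.0}),
        "at": DistributionSpec("at", "constant", {"value": 25550.0}),
        "cf": DistributionSpec("cf", "constant", {"value": 1e-6}),
    }


def ht_scenario(logistic_scale: float | None = None) -> dict[str, DistributionSpec]:
    """High-traffic group scenario: TEQ logistic mean 2.32, BW LN(33.13, 14.54)."""
    return _scenario(2.32, 33.13, 14.54, logistic_scale)


def lt_scenario(logistic_scale: float | None = None) -> dict[str, DistributionSpec]:
    """Low-traffic group scenario: TEQ logistic mean 1.02, BW LN(28.33, 10.86)."""
    return _scenario(1.02, 28.33, 10.86, logistic_scale)


def write_risk_summary(
    result: ILCRResult,
    specs: Mapping[str, DistributionSpec],
    path: str | Path,
    percentiles: tuple[float, ...] = (5, 25, 50, 75, 95),
) -> dict:
    """Write ilcr_summary.json: summary stats, sensitivities and settings echo."""
    summary = {
        "mean": result.mean,
        "median": result.median,
        "p95": result.p95,
        "percentiles": {str(q): result.percentile(q) for q in percentiles},
        "sensitivity": sensitivity(result, specs),
        "settings": {
            "n_iterations": result.n_iterations,
            "seed": result.seed,
            "distributions": {
                v: {"kind": s.kind, "params": dict(s.params), "truncate_low": s.truncate_low}
                for v, s in specs.items()
            },
        },
    }
    Path(path).write_text(json.dumps(summary, indent=2))
    return summary
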