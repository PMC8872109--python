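"""Diagnostic concentration ratios and rule-based PAH source apportionment.

Four isomer-pair ratios distinguish petrogenic (unburned petroleum) from
pyrogenic (combustion) origins and, within traffic emissions, diesel from
gasoline exhaust:

=================  =====================================================
ANT/(ANT+PHE)      < 0.1 petrogenic; otherwise pyrogenic
IcP/(IcP+BgP)      > 0.2 pyrogenic contribution; otherwise petrogenic-leaning
BaA/(BaA+CYR)      < 0.2 petrogenic; 0.2-0.35 mixed; > 0.35 combustion
FLR/(FLR+PYR)      > 0.5 diesel emission; otherwise gasoline emission
=================  =====================================================

Threshold points fall on the side written above (strict inequalities for
the named side; both BaA/(BaA+CYR) boundaries fall into "mixed").  A ratio
whose denominator is zero is undefined (``None``), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import PAHProfile, SampleSet

__all__ = [
    "DiagnosticRatios",
    "SourceCall",
    "diagnostic_ratios",
    "classify_source",
    "site_source_summary",
]


@dataclass(frozen=True)
class DiagnosticRatios:
    ant_phe: float | None
    icp_bgp: float | None
    baa_cyr: float | None
    flr_pyr: float | None


@dataclass(frozen=True)
class SourceCall:
    origin: str  # petrogenic | pyrogenic | undefined
    pyro_support: str  # pyrogenic | petrogenic-leaning | undefined
    combustion: str  # petrogenic | mixed | combustion | undefined
    fuel: str  # diesel | gasoline | undefined


def _ratio(num: float, den_other: float) -> float | None:
    den = num + den_other
    return None if den == 0 else num / den


def diagnostic_ratios(profile: PAHProfile) -> DiagnosticRatios:
    """Compute the four source-diagnostic ratios for one sample."""
    return DiagnosticRatios(
        ant_phe=_ratio(profile.get("ANT"), profile.get("PHE")),
        icp_bgp=_ratio(profile.get("IcP"), profile.get("BgP")),
        baa_cyr=_ratio(profile.get("BaA"), profile.get("CYR")),
        flr_pyr=_ratio(profile.get("FLR"), profile.get("PYR")),
    )


def classify_source(ratios: DiagnosticRatios) -> SourceCall:
    """Apply the threshold rules to a set of diagnostic ratios."""
    if ratios.ant_phe is None:
        origin = "undefined"
    elif ratios.ant_phe < 0.1:
        origin = "petrogenic"
    else:
        origin = "pyrogenic"

    if ratios.icp_bgp is None:
        pyro = "undefined"
    elif ratios.icp_bgp > 0.2:
        pyro = "pyrogenic"
    else:
        pyro = "petrogenic-leaning"

    if ratios.baa_cyr is None:
        combustion = "undefined"
    elif ratios.baa_cyr < 0.2:
        combustion = "petrogenic"
    elif ratios.baa_cyr > 0.35:
        combustion = "combustion"
    else:
        combustion = "mixed"

    if ratios.flr_pyr is None:
        fuel = "undefined"
    elif ratios.flr_pyr > 0.5:
        fuel = "diesel"
    else:
        fuel = "gasoline"

    return SourceCall(origin=origin, pyro_support=pyro, combustion=combustion, fuel=fuel)


def site_source_summary(samples: SampleSet) -> pd.DataFrame:
    """Per-site counts and percentages of each source label.

    Undefined calls (zero denominator) are excluded from the percentage
    denominator and reported separately as ``n_undefined``.
    """
    rows = []
    for p in samples:
        call = classify_source(diagnostic_ratios(p))
        rows.append(
            {"site_id": p.site_id, "origin": call.origin, "pyro_support": call.pyro_support,
             "combustion": call.combustion, "fuel": call.fuel}
        )
    df = pd.DataFrame(rows)
    out = []
    for site, g in df.groupby("site_id"):
        for field in ("origin", "pyro_support", "combustion", "fuel"):
            counts = g[field].value_counts()
            n_undef = int(counts.get("undefined", 0))
            defined = counts.drop("undefined", errors="ignore")
            n_def = int(defined.sum())
            for label, n in defined.items():
                out.append(
                    {
                        "site_id": site,
                        "field": field,
                        "label": label,
                        "n": int(n),
                        "pct": 100.0 * n / n_def if n_def else float("nan"),
                        "n_undefined": n_undef,
                    }
                )
            if n_def == 0:
                out.append(
                    {"site_id": site, "field": field, "label": "undefined",
                     "n": 0, "pct": float("nan"), "n_undefined": n_undef}
                )
    return pd.DataFrame(out)


def write_source_outputs(samples: SampleSet, out_dir: str | Path) -> dict[str, Path]:
    """Write diagnostic_ratios.csv and source_calls.csv (undefined -> empty field)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ratio_rows, call_rows = [], []
    for p in samples:
        r = diagnostic_ratios(p)
        c = classify_source(r)
        ratio_rows.append(
            {"sample_id": p.sample_id, "site_id": p.site_id, "location": p.location}
            | {k: ("" if v is None else v) for k, v in vars(r).items()}
        )
        call_rows.append({"sample_id": p.sample_id, "site_id": p.site_id} | vars(c))
    paths = {
        "diagnostic_ratios": out_dir / "diagnostic_ratios.csv",
        "source_calls": out_dir / "source_calls.csv",
    }
    pd.DataFrame(ratio_rows).to_csv(paths["diagnostic_ratios"], index=False)
    pd.DataFrame(call_rows).to_csv(paths["source_calls"], index=False)
    return paths
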