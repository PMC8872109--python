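"""Species registry, sample data model, and CSV I/O for particulate PAH data.

The study quantifies 15 US-EPA priority PAHs in PM2.5 (naphthalene is
excluded for its volatility).  Each species carries an aromatic-ring count
used for the LMW/HMW split and a toxic equivalency factor (TEF) relative to
benzo[a]pyrene used for the TEQ computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PAHSpecies",
    "SpeciesRegistry",
    "PAHProfile",
    "SampleSet",
    "species_registry",
    "load_samples",
    "write_samples",
    "total_pah",
    "LOD_POLICIES",
]

#: Allowed below-detection substitution policies.
LOD_POLICIES = ("zero", "half_lod", "lod")

#: Token used in concentration CSVs for a value below the detection limit.
LOD_TOKEN = "<LOD"

#: Legacy species codes accepted on input and canonicalised.
SPECIES_ALIASES = {"ACE": "ACP", "IND": "IcP"}

CSV_COLUMNS = [
    "sample_id",
    "site_id",
    "traffic_group",
    "location",
    "species",
    "conc_ng_m3",
]


@dataclass(frozen=True)
class PAHSpecies:
    """One PAH species: short code, chemical name, ring count and TEF weight."""

    code: str
    name: str
    rings: int
    tef: float

    def __post_init__(self) -> None:
        if self.rings not in (3, 4, 5, 6):
            raise ValueError(f"{self.code}: ring count {self.rings} outside 3-6")
        if not self.tef > 0:
            raise ValueError(f"{self.code}: TEF must be positive")


# Ring counts per the LMW (3-ring) / HMW (4-6-ring) classification; TEF
# weights relative to BaP (=1), with dibenz[a,h]anthracene the most potent
# congener at 5.
_SPECIES = (
    PAHSpecies("ACY", "acenaphthylene", 3, 0.001),
    PAHSpecies("ACP", "acenaphthene", 3, 0.001),
    PAHSpecies("FLR", "fluorene", 3, 0.001),
    PAHSpecies("PHE", "phenanthrene", 3, 0.001),
    PAHSpecies("ANT", "anthracene", 3, 0.01),
    PAHSpecies("FLT", "fluoranthene", 4, 0.001),
    PAHSpecies("PYR", "pyrene", 4, 0.001),
    PAHSpecies("BaA", "benz[a]anthracene", 4, 0.1),
    PAHSpecies("CYR", "chrysene", 4, 0.01),
    PAHSpecies("BkF", "benzo[k]fluoranthene", 5, 0.1),
    PAHSpecies("BbF", "benzo[b]fluoranthene", 5, 0.1),
    PAHSpecies("BaP", "benzo[a]pyrene", 5, 1.0),
    PAHSpecies("DhA", "dibenz[a,h]anthracene", 5, 5.0),
    PAHSpecies("IcP", "indeno[1,2,3-cd]pyrene", 6, 0.1),
    PAHSpecies("BgP", "benzo[ghi]perylene", 6, 0.01),
)


class SpeciesRegistry:
    """Immutable lookup table of the 15 measured PAH species.

    Obtain the canonical instance via :func:`species_registry`.
    """

    def __init__(self, species: Iterable[PAHSpecies] = _SPECIES):
        species = tuple(species)
        codes = [s.code for s in species]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes in registry")
        self._by_code = {s.code: s for s in species}

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._by_code)

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def canonicalize(self, code: str) -> str:
        """Resolve legacy aliases (ACE, IND) to canonical codes.

        Raises ``KeyError`` for codes outside the study's species set
        (notably NAP, excluded for its volatility).
        """
        code = SPECIES_ALIASES.get(code, code)
        if code not in self._by_code:
            raise KeyError(f"unknown PAH species code: {code!r}")
        return code

    def species(self, code: str) -> PAHSpecies:
        return self._by_code[self.canonicalize(code)]

    def tef(self, code: str) -> float:
        return self.species(code).tef

    def rings(self, code: str) -> int:
        return self.species(code).rings

    def ring_members(self, rings: int) -> tuple[str, ...]:
        return tuple(c for c, s in self._by_code.items() if s.rings == rings)


_REGISTRY = SpeciesRegistry()


def species_registry() -> SpeciesRegistry:
    """Return the canonical immutable 15-species registry."""
    return _REGISTRY


@dataclass
class PAHProfile:
    """Per-species concentrations (ng m^-3) for one sample.

    Missing species are interpreted as not detected (contributing 0 to sums),
    not as errors.
    """

    sample_id: str
    site_id: str
    traffic_group: str
    location: str
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        reg = species_registry()
        canon: dict[str, float] = {}
        for code, value in self.concentrations.items():
            code = reg.canonicalize(code)
            value = float(value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{self.sample_id}/{code}: concentration must be finite and >= 0, got {value}"
                )
            if code in canon:
                raise ValueError(f"{self.sample_id}: duplicate species {code}")
            canon[code] = value
        self.concentrations = canon

    def get(self, code: str, default: float = 0.0) -> float:
        return self.concentrations.get(species_registry().canonicalize(code), default)


@dataclass
class SampleSet:
    """Ordered collection of profiles with free-form provenance metadata."""

    profiles: list[PAHProfile] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in SampleSet")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view, one row per (sample, detected species)."""
        rows = [
            {
                "sample_id": p.sample_id,
                "site_id": p.site_id,
                "traffic_group": p.traffic_group,
                "location": p.location,
                "species": code,
                "conc_ng_m3": conc,
            }
            for p in self.profiles
            for code, conc in p.concentrations.items()
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def total_pah(profile: PAHProfile) -> float:
    """Total PAH concentration: arithmetic sum over present species (ng m^-3)."""
    return float(sum(profile.concentrations.values()))


def _substitute_lod(policy: str, lod: float) -> float:
    if policy == "zero":
        return 0.0
    if policy == "half_lod":
        return lod / 2.0
    if policy == "lod":
        return lod
    raise ValueError(f"lod_policy must be one of {LOD_POLICIES}, got {policy!r}")


def load_samples(
    path: str | Path,
    lod_policy: str = "half_lod",
    lod_table: Mapping[str, float] | str | Path | None = None,
) -> SampleSet:
    """Read a long-format concentration CSV into a :class:`SampleSet`.

    Parameters
    ----------
    path
        CSV with header ``sample_id,site_id,traffic_group,location,species,conc_ng_m3``.
        ``conc_ng_m3`` is a non-negative decimal or the literal ``<LOD``.
    lod_policy
        Substitution rule for below-detection values: ``zero``, ``half_lod``
        (default) or ``lod``.
    lod_table
        Mapping species code -> LOD (ng m^-3), or path to a CSV with columns
        ``species,lod_ng_m3``.  Required if any value is ``<LOD``.
    """
    if lod_policy not in LOD_POLICIES:
        raise ValueError(f"lod_policy must be one of {LOD_POLICIES}, got {lod_policy!r}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    reg = species_registry()
    lods: dict[str, float] = {}
    if lod_table is not None:
        if isinstance(lod_table, (str, Path)):
            lod_df = pd.read_csv(lod_table)
            lod_table = dict(zip(lod_df["species"], lod_df["lod_ng_m3"]))
        lods = {reg.canonicalize(k): float(v) for k, v in lod_table.items()}

    profiles: dict[str, dict] = {}
    for i, row in df.iterrows():
        sample_id = str(row["sample_id"])
        code = reg.canonicalize(str(row["species"]))  # raises on unknown / NAP
        raw = str(row["conc_ng_m3"]).strip()
        if raw == LOD_TOKEN:
            if code not in lods:
                raise ValueError(f"row {i}: {LOD_TOKEN} value but no LOD for {code}")
            conc = _substitute_lod(lod_policy, lods[code])
        else:
            conc = float(raw)
            if conc < 0:
                raise ValueError(f"row {i}: negative concentration {conc} for {code}")
        entry = profiles.setdefault(
            sample_id,
            {
                "site_id": str(row["site_id"]),
                "traffic_group": str(row["traffic_group"]),
                "location": str(row["location"]),
                "conc": {},
            },
        )
        if code in entry["conc"]:
            raise ValueError(f"duplicate (sample_id, species) pair: ({sample_id}, {code})")
        entry["conc"][code] = conc

    out = [
        PAHProfile(
            sample_id=sid,
            site_id=e["site_id"],
            traffic_group=e["traffic_group"],
            location=e["location"],
            concentrations=e["conc"],
        )
        for sid, e in profiles.items()
    ]
    return SampleSet(profiles=out, metadata={"source": str(path), "lod_policy": lod_policy})


def write_samples(samples: SampleSet, path: str | Path) -> None:
    """Write a sample set back to the long CSV dialect read by :func:`load_samples`."""
    samples.to_frame().to_csv(path, index=False)
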