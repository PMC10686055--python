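"""Fermentation media: nitrogen accounting and theoretical CO2 capacity.

A synthetic grape must is described by its fermentable sugar load
(glucose + fructose, treated as a single hexose pool), its yeast
assimilable nitrogen (YAN) broken down by source class, and an optional
sulfate scaling for sulfur-limited variants.  Proline nitrogen is never
part of a :class:`MediumSpec`: it is not assimilated by yeast under
fermentative conditions, so medium configs are authored already
excluding it.

The theoretical CO2 capacity follows the fermentation stoichiometry of
2 mol CO2 per mol hexose.  Glucose and fructose are isomers, so a single
hexose molar mass covers an equimolar mix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "NitrogenSource",
    "MediumSpec",
    "total_nitrogen",
    "theoretical_co2_max",
    "make_sulfur_limited",
    "load_medium",
    "builtin_medium",
    "BUILTIN_MEDIA",
    "HEXOSE_MOLAR_MASS",
    "CO2_MOLAR_MASS",
    "CO2_MOL_PER_MOL_HEXOSE",
]

#: Average molar mass of C6H12O6 (g/mol); glucose and fructose share it.
HEXOSE_MOLAR_MASS = 180.156
#: Molar mass of CO2 (g/mol).
CO2_MOLAR_MASS = 44.0095
#: Fermentation stoichiometry: mol CO2 produced per mol hexose consumed.
CO2_MOL_PER_MOL_HEXOSE = 2.0

SOURCE_CLASSES = ("ammonium", "free_amino_acids", "peptides")


@dataclass(frozen=True)
class NitrogenSource:
    """One class of assimilable nitrogen, in mg N per litre."""

    source_class: str
    nitrogen_mg_per_l: float

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"unknown nitrogen source class {self.source_class!r}; "
                f"expected one of {SOURCE_CLASSES}"
            )
        if self.nitrogen_mg_per_l < 0:
            raise ValueError(
                f"nitrogen must be non-negative, got {self.nitrogen_mg_per_l}"
            )


@dataclass(frozen=True)
class MediumSpec:
    """A fermentation medium: sugars, nitrogen sources, sulfate scaling.

    Parameters
    ----------
    name
        Label, e.g. ``"NA100"``.
    sugar_g_per_l
        Total fermentable hexose (glucose + fructose), g/L.
    volume_l
        Working volume of the fermentation, litres.
    sources
        Nitrogen sources by class, mg N/L each.  Proline nitrogen is
        excluded by construction.
    sulfate_scale
        1.0 for a standard medium; in (0, 1) for a sulfur-limited
        variant (fraction of the standard sulfate concentration kept).
    k_mg_compensated
        Whether K and Mg lost with the sulfate salts were restored as
        chloride salts.  Annotation only; no salt chemistry is modelled.
    """

    name: str
    sugar_g_per_l: float
    volume_l: float
    sources: tuple[NitrogenSource, ...]
    sulfate_scale: float = 1.0
    k_mg_compensated: bool = False

    def __post_init__(self) -> None:
        if self.sugar_g_per_l <= 0:
            raise ValueError(f"sugar_g_per_l must be > 0, got {self.sugar_g_per_l}")
        if self.volume_l <= 0:
            raise ValueError(f"volume_l must be > 0, got {self.volume_l}")
        if not 0 < self.sulfate_scale <= 1:
            raise ValueError(
                f"sulfate_scale must be in (0, 1], got {self.sulfate_scale}"
            )
        object.__setattr__(self, "sources", tuple(self.sources))

    def nitrogen(self, source_class: str) -> float:
        """mg N/L contributed by one source class (0 if absent)."""
        return sum(
            s.nitrogen_mg_per_l for s in self.sources if s.source_class == source_class
        )


def total_nitrogen(medium: MediumSpec) -> float:
    """Total assimilable nitrogen of a medium, mg N per litre.

    The exact sum over the medium's nitrogen sources (ammonium, free
    amino acids, peptides); proline nitrogen never enters the sum
    because it is excluded from the spec itself.
    """
    return sum(s.nitrogen_mg_per_l for s in medium.sources)


def theoretical_co2_max(medium: MediumSpec) -> float:
    """Maximum theoretical CO2 production for the whole volume, grams.

    2 mol CO2 per mol hexose: ``2 * (sugar mass / 180.156) * 44.0095``.
    """
    sugar_mass_g = medium.sugar_g_per_l * medium.volume_l
    return (
        CO2_MOL_PER_MOL_HEXOSE * sugar_mass_g / HEXOSE_MOLAR_MASS * CO2_MOLAR_MASS
    )


def make_sulfur_limited(medium: MediumSpec, reduction_fraction: float) -> MediumSpec:
    """Derive a sulfur-limited variant of a medium.

    ``reduction_fraction`` is the fraction of sulfate removed (0.87 for
    an 87% reduction); the result carries ``sulfate_scale = 1 -
    reduction_fraction`` and is flagged as K/Mg-compensated (the lost
    potassium and magnesium are assumed restored as chlorides).
    Nitrogen sources and sugars are untouched.
    """
    if not 0 < reduction_fraction < 1:
        raise ValueError(
            f"reduction_fraction must be in (0, 1), got {reduction_fraction}"
        )
    return replace(
        medium,
        name=f"{medium.name}-SO4",
        sulfate_scale=1.0 - reduction_fraction,
        k_mg_compensated=True,
    )


def _medium_from_dict(cfg: dict) -> MediumSpec:
    nitrogen = cfg.get("nitrogen", {})
    unknown = set(nitrogen) - set(SOURCE_CLASSES)
    if unknown:
        raise ValueError(f"unknown nitrogen source classes in config: {sorted(unknown)}")
    sources = tuple(
        NitrogenSource(cls, float(nitrogen[cls]))
        for cls in SOURCE_CLASSES
        if cls in nitrogen
    )
    return MediumSpec(
        name=str(cfg["name"]),
        sugar_g_per_l=float(cfg["sugar_g_per_l"]),
        volume_l=float(cfg.get("volume_l", 0.1)),
        sources=sources,
        sulfate_scale=float(cfg.get("sulfate_scale", 1.0)),
        k_mg_compensated=bool(cfg.get("k_mg_compensated", False)),
    )


def load_medium(path: str | Path) -> MediumSpec:
    """Load a medium config from a YAML (or JSON) file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _medium_from_dict(cfg)


#: Names of the media shipped with the package.
BUILTIN_MEDIA = ("NA100", "NAP200", "P200", "P200-SO4")


def builtin_medium(name: str) -> MediumSpec:
    """Return one of the bundled media (NA100, NAP200, P200, P200-SO4)."""
    if name not in BUILTIN_MEDIA:
        raise KeyError(f"no bundled medium {name!r}; choose from {BUILTIN_MEDIA}")
    fname = name.replace("-SO4", "_SO4") + ".yaml"
    ref = resources.files("pepferm").joinpath("data", "media", fname)
    cfg = yaml.safe_load(ref.read_text())
    return _medium_from_dict(cfg)
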