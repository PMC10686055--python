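"""Seeded synthetic fermentation datasets with transporter structure.

The generator produces everything the analysis consumes — peptide/FAA
relative-abundance series, OD600 and cumulative-CO2 curves, and qPCR Ct
tables — with the statistical structure the scoring pipeline assumes:

* peptide depletion is first-order with an onset delay, and which
  lengths deplete is set by the strain's transporter genotype
  (Fot: lengths 2-4, early; Opt2: lengths 4-7 strongly and 2-3 weakly,
  delayed when preferred nitrogen and other transporters are present;
  Opt1 and Dal5 move no peptides here);
* a PP-like dipeptide control is non-transportable for every genotype;
* growth is logistic with a carrying capacity that rises with the
  nitrogen the genotype can actually reach, and cumulative CO2 follows
  a yield-limited model driven by biomass;
* transporter-gene expression is higher at 48 h than at 18 h, with
  OPT1 induced under sulfate limitation.

All stochastic draws come from one ``numpy`` generator seeded by the
scenario config: identical seed and config give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .consumption import AbundanceSeries
from .kinetics import CO2Curve, GrowthCurve
from .media import MediumSpec, theoretical_co2_max

__all__ = [
    "GenotypeProfile",
    "ScenarioConfig",
    "simulate_peptide_series",
    "simulate_growth_and_co2",
    "simulate_ct_table",
    "simulate_dataset",
    "DEFAULT_SCHEDULE",
    "STRAIN_TRANSPORTERS",
    "load_params",
]

#: Default sampling grid (h): every 6 h to 48 h, every 12 h to 96 h,
#: every 24 h to 168 h, plus endpoint checks at 240 and 288 h.
DEFAULT_SCHEDULE = tuple(
    list(range(0, 49, 6)) + list(range(60, 97, 12)) + list(range(120, 169, 24)) + [240, 288]
)

#: Transporter complements of the knockout/knockin strain panel.
STRAIN_TRANSPORTERS: Mapping[str, frozenset[str]] = {
    "59A": frozenset({"FOT1", "FOT2", "DAL5", "OPT1", "OPT2"}),
    "PepKO": frozenset(),
    "Opt1": frozenset({"OPT1"}),
    "Opt2": frozenset({"OPT2"}),
    "Fot1": frozenset({"FOT1"}),
    "Fot2": frozenset({"FOT2"}),
    "Fot3": frozenset({"FOT3"}),
    "Fot1Fot2": frozenset({"FOT1", "FOT2"}),
    "fot1fot2": frozenset({"DAL5", "OPT1", "OPT2"}),
    "opt1": frozenset({"FOT1", "FOT2", "DAL5", "OPT2"}),
    "opt2": frozenset({"FOT1", "FOT2", "DAL5", "OPT1"}),
}

_FOT_GENES = {"FOT1", "FOT2", "FOT3"}
PEPTIDE_LENGTHS = (2, 3, 4, 5, 6, 7)


def load_params() -> dict:
    """Load the versioned generator constants bundled with the package."""
    ref = resources.files("pepferm").joinpath("data", "simulator_params.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class GenotypeProfile:
    """A strain's transporter set and the uptake kinetics it implies.

    ``uptake`` maps each peptide length 2-7 to a first-order rate
    (per hour) and an onset delay (hours).  When several transporters
    cover the same length, the pair with the larger depletion potential
    ``rate * max(0, 72 - onset)`` wins (dominant-transporter
    approximation).
    """

    strain: str
    transporters: frozenset[str]
    uptake: Mapping[int, tuple[float, float]]

    def __post_init__(self) -> None:
        for length, (rate, onset) in self.uptake.items():
            if length not in PEPTIDE_LENGTHS:
                raise ValueError(f"peptide length must be 2-7, got {length}")
            if rate < 0 or onset < 0:
                raise ValueError("uptake rates and onsets must be non-negative")

    @classmethod
    def from_transporters(
        cls,
        strain: str,
        transporters: frozenset[str] | set[str],
        medium: MediumSpec,
        params: Optional[dict] = None,
    ) -> "GenotypeProfile":
        """Derive per-length uptake kinetics from a transporter set.

        Fot transporters cover lengths 2-4 from early fermentation.
        Opt2 covers 4-7 strongly and 2-3 weakly; its onset is pushed
        back when the medium holds preferred nitrogen (ammonium) *and*
        the genotype carries other peptide transporters — uptake of
        longer peptides is then secondary to easier sources.  Opt1 and
        Dal5 contribute no peptide uptake (Opt1 moved no peptides in
        the conditions emulated here).
        """
        params = params or load_params()
        tp = params["transporters"]
        transporters = frozenset(transporters)
        candidates: dict[int, list[tuple[float, float]]] = {L: [] for L in PEPTIDE_LENGTHS}
        if transporters & _FOT_GENES:
            spec = tp["fot"]
            for L in spec["lengths"]:
                candidates[L].append((spec["rate_per_h"], spec["onset_h"]))
        if "OPT2" in transporters:
            others = transporters - {"OPT2"}
            gated = bool(others) and medium.nitrogen("ammonium") > 0
            extra = params["opt2_preferred_n_extra_onset_h"] if gated else 0.0
            for key in ("opt2_strong", "opt2_weak"):
                spec = tp[key]
                for L in spec["lengths"]:
                    candidates[L].append((spec["rate_per_h"], spec["onset_h"] + extra))
        uptake = {}
        for L, opts in candidates.items():
            if not opts:
                uptake[L] = (0.0, 0.0)
            else:
                uptake[L] = max(opts, key=lambda ro: ro[0] * max(0.0, 72.0 - ro[1]))
        return cls(strain=strain, transporters=transporters, uptake=uptake)

    def accessible_nitrogen(self, medium: MediumSpec, params: Optional[dict] = None) -> float:
        """mg N/L the genotype can reach: ammonium + FAA + peptide N
        weighted by the fraction of each length class depleted by 72 h
        (peptide nitrogen is assumed uniform over lengths 2-7)."""
        frac = np.mean(
            [
                1.0 - np.exp(-rate * max(0.0, 72.0 - onset))
                for rate, onset in (self.uptake[L] for L in PEPTIDE_LENGTHS)
            ]
        )
        return (
            medium.nitrogen("ammonium")
            + medium.nitrogen("free_amino_acids")
            + float(frac) * medium.nitrogen("peptides")
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated fermentation: medium, genotype, noise, seed, grid."""

    medium: MediumSpec
    genotype: GenotypeProfile
    noise_sigma: float = 0.05
    seed: int = 0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        sched = tuple(float(t) for t in self.schedule)
        if sched[0] != 0 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must start at 0 and increase strictly")
        object.__setattr__(self, "schedule", sched)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for one output stream."""
        ss = np.random.SeedSequence(
            [self.seed, abs(hash_stable(stream)) % (2**31)]
        )
        return np.random.default_rng(ss)


def hash_stable(text: str) -> int:
    """Deterministic 31-bit hash of a short label (not security-related)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def scenario(
    strain: str,
    medium: MediumSpec,
    noise_sigma: float = 0.05,
    seed: int = 0,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    params: Optional[dict] = None,
) -> ScenarioConfig:
    """Convenience constructor from a strain name in the panel."""
    if strain not in STRAIN_TRANSPORTERS:
        raise KeyError(f"unknown strain {strain!r}; choose from {sorted(STRAIN_TRANSPORTERS)}")
    genotype = GenotypeProfile.from_transporters(
        strain, STRAIN_TRANSPORTERS[strain], medium, params
    )
    return ScenarioConfig(
        medium=medium,
        genotype=genotype,
        noise_sigma=noise_sigma,
        seed=seed,
        schedule=tuple(schedule),
    )


def _depletion(times: np.ndarray, rate: float, onset: float) -> np.ndarray:
    return 100.0 * np.exp(-rate * np.maximum(0.0, times - onset))


def simulate_peptide_series(
    config: ScenarioConfig, params: Optional[dict] = None
) -> list[AbundanceSeries]:
    """Generate the monitored analyte panel as relative-abundance series.

    Panel composition follows the bundled fixture (18 FAAs; 19 di-, 29
    tri-, and smaller tetra- to heptapeptide groups); one dipeptide
    (``pep2_PP``) is non-transportable for every genotype.  Each series
    is ``100 * exp(-rate * max(0, t - onset))`` with multiplicative
    lognormal noise after t=0; the t=0 sample is exactly 100.
    """
    params = params or load_params()
    t = np.asarray(config.schedule, dtype=float)
    rng = config.rng("peptides")
    sigma = config.noise_sigma
    out: list[AbundanceSeries] = []

    def noisy(values: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return values
        factors = np.exp(rng.normal(0.0, sigma, size=values.size))
        factors[0] = 1.0
        return values * factors

    faa = params["faa"]
    for i in range(params["panel"]["n_faa"]):
        vals = noisy(_depletion(t, faa["rate_per_h"], faa["onset_h"]))
        out.append(
            AbundanceSeries(
                analyte_id=f"faa_{i + 1:02d}", kind="free_amino_acid", length=1,
                times=t, abundance=vals,
            )
        )
    for length, count in sorted(params["panel"]["peptides"].items()):
        rate, onset = config.genotype.uptake[int(length)]
        for i in range(count):
            analyte_id = f"pep{length}_{i + 1:02d}"
            r_i, o_i = rate, onset
            if int(length) == 2 and i == count - 1:
                analyte_id = "pep2_PP"  # non-transportable control
                r_i, o_i = 0.0, 0.0
            vals = noisy(_depletion(t, r_i, o_i))
            out.append(
                AbundanceSeries(
                    analyte_id=analyte_id, kind="peptide", length=int(length),
                    times=t, abundance=vals,
                )
            )
    return out


def simulate_growth_and_co2(
    config: ScenarioConfig, params: Optional[dict] = None
) -> tuple[GrowthCurve, CO2Curve]:
    """Logistic growth plus yield-limited cumulative CO2.

    The carrying capacity rises linearly with the nitrogen the genotype
    can access; CO2 production is proportional to biomass and saturates
    toward an attainable maximum ``A = theoretical max * min(1,
    N_accessible / N_ref)``.  Genotypes with (almost) no accessible
    nitrogen on peptide-only media therefore never approach 80%
    attenuation.  OD noise is multiplicative; CO2 noise is applied to
    increments so cumulative curves stay monotone.
    """
    params = params or load_params()
    g = params["growth"]
    t = np.asarray(config.schedule, dtype=float)
    n_acc = config.genotype.accessible_nitrogen(config.medium, params)
    k = g["k_base"] + g["k_per_mg_n"] * n_acc
    n0, r = g["od_init"], g["r_per_h"]
    od = k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))

    a_max = theoretical_co2_max(config.medium) * min(1.0, n_acc / g["n_ref_mg_per_l"])
    # integral of logistic biomass, closed form
    integral = (k / r) * np.log((k - n0 + n0 * np.exp(r * t)) / k)
    if a_max > 1e-12:
        co2 = a_max * (1.0 - np.exp(-g["co2_alpha"] * integral / a_max))
    else:
        co2 = np.zeros_like(t)

    sigma = config.noise_sigma
    if sigma > 0:
        rng = config.rng("growth")
        od = od * np.exp(rng.normal(0.0, sigma, size=od.size))
        inc = np.diff(co2, prepend=0.0)
        inc = inc * np.exp(rng.normal(0.0, sigma, size=inc.size))
        co2 = np.cumsum(inc)
    return GrowthCurve(times=t, od=od), CO2Curve(times=t, co2_g=co2)


def simulate_ct_table(
    config: ScenarioConfig, params: Optional[dict] = None
) -> pd.DataFrame:
    """qPCR Ct records (technical duplicates) at 18 h and 48 h.

    ACT1 sits at a constant Ct; each transporter gene present in the
    genotype gets Ct values implying normalized expression below the
    48-h value at 18 h, an OPT1 boost under sulfate limitation, and
    OPT2 damping when ammonium is present.
    """
    params = params or load_params()
    c = params["ct"]
    rng = config.rng("ct")
    ct_sd = c["ct_noise_sd"] if config.noise_sigma > 0 else 0.0
    genes = sorted(config.genotype.transporters & {"DAL5", "OPT1", "OPT2", "FOT1", "FOT2"})
    rows = []
    for time_h in (18, 48):
        sample_id = f"{config.genotype.strain}_{config.medium.name}_{time_h}h"
        for gene in [ "ACT1", *genes]:
            if gene == "ACT1":
                expr = 1.0
            else:
                expr = c["expr_18h"] if time_h == 18 else c["expr_48h"]
                if gene == "OPT1" and config.medium.sulfate_scale < 1:
                    expr *= c["opt1_sulfate_boost"]
                if gene == "OPT2" and config.medium.nitrogen("ammonium") > 0:
                    expr *= c["opt2_preferred_n_repression"]
            ct_true = c["act1_ct"] - np.log2(expr)
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "strain": config.genotype.strain,
                        "medium": config.medium.name,
                        "time_h": time_h,
                        "gene": gene,
                        "replicate": rep,
                        "ct": float(ct_true + rng.normal(0.0, ct_sd)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_dataset(config: ScenarioConfig, params: Optional[dict] = None) -> dict:
    """Generate all four tables for one scenario, in reader schemas.

    Returns a dict with DataFrames ``peptides`` (long abundance table),
    ``od``, ``co2``, ``ct`` and a ``config`` echo dict.
    """
    params = params or load_params()
    series = simulate_peptide_series(config, params)
    growth, co2 = simulate_growth_and_co2(config, params)
    strain, medium = config.genotype.strain, config.medium.name
    pep_rows = []
    for s in series:
        for ti, ai in zip(s.times, s.abundance):
            pep_rows.append(
                {
                    "strain": strain, "medium": medium, "analyte_id": s.analyte_id,
                    "kind": s.kind, "length": s.length,
                    "time_h": float(ti), "abundance_pct": float(ai),
                }
            )
    sample = f"{strain}_{medium}"
    od_df = pd.DataFrame(
        {
            "sample_id": sample, "strain": strain, "medium": medium,
            "time_h": growth.times, "od600": growth.od,
        }
    )
    co2_df = pd.DataFrame(
        {
            "sample_id": sample, "strain": strain, "medium": medium,
            "time_h": co2.times, "co2_g": co2.co2_g,
        }
    )
    echo = {
        "strain": strain,
        "medium": medium,
        "transporters": sorted(config.genotype.transporters),
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
        "schedule_h": list(config.schedule),
        "params_version": params["version"],
    }
    return {
        "peptides": pd.DataFrame(pep_rows),
        "od": od_df,
        "co2": co2_df,
        "ct": simulate_ct_table(config, params),
        "config": echo,
    }
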