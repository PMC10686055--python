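"""Consumption scoring of peptide and free-amino-acid depletion curves.

Each analyte's MS response over the fermentation is expressed relative
to its response at inoculation (100%).  Scoring then proceeds in four
steps:

1. **Normalize** — abundance = 100 x raw/raw(0), capped at 100%; the
   pre-capping maximum ratio is retained because the exclusion filter
   keys on it.
2. **Filter** — analytes whose raw signal ever rises more than 20%
   above the start are *excluded* (signal not behaving as a depleting
   substrate); a drop of at least 20% at any point counts as
   *consumption*; otherwise the analyte is *unchanged*.
3. **AUC** — trapezoidal area under the capped abundance curve over the
   first 72 h, as a fraction of a virtual negative control that stays
   at 100% for the whole window (control AUC = 100 x 72).
4. **Level** — the AUC fraction is banded into consumption levels 0-4:
   level 0 for >= 80% of the control, then 20-percent-point bands down
   to level 4 below 20%.

The same procedure applies to free amino acids (length class 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceSeries",
    "ConsumptionResult",
    "normalize_series",
    "classify_status",
    "auc_fraction",
    "assign_level",
    "score_series",
    "score_table",
    "consumption_matrix",
    "level_summary",
    "HORIZON_H",
    "EXCLUSION_INCREASE",
    "CONSUMPTION_REDUCTION",
    "LEVEL_EDGES",
]

#: Scoring window (h); the virtual negative control is defined over it.
HORIZON_H = 72.0
#: Raw-signal increase (fraction of start) beyond which an analyte is excluded.
EXCLUSION_INCREASE = 0.20
#: Minimum reduction (fraction of start) counted as consumption.
CONSUMPTION_REDUCTION = 0.20
#: Lower edges of levels 0..3; below the last edge is level 4.
LEVEL_EDGES = (0.80, 0.60, 0.40, 0.20)

Status = Literal["consumed", "excluded", "unchanged"]


@dataclass(frozen=True)
class AbundanceSeries:
    """One analyte's relative-abundance time course.

    ``abundance`` is percent of the initial response, capped at 100;
    ``raw_max_ratio`` is the pre-capping maximum raw/raw(0) ratio, kept
    for the exclusion filter.  ``length`` is the residue count for
    peptides and 1 for free amino acids.
    """

    analyte_id: str
    kind: Literal["peptide", "free_amino_acid"]
    length: int
    times: np.ndarray
    abundance: np.ndarray
    raw_max_ratio: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.abundance, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and abundance must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("need at least two time points")
        if t[0] != 0:
            raise ValueError("series must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("abundance must be non-negative")
        if self.kind == "free_amino_acid" and self.length != 1:
            raise ValueError("free amino acids have length class 1")
        if self.kind == "peptide" and not 2 <= self.length <= 7:
            raise ValueError("peptide length class must be 2-7")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "abundance", a)


@dataclass(frozen=True)
class ConsumptionResult:
    """Scoring outcome for one analyte.

    ``level`` is present iff the analyte was not excluded; excluded
    analytes keep their AUC fraction for reference but no level.
    """

    analyte_id: str
    status: Status
    auc_fraction: float
    level: Optional[int]

    def __post_init__(self) -> None:
        if (self.level is None) != (self.status == "excluded"):
            raise ValueError("level must be present iff status != excluded")


def normalize_series(
    raw_responses: Sequence[float],
    times: Sequence[float],
    analyte_id: str = "analyte",
    kind: Literal["peptide", "free_amino_acid"] = "peptide",
    length: int = 2,
) -> AbundanceSeries:
    """Scale a raw response curve to percent-of-start, capped at 100.

    The raw maximum ratio (max raw / raw at t=0) is recorded on the
    returned series *before* capping so the >20%-increase exclusion
    test still sees it.
    """
    raw = np.asarray(raw_responses, dtype=float)
    t = np.asarray(times, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least two time points")
    if raw[0] <= 0:
        raise ValueError("raw response at t = 0 must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    rel = 100.0 * raw / raw[0]
    ratio = float(np.max(raw) / raw[0])
    return AbundanceSeries(
        analyte_id=analyte_id,
        kind=kind,
        length=length,
        times=t,
        abundance=np.minimum(rel, 100.0),
        raw_max_ratio=ratio,
    )


def classify_status(
    series: AbundanceSeries, raw_max_ratio: Optional[float] = None
) -> Status:
    """Apply the 20% filters: excluded / consumed / unchanged.

    Exclusion uses the pre-capping raw maximum (strictly more than a
    20% increase); consumption uses the capped curve (a reduction of at
    least 20%, i.e. minimum abundance <= 80%).
    """
    ratio = series.raw_max_ratio if raw_max_ratio is None else raw_max_ratio
    if ratio > 1.0 + EXCLUSION_INCREASE:
        return "excluded"
    if float(np.min(series.abundance)) <= 100.0 * (1.0 - CONSUMPTION_REDUCTION):
        return "consumed"
    return "unchanged"


def _restrict_to_horizon(series: AbundanceSeries, horizon: float):
    t, a = series.times, series.abundance
    if t[-1] < horizon:
        raise ValueError(
            f"series ends at {t[-1]} h, before the {horizon} h scoring window"
        )
    mask = t <= horizon
    tt = t[mask]
    aa = a[mask]
    if tt[-1] < horizon:
        # complete the window by linear interpolation
        a_h = float(np.interp(horizon, t, a))
        tt = np.append(tt, horizon)
        aa = np.append(aa, a_h)
    return tt, aa


def auc_fraction(series: AbundanceSeries, horizon: float = HORIZON_H) -> float:
    """Trapezoidal AUC over [0, horizon] as a fraction of the control.

    The virtual negative control sits at 100% abundance for the whole
    window, so its AUC is ``100 * horizon``.  Samples beyond the
    horizon are ignored; if no sample falls exactly on the horizon the
    curve is linearly interpolated there.
    """
    tt, aa = _restrict_to_horizon(series, horizon)
    area = float(np.trapezoid(aa, tt))
    return area / (100.0 * horizon)


def assign_level(fraction: float) -> int:
    """Band an AUC fraction into a consumption level 0-4.

    [0.80, 1] -> 0; [0.60, 0.80) -> 1; [0.40, 0.60) -> 2;
    [0.20, 0.40) -> 3; [0, 0.20) -> 4.  Bands are closed at their lower
    edge (a fraction of exactly 0.60 is level 1).
    """
    if not -1e-12 <= fraction <= 1.0 + 1e-9:
        raise ValueError(f"auc fraction must be in [0, 1], got {fraction}")
    for level, edge in enumerate(LEVEL_EDGES):
        if fraction >= edge:
            return level
    return 4


def score_series(series: AbundanceSeries, horizon: float = HORIZON_H) -> ConsumptionResult:
    """Full scoring of one normalized series: status, AUC fraction, level."""
    status = classify_status(series)
    frac = auc_fraction(series, horizon)
    level = None if status == "excluded" else assign_level(frac)
    return ConsumptionResult(
        analyte_id=series.analyte_id, status=status, auc_fraction=frac, level=level
    )


def score_table(df: pd.DataFrame, horizon: float = HORIZON_H) -> pd.DataFrame:
    """Score a long-format abundance table.

    Required columns: ``analyte_id, kind, length, time_h,
    abundance_pct`` plus optional grouping columns ``strain`` and
    ``medium``.  Values are treated as raw relative responses and
    re-normalized per analyte (so a start value of 100 passes through
    unchanged).  Returns one row per (group, analyte) with status, AUC
    fraction and level, deterministically ordered.
    """
    required = {"analyte_id", "kind", "length", "time_h", "abundance_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["length"].isna().any():
        raise ValueError("every analyte needs a length class")
    group_cols = [c for c in ("strain", "medium") if c in df.columns]
    rows = []
    keys = group_cols + ["analyte_id"]
    for key, sub in df.sort_values(keys + ["time_h"]).groupby(keys, sort=True):
        key = (key,) if len(keys) == 1 else key
        sub = sub.reset_index(drop=True)
        series = normalize_series(
            sub["abundance_pct"].to_numpy(),
            sub["time_h"].to_numpy(),
            analyte_id=str(key[-1]),
            kind=str(sub["kind"].iloc[0]),
            length=int(sub["length"].iloc[0]),
        )
        res = score_series(series, horizon)
        row = dict(zip(keys, key))
        row.update(
            length_class=series.length,
            kind=series.kind,
            status=res.status,
            auc_fraction=res.auc_fraction,
            level=res.level if res.level is not None else pd.NA,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["level"] = out["level"].astype("Int64")
    return out


def consumption_matrix(df: pd.DataFrame, horizon: float = HORIZON_H):
    """Score a dataset and aggregate by strain x medium x length class.

    Returns ``(results, summary)``: the long per-analyte results table
    from :func:`score_table`, and a per-length-class summary with the
    median level and per-level counts, mirroring the strain x
    peptide-length consumption matrices used to compare transporter
    genotypes.
    """
    results = score_table(df, horizon)
    summary = level_summary(results)
    return results, summary


def level_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate scored analytes per group and length class."""
    group_cols = [c for c in ("strain", "medium") if c in results.columns]
    keys = group_cols + ["length_class"]
    scored = results[results["status"] != "excluded"]
    rows = []
    for key, sub in scored.groupby(keys, sort=True):
        key = (key,) if len(keys) == 1 else key
        row = dict(zip(keys, key))
        levels = sub["level"].astype(int)
        row["n_analytes"] = len(sub)
        row["median_level"] = float(np.median(levels))
        for lv in range(5):
            row[f"n_level_{lv}"] = int((levels == lv).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_level_heatmap(results: pd.DataFrame, path=None, ax=None):
    """Render a strain x analyte heatmap colored by consumption level.

    Excluded analytes appear blank.  Returns the matplotlib Axes; if
    ``path`` is given the figure is also saved (SVG/PNG by extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "strain" not in results.columns:
        results = results.assign(strain="all")
    pivot = results.pivot_table(
        index="strain",
        columns="analyte_id",
        values="level",
        aggfunc="first",
        observed=True,
    )
    order = (
        results.drop_duplicates("analyte_id")
        .sort_values(["length_class", "analyte_id"])["analyte_id"]
        .tolist()
    )
    pivot = pivot.reindex(columns=order)
    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(6, 0.18 * pivot.shape[1]), max(2, 0.4 * pivot.shape[0]))
        )
    im = ax.imshow(pivot.to_numpy(dtype=float), aspect="auto", cmap="viridis", vmin=0, vmax=4)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_xlabel("analyte (grouped by length class)")
    ax.figure.colorbar(im, ax=ax, label="consumption level")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
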