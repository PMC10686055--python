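"""TSV readers/writers for the pipeline's tabular interfaces.

All tables are plain tab-separated text with header rows.  The
abundance reader accepts either the long layout (one row per analyte
and time point) or a wide layout (one column per time point, named
like ``t0``, ``t6`` ... or plain numbers); the dialect is detected from
the header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_od_table",
    "read_co2_table",
    "read_ct_table",
    "write_table",
]

_ABUNDANCE_LONG = {"analyte_id", "kind", "length", "time_h", "abundance_pct"}
_OD_COLS = {"sample_id", "time_h", "od600"}
_CO2_COLS = {"sample_id", "time_h", "co2_g"}
_CT_COLS = {"sample_id", "gene", "replicate", "ct"}


def _require(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what} table is missing columns {sorted(missing)}")


def _parse_time_column(name: str) -> float | None:
    s = name[1:] if name.startswith(("t", "T")) else name
    try:
        return float(s)
    except ValueError:
        return None


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read an abundance TSV (long or wide) into the long layout."""
    df = pd.read_csv(path, sep="\t")
    if _ABUNDANCE_LONG <= set(df.columns):
        return df
    # wide layout: id columns + one column per time point
    time_cols = {c: _parse_time_column(c) for c in df.columns}
    value_cols = [c for c, t in time_cols.items() if t is not None]
    if not value_cols:
        raise ValueError(
            "abundance table is neither long (analyte_id/kind/length/"
            "time_h/abundance_pct) nor wide (time-point columns)"
        )
    id_cols = [c for c in df.columns if c not in value_cols]
    if "analyte_id" not in id_cols:
        raise ValueError("wide abundance table needs an analyte_id column")
    long = df.melt(
        id_vars=id_cols, value_vars=value_cols,
        var_name="_time", value_name="abundance_pct",
    )
    long["time_h"] = long["_time"].map(time_cols)
    long = long.drop(columns="_time")
    if "kind" not in long.columns:
        long["kind"] = "peptide"
    if "length" not in long.columns:
        raise ValueError("wide abundance table needs a length column")
    return long.sort_values(["analyte_id", "time_h"]).reset_index(drop=True)


def write_abundance_table(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, _ABUNDANCE_LONG, "abundance")
    df.to_csv(path, sep="\t", index=False)


def read_od_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, _OD_COLS, "OD600")
    return df


def read_co2_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, _CO2_COLS, "CO2")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, _CT_COLS, "Ct")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any pipeline table as TSV (no index column)."""
    df.to_csv(path, sep="\t", index=False)
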