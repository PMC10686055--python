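"""qPCR expression of peptide-transporter genes, normalized to ACT1.

Transporter-gene transcription (DAL5, OPT1, OPT2, FOT1, FOT2) is
quantified by real-time PCR at 18 h (early exponential phase) and 48 h
(early stationary phase).  Technical replicates are averaged on the Ct
scale — equivalent to a geometric mean on the expression scale — and
each gene's Ct is referenced to the housekeeping gene ACT1 of the same
sample:

    expression = efficiency ** -(Ct_gene - Ct_ACT1)

with a default amplification efficiency of 2.0 (perfect doubling per
cycle); per-gene efficiencies can be supplied.  The result is in
arbitrary units (AU): 1.0 means the gene amplifies like ACT1.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

__all__ = ["normalize_to_act1", "HOUSEKEEPING_GENE"]

HOUSEKEEPING_GENE = "ACT1"

#: Columns identifying one biological sample.
_SAMPLE_COLS = ["sample_id", "strain", "medium", "time_h"]


def normalize_to_act1(
    records: pd.DataFrame,
    efficiency: float = 2.0,
    efficiencies: Optional[Mapping[str, float]] = None,
    qc_ct_spread: float = 0.5,
) -> pd.DataFrame:
    """Delta-Ct normalization of a long Ct table against ACT1.

    Parameters
    ----------
    records
        Long table with columns ``sample_id, gene, replicate, ct`` and
        optionally ``strain, medium, time_h`` (carried through).  Every
        sample must include ACT1.
    efficiency
        Default per-cycle amplification factor (2.0 = 100% efficiency).
    efficiencies
        Optional per-gene overrides, e.g. ``{"OPT1": 1.93}``.
    qc_ct_spread
        Technical replicates further apart than this many cycles flag
        the value (``qc_flag=True``); the value is still reported.

    Returns
    -------
    DataFrame with one row per sample x gene (ACT1 excluded):
    ``normalized_expression`` in AU plus ``qc_flag``.
    """
    required = {"sample_id", "gene", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    effs = dict(efficiencies or {})

    carry = [c for c in _SAMPLE_COLS if c in records.columns]
    # technical replicates: mean and spread on the Ct scale
    agg = (
        records.groupby(carry + ["gene"], sort=True)["ct"]
        .agg(ct_mean="mean", ct_spread=lambda s: s.max() - s.min())
        .reset_index()
    )
    rows = []
    for key, sub in agg.groupby("sample_id", sort=True):
        sub = sub.set_index("gene")
        if HOUSEKEEPING_GENE not in sub.index:
            raise ValueError(f"sample {key!r} has no {HOUSEKEEPING_GENE} Ct")
        ct_ref = float(sub.loc[HOUSEKEEPING_GENE, "ct_mean"])
        ref_spread = float(sub.loc[HOUSEKEEPING_GENE, "ct_spread"])
        for gene, rec in sub.iterrows():
            if gene == HOUSEKEEPING_GENE:
                continue
            eff = float(effs.get(gene, efficiency))
            if eff <= 1:
                raise ValueError(f"amplification efficiency must exceed 1, got {eff}")
            delta = float(rec["ct_mean"]) - ct_ref
            row = {c: rec[c] for c in carry if c != "sample_id"}
            row.update(
                sample_id=key,
                gene=gene,
                normalized_expression=eff ** (-delta),
                qc_flag=bool(
                    rec["ct_spread"] > qc_ct_spread or ref_spread > qc_ct_spread
                ),
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    ordered = ["sample_id"] + [c for c in carry if c != "sample_id"] + [
        "gene",
        "normalized_expression",
        "qc_flag",
    ]
    return out[ordered].sort_values(["sample_id", "gene"]).reset_index(drop=True)
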