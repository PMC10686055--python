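"""Monoisotopic mass arithmetic and composition-level peptide identity.

High-resolution MS of a protein hydrolysate identifies small peptides at
the level of *length and amino-acid composition*, not sequence: every
permutation of a residue multiset has the same neutral mass.  This
module provides the forward calculation (composition -> neutral
monoisotopic mass) and the inverse search (neutral mass -> all residue
multisets of length 2-7 within a ppm tolerance).

Leucine and isoleucine are exactly isobaric, so they form a single
equivalence class reported as ``[I/L]``; lysine and glutamine differ by
0.03638 Da and remain distinct (resolvable at a few ppm for short
peptides).  Charge states and adducts are out of scope: inputs are
neutral monoisotopic masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "ResidueMassTable",
    "PeptideComposition",
    "peptide_mass",
    "enumerate_compositions",
    "identify_composition_table",
    "format_composition",
    "parse_composition",
    "DEFAULT_TABLE",
]

ISOLEUCINE_LEUCINE = "I/L"


def _default_class_masses() -> dict[str, float]:
    aa = _pmass.std_aa_mass
    classes = {}
    for r in "ACDEFGHKMNPQRSTVWY":
        classes[r] = aa[r]
    classes[ISOLEUCINE_LEUCINE] = aa["I"]  # identical to aa['L']
    return classes


@dataclass(frozen=True)
class ResidueMassTable:
    """Immutable residue-class -> monoisotopic mass map plus water mass.

    The default table merges I and L into the ``[I/L]`` class (19
    classes for the 20 proteinogenic residues); masses come from the
    standard monoisotopic residue table.
    """

    masses: Mapping[str, float]
    water: float

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("residue masses must be positive")
        object.__setattr__(self, "masses", MappingProxyType(dict(self.masses)))

    @property
    def alphabet(self) -> tuple[str, ...]:
        """Residue classes in deterministic (sorted) order."""
        return tuple(sorted(self.masses))

    def canonical(self, residue: str) -> str:
        """Map a residue symbol to its class ('I' and 'L' -> 'I/L')."""
        if residue in ("I", "L", ISOLEUCINE_LEUCINE):
            return ISOLEUCINE_LEUCINE
        if residue not in self.masses:
            raise KeyError(f"unknown residue symbol {residue!r}")
        return residue


DEFAULT_TABLE = ResidueMassTable(
    masses=_default_class_masses(),
    water=_pmass.calculate_mass(formula="H2O"),
)

MIN_LENGTH, MAX_LENGTH = 2, 7


@dataclass(frozen=True)
class PeptideComposition:
    """A residue multiset of length 2-7, the unit of peptide identity.

    ``counts`` maps residue classes to non-negative counts; I and L are
    folded into the ``I/L`` class on construction.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        folded: dict[str, int] = {}
        for res, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for residue {res!r}")
            if n == 0:
                continue
            key = DEFAULT_TABLE.canonical(res)
            folded[key] = folded.get(key, 0) + int(n)
        length = sum(folded.values())
        if not MIN_LENGTH <= length <= MAX_LENGTH:
            raise ValueError(
                f"peptide length must be {MIN_LENGTH}-{MAX_LENGTH}, got {length}"
            )
        object.__setattr__(self, "counts", MappingProxyType(folded))

    @property
    def length(self) -> int:
        return sum(self.counts.values())

    def sort_key(self) -> tuple:
        vec = tuple(self.counts.get(r, 0) for r in DEFAULT_TABLE.alphabet)
        return (self.length, vec)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeptideComposition):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)


def peptide_mass(
    comp: PeptideComposition | Mapping[str, int] | str,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Neutral monoisotopic mass of a peptide: sum of residues + water.

    Accepts a :class:`PeptideComposition`, a residue->count mapping, or
    a plain sequence string like ``"GAK"`` (order irrelevant).
    """
    if isinstance(comp, str):
        counts: dict[str, int] = {}
        for ch in comp:
            counts[ch] = counts.get(ch, 0) + 1
        comp = counts
    if isinstance(comp, PeptideComposition):
        items: Iterable[tuple[str, int]] = comp.counts.items()
    else:
        items = comp.items()
    total = table.water
    for res, n in items:
        total += table.masses[table.canonical(res)] * n
    return total


def enumerate_compositions(
    neutral_mass: float,
    length_range: tuple[int, int] = (MIN_LENGTH, MAX_LENGTH),
    tol_ppm: float = 5.0,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[PeptideComposition]:
    """All residue multisets whose neutral mass matches within tol_ppm.

    Depth-first search over residue counts with branch-and-bound on the
    residual mass: at every node the residual must stay between
    ``slots * min`` and ``slots * max`` over the residue classes still
    available.  The result is sorted by length, then lexicographically
    by the count vector over the sorted alphabet, so the ordering never
    depends on search order.

    An empty list is a valid result (e.g. the bare water mass matches
    no peptide).
    """
    if neutral_mass <= table.water:
        return []
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    lo, hi = length_range
    lo = max(lo, 1)
    tol_da = neutral_mass * tol_ppm * 1e-6
    target = neutral_mass - table.water
    alphabet = table.alphabet
    masses = [table.masses[r] for r in alphabet]
    # suffix min/max residue mass for the bound
    n = len(alphabet)
    suf_min = [0.0] * (n + 1)
    suf_max = [0.0] * (n + 1)
    suf_min[n] = float("inf")
    suf_max[n] = float("-inf")
    for i in range(n - 1, -1, -1):
        suf_min[i] = min(masses[i], suf_min[i + 1])
        suf_max[i] = max(masses[i], suf_max[i + 1])

    out: list[PeptideComposition] = []

    def dfs(i: int, slots: int, residual: float, counts: dict[str, int]) -> None:
        if slots == 0:
            if abs(residual) <= tol_da:
                out.append(PeptideComposition(dict(counts)))
            return
        if i == n:
            return
        if residual < slots * suf_min[i] - tol_da:
            return
        if residual > slots * suf_max[i] + tol_da:
            return
        m = masses[i]
        max_c = min(slots, int((residual + tol_da) // m) if m > 0 else slots)
        for c in range(max_c + 1):
            if c:
                counts[alphabet[i]] = c
            dfs(i + 1, slots - c, residual - c * m, counts)
        counts.pop(alphabet[i], None)

    for length in range(lo, hi + 1):
        dfs(0, length, target, {})
    return sorted(out, key=PeptideComposition.sort_key)


def format_composition(comp: PeptideComposition) -> str:
    """Render a composition as e.g. ``"A1 G2 [I/L]1"``."""
    parts = []
    for res in DEFAULT_TABLE.alphabet:
        c = comp.counts.get(res, 0)
        if c:
            label = f"[{res}]" if res == ISOLEUCINE_LEUCINE else res
            parts.append(f"{label}{c}")
    return " ".join(parts)


def parse_composition(text: str) -> PeptideComposition:
    """Inverse of :func:`format_composition`."""
    counts: dict[str, int] = {}
    for token in text.split():
        if token.startswith("[") :
            res, _, num = token[1:].partition("]")
        else:
            res, num = token[0], token[1:]
        counts[res] = counts.get(res, 0) + int(num or 1)
    return PeptideComposition(counts)


def identify_composition_table(
    masses: pd.DataFrame,
    tol_ppm: float = 5.0,
    length_range: tuple[int, int] = (MIN_LENGTH, MAX_LENGTH),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> pd.DataFrame:
    """Annotate a peptide mass table with candidate compositions.

    Input columns: ``peptide_id``, ``neutral_mass_da`` and optionally
    ``length`` (restricts the search to that length).  Output columns:
    ``peptide_id``, ``candidate_rank``, ``length``, ``composition``,
    ``delta_ppm`` — one row per candidate, ranked by |delta_ppm|.
    """
    required = {"peptide_id", "neutral_mass_da"}
    if not required <= set(masses.columns):
        raise ValueError(f"input table must have columns {sorted(required)}")
    rows = []
    for rec in masses.itertuples(index=False):
        m = float(rec.neutral_mass_da)
        rng = length_range
        if "length" in masses.columns and not pd.isna(getattr(rec, "length", None)):
            L = int(rec.length)
            rng = (L, L)
        cands = enumerate_compositions(m, rng, tol_ppm, table)
        cands = sorted(
            cands, key=lambda c: (abs(peptide_mass(c, table) - m), c.sort_key())
        )
        for rank, c in enumerate(cands, start=1):
            delta = (peptide_mass(c, table) - m) / m * 1e6
            rows.append(
                {
                    "peptide_id": rec.peptide_id,
                    "candidate_rank": rank,
                    "length": c.length,
                    "composition": format_composition(c),
                    "delta_ppm": delta,
                }
            )
    return pd.DataFrame(
        rows, columns=["peptide_id", "candidate_rank", "length", "composition", "delta_ppm"]
    )
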