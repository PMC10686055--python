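"""Composition-level peptide identity from neutral monoisotopic masses.

High-resolution MS pins a small peptide down to its length and residue
multiset, not its sequence.  This script computes a few neutral masses
and then inverts them: every amino-acid composition (length 2-7) whose
mass lies within 5 ppm.  I and L are one class ([I/L]); K and Q stay
separate (0.036 Da apart, resolvable at this accuracy).
"""

import pandas as pd

import pepferm as pf

for seq in ("GG", "PP", "AK", "AQ"):
    print(f"mass({seq}) = {pf.peptide_mass(seq):.5f} Da")

print("\nCandidates within 5 ppm of mass(AK):")
for comp in pf.enumerate_compositions(pf.peptide_mass("AK"), (2, 2), tol_ppm=5):
    print("  ", pf.format_composition(comp))

table = pd.DataFrame(
    {
        "peptide_id": ["bsa_frag_1", "bsa_frag_2"],
        "neutral_mass_da": [pf.peptide_mass("GAK"), pf.peptide_mass("LSEG")],
    }
)
print("\nAnnotated mass table (rank 1..n per peptide, by |delta ppm|):")
print(pf.identify_composition_table(table, tol_ppm=5).to_string(index=False))
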