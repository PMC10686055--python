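"""Transporter-gene expression normalized to ACT1, with sulfate limitation.

Simulates qPCR Ct tables for the wild-type genotype on the peptide-only
medium and its sulfur-limited variant, normalizes each gene to the
ACT1 housekeeping reference (2^-dCt, arbitrary units), and prints the
48-h values.  OPT1 is induced when sulfate is scarce; all transporter
genes sit below 0.7 AU at 18 h and rise by 48 h.
"""

import pepferm as pf

for medium_name in ("P200", "P200-SO4"):
    medium = pf.builtin_medium(medium_name)
    cfg = pf.scenario("59A", medium, noise_sigma=0.02, seed=4)
    expr = pf.normalize_to_act1(pf.simulate_ct_table(cfg))
    at48 = expr[expr.time_h == 48].set_index("gene")["normalized_expression"]
    at18 = expr[expr.time_h == 18].set_index("gene")["normalized_expression"]
    print(f"\n{medium_name} (AU, normalized to ACT1):")
    for gene in at48.index:
        print(f"  {gene:5s} 18 h: {at18[gene]:5.2f}   48 h: {at48[gene]:5.2f}")
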