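"""Nitrogen accounting and CO2 capacity of the four fermentation media.

Builds the bundled media and prints, for each: total yeast assimilable
nitrogen (mg N/L, proline excluded by construction) and the maximum
theoretical CO2 for the 100-mL working volume (2 mol CO2 per mol
hexose).  The sulfur-limited medium keeps the same nitrogen and sugar.
"""

import pepferm as pf

for name in ("NA100", "NAP200", "P200", "P200-SO4"):
    medium = pf.builtin_medium(name)
    print(
        f"{name:9s} YAN = {pf.total_nitrogen(medium):6.1f} mg N/L   "
        f"CO2 max = {pf.theoretical_co2_max(medium):6.3f} g   "
        f"sulfate scale = {medium.sulfate_scale:.2f}"
    )

limited = pf.make_sulfur_limited(pf.builtin_medium("P200"), 0.87)
print(
    f"\nP200 with 87% sulfate reduction -> sulfate_scale "
    f"{limited.sulfate_scale:.2f}, K/Mg compensated: {limited.k_mg_compensated}; "
    f"YAN unchanged at {pf.total_nitrogen(limited):.0f} mg N/L"
)
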