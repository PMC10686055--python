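"""Fermentation/growth parameters across nitrogen conditions.

Simulates the wild-type genotype and the transporter-free knockout on
three media and extracts the five per-fermentation parameters: logistic
carrying capacity k (max cell population, OD units) and rate r (1/h),
maximum CO2 rate vmax (g/h), lag time (h to 1 g CO2), and t80 (h to 80%
of the theoretical CO2 maximum).  'not reached' marks fermentations
that plateau before the threshold — the knockout cannot use peptide
nitrogen, so on the peptide-only medium it stalls.
"""

import pepferm as pf


def fmt(x):
    return "not reached" if x is None else f"{x:7.1f}"


print(f"{'strain':7s} {'medium':8s} {'k':>6s} {'r':>6s} {'vmax':>7s} {'lag':>11s} {'t80':>11s}")
for strain in ("59A", "PepKO"):
    for medium_name in ("NA100", "NAP200", "P200"):
        medium = pf.builtin_medium(medium_name)
        cfg = pf.scenario(strain, medium, noise_sigma=0.02, seed=11)
        growth, co2 = pf.simulate_growth_and_co2(cfg)
        s = pf.summarize(growth, co2, medium)
        print(
            f"{strain:7s} {medium_name:8s} {s.k:6.2f} {s.r:6.3f} "
            f"{s.vmax:7.3f} {fmt(s.lagtime):>11s} {fmt(s.t80):>11s}"
        )
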