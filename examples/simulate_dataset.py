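"""Generate a complete synthetic fermentation dataset and re-analyse it.

Equivalent to the `pepferm simulate` CLI: writes the four TSV tables
(peptide abundances, OD600, cumulative CO2, qPCR Ct) for one scenario,
then reads them back through the package's own readers and runs the
scoring and kinetics stages — demonstrating that the generated schemas
are exactly what the analysis consumes.
"""

import tempfile
from pathlib import Path

import pepferm as pf
from pepferm import io as pio

out = Path(tempfile.mkdtemp()) / "sim"
out.mkdir()

medium = pf.builtin_medium("NAP200")
cfg = pf.scenario("fot1fot2", medium, noise_sigma=0.05, seed=21)
data = pf.simulate_dataset(cfg)
for name in ("peptides", "od", "co2", "ct"):
    pio.write_table(data[name], out / f"{name}.tsv")
print("wrote:", ", ".join(p.name for p in sorted(out.iterdir())))

abund = pio.read_abundance_table(out / "peptides.tsv")
results, summary = pf.consumption_matrix(abund)
print("\nMedian level per length class (fot1fot2 strain, NAP200 — Opt2's")
print("longer-peptide uptake is delayed while ammonium/FAA are present):")
print(summary[["length_class", "n_analytes", "median_level"]].to_string(index=False))

od = pio.read_od_table(out / "od.tsv")
co2 = pio.read_co2_table(out / "co2.tsv")
s = pf.summarize(
    pf.GrowthCurve(times=od.time_h.to_numpy(), od=od.od600.to_numpy()),
    pf.CO2Curve(times=co2.time_h.to_numpy(), co2_g=co2.co2_g.to_numpy()),
    medium,
)
print(f"\nkinetics: k={s.k:.2f} OD, r={s.r:.3f}/h, vmax={s.vmax:.3f} g/h, "
      f"lag={s.lagtime:.1f} h, t80={s.t80:.1f} h")
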