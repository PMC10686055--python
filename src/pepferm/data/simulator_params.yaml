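# Versioned constants for the synthetic fermentation generator.
# Per-peptide uptake rate constants are illustrative by design: the
# reference experiments report consumption levels, not rate constants.
# Rates/onsets are chosen so that transportable peptides are essentially
# depleted within the windows the experiments describe (di-tetra by
# 18-36 h via Fot; tetra-hepta by 24-36 h via Opt2 acting alone).
version: 1

transporters:
  fot:                      # Fot1/Fot2/Fot3: di- to tetrapeptides, early
    lengths: [2, 3, 4]
    rate_per_h: 0.25
    onset_h: 6.0
  opt2_strong:              # Opt2: tetra- to heptapeptides
    lengths: [4, 5, 6, 7]
    rate_per_h: 0.22
    onset_h: 9.0
  opt2_weak:                # Opt2: marginal di/tripeptide uptake
    lengths: [2, 3]
    rate_per_h: 0.015
    onset_h: 12.0
# Extra Opt2 onset delay when preferred nitrogen (ammonium) is present
# and the genotype carries other peptide transporters: longer-peptide
# uptake then only starts once easier sources are drawn down.
opt2_preferred_n_extra_onset_h: 21.0

faa:                        # free amino acids, consumed by every strain
  rate_per_h: 0.08
  onset_h: 6.0

panel:                      # monitored analyte counts per length class
  n_faa: 18
  peptides: {2: 19, 3: 29, 4: 14, 5: 12, 6: 10, 7: 8}
  # one dipeptide (PP-like) is non-transportable for every genotype;
  # it is counted within the 19 dipeptides.

growth:
  od_init: 0.1              # inoculum, OD600 units
  r_per_h: 0.2              # intrinsic growth rate
  k_base: 0.5               # carrying capacity at zero assimilable N
  k_per_mg_n: 0.05          # OD per mg/L accessible nitrogen
  n_ref_mg_per_l: 100.0     # N needed to ferment the sugars out
  co2_alpha: 0.0127         # g CO2 per OD per hour (yield-limited model)

ct:
  act1_ct: 20.0
  expr_18h: 0.3             # normalized expression targets (AU)
  expr_48h: 1.5
  opt1_sulfate_boost: 3.0   # OPT1 induction under sulfate limitation
  opt2_preferred_n_repression: 0.5  # OPT2 damping when ammonium present
  ct_noise_sd: 0.05         # per technical replicate, cycles
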