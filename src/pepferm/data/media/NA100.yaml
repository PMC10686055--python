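# NA100: ammonium + free amino acids only (~100 mg/L YAN).
# Proline nitrogen (a further 17 mg/L) is excluded by definition:
# it is not assimilated during fermentation.
name: NA100
sugar_g_per_l: 220.0
volume_l: 0.1
nitrogen:
  ammonium: 30.0
  free_amino_acids: 78.0
sulfate_scale: 1.0
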