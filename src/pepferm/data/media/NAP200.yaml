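# NAP200: NA100 plus ~100 mg/L nitrogen from BSA-hydrolysate peptides.
name: NAP200
sugar_g_per_l: 220.0
volume_l: 0.1
nitrogen:
  ammonium: 30.0
  free_amino_acids: 82.0
  peptides: 100.0
sulfate_scale: 1.0
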