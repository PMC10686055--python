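# P200-SO4: P200 with 87% of the sulfate salts removed; K and Mg are
# restored as chloride salts (annotation only).
name: P200-SO4
sugar_g_per_l: 220.0
volume_l: 0.1
nitrogen:
  free_amino_acids: 8.0
  peptides: 200.0
sulfate_scale: 0.13
k_mg_compensated: true
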