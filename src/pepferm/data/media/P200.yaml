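# P200: peptides as the (near-)sole nitrogen source; the small free
# amino acid fraction derives from the hydrolysate itself.
name: P200
sugar_g_per_l: 220.0
volume_l: 0.1
nitrogen:
  free_amino_acids: 8.0
  peptides: 200.0
sulfate_scale: 1.0
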