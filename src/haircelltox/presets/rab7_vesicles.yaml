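# Vesicle detector preset for EGFP-Rab7a (late endosome/lysosome) channels.
dot_pairs:
  - [4, 0.5]
  - [2, 0.08]
filament_pairs:
  - [2, 1.0]
  - [1, 0.9]
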