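# Vesicle detector preset for G418-Texas Red channels.
dot_pairs:
  - [4, 0.04]
  - [1, 0.05]
filament_pairs:
  - [3, 0.2]
  - [2, 0.09]
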