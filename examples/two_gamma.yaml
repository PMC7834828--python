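# Horizontal-connection setting that generates both slow and fast gamma.
model:
  w_ee_hc: 0.03
  w_ie_hc: 2.5
stimulus:
  radius: 1.0e+9     # full field
simulation:
  repeats: 100
  seed: 1
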