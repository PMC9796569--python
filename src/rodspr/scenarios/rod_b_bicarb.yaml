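# Rod-b (base surrogate) with bicarbonate: maximal cyclase rate increased by
# 100% and transducin activation decreased by 30% at the base.
label: rod_b_bicarb
multipliers:
  alpha_max: 2.0
  nu_RG: 0.7
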