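# Rod-t (tip surrogate) with bicarbonate: relative to rod-t in Ringer's the
# maximal cyclase rate rises by 30% and f_Ca falls by 25% (x 0.75).
# Factors below are relative to the toad BASE parameters:
# nu_RG 0.52 (tip), f_Ca 1.56 x 0.75 = 1.17, alpha_max x 1.3.
label: rod_t_bicarb
multipliers:
  nu_RG: 0.52
  f_Ca: 1.17
  alpha_max: 1.3
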