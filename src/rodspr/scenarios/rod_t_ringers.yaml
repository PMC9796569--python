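# Homogeneous surrogate for the TIP of a toad outer segment in Ringer's:
# transducin activation (nu_RG) 48% lower and the Ca2+ fraction of the dark
# current (f_Ca) 56% higher than at the base, raising total dark Ca2+ ~60%.
label: rod_t_ringers
multipliers:
  nu_RG: 0.52
  f_Ca: 1.56
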