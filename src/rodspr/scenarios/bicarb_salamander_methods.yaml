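# Salamander, 30 mM bicarbonate: cyclase stimulation with a 13% increase of
# the minimum (high-Ca) rate and a doubled maximum (low-Ca) rate, chosen to
# raise dark current by ~13.0% and shorten recovery tau by ~16.5%.
label: bicarb_salamander_methods
multipliers:
  alpha_min: 1.13
  alpha_max: 2.0
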