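# Salamander, 30 mM bicarbonate: cyclase stimulation variant with a 7%
# increase of the minimum (high-Ca) rate and a doubled maximum (low-Ca) rate.
label: bicarb_salamander_fig1
multipliers:
  alpha_min: 1.07
  alpha_max: 2.0
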