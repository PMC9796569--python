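# Salamander, 30 mM bicarbonate: cyclase multipliers solved by
# calibrate_cyclase against the recorded effects of bicarbonate
# (+13.0% dark current, -16.5% recovery tau) for the bundled salamander
# parameter set; the maximal-rate factor lands at ~2 (a doubling of the
# low-Ca cyclase rate), the high-Ca rate is essentially unchanged.
label: bicarb_salamander_calibrated
multipliers:
  alpha_min: 0.995
  alpha_max: 2.06
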