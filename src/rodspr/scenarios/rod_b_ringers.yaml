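# Homogeneous surrogate for the BASE of a toad outer segment in Ringer's:
# the toad base parameters unchanged.
label: rod_b_ringers
multipliers: {}
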