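"""Unit conventions and physical conversion constants.

The package uses a single unit system throughout:

========  =========
quantity  unit
========  =========
length    micrometre (um)
time      millisecond (ms)
volume    um^3  (1 um^3 = 1e-15 L)
amount    concentration in micromolar (uM); 1 uM * um^3 = 1e-15 umol
current   picoampere (pA)
========  =========

Membrane currents are converted to molar fluxes via Faraday's constant.
With the units above, a 1 pA current of a z-valent ion moves
``1e-12 / (z * F)`` mol/s, which works out to ``10.364 / z`` uM*um^3/ms.
"""

FARADAY = 96485.33212  # C/mol

#: uM*um^3 of a monovalent ion moved per ms by 1 pA.
PA_TO_FLUX_1 = 1e-12 / FARADAY * 1e6 * 1e15 * 1e-3  # = 10.364
#: Same for a divalent ion (Ca2+ through the CNG channel).
PA_TO_FLUX_2 = PA_TO_FLUX_1 / 2.0
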