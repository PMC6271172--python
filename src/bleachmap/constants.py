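"""Physical constants used throughout the photokinetic formulas.

The values are the conventional textbook ones at the precision used in the
photobleaching literature; keeping them in one place guarantees that the
printed example numbers (photon energies, photon fluxes) are reproducible
to the last digit.
"""

#: Planck's constant (J·s).
PLANCK_H = 6.626e-34

#: Speed of light in nm/s (3 x 10^5 km/s), so that wavelengths in nm can be
#: used directly in E = h*c/lambda.
SPEED_OF_LIGHT_NM = 3e17

#: Avogadro's number (mol^-1).
AVOGADRO = 6.0221e23
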