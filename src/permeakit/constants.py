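"""Unit system and physical constants.

The package works in a single force-field-style unit system throughout:
lengths in Å, times in ps, energies in kcal/mol, charges in elementary
charge e, temperatures in Kelvin, masses in amu.  All conversion factors
live here and nowhere else.
"""

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_KCAL = 332.0636

#: Force conversion for an external electric field: 1 e·(V/Å) in kcal/(mol·Å).
EEF_TO_FORCE = 23.0609

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL = 0.0019872041

#: Acceleration conversion: (kcal/mol/Å) / amu -> Å/ps².
ACCEL_CONV = 418.4

#: Half the Coulomb constant; prefactor of the Born solvation energy.
BORN_PREFACTOR = COULOMB_KCAL / 2.0
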