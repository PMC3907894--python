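"""Physical constants used throughout the package.

The gas constant is fixed at 1.987 cal K^-1 mol^-1 (the value conventional in
the protein-unfolding literature), expressed in kcal so that activation
energies and van't Hoff enthalpies come out in kcal/mol.
"""

#: Gas constant, kcal K^-1 mol^-1.
R_KCAL = 1.987e-3

#: Offset from degrees Celsius to kelvin.
CELSIUS_TO_KELVIN = 273.15


def celsius_to_kelvin(temp_c):
    """Convert a temperature (scalar or array) from Celsius to kelvin."""
    return temp_c + CELSIUS_TO_KELVIN
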