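"""Physical constants and unit conversions (CODATA 2018).

All internal energies are kJ·mol⁻¹, pressures GPa, volumes Å³, lengths Å.
"""

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 GPa·Å³ per molecule expressed in kJ·mol⁻¹ (N_A × 1e-30 kJ per kJ... i.e.
#: 1 GPa·Å³ = 1e9 Pa × 1e-30 m³ = 1e-21 J per molecule = N_A×1e-24 kJ/mol).
GPA_A3_TO_KJMOL = AVOGADRO * 1e-24  # 0.602214076

#: Hartree in kJ·mol⁻¹.
HARTREE_TO_KJMOL = 2625.4996394799

#: Electronvolt in kJ·mol⁻¹.
EV_TO_KJMOL = 96.48533212331


def hartree_to_kjmol(value: float) -> float:
    """Convert an energy in hartree to kJ·mol⁻¹."""
    return value * HARTREE_TO_KJMOL


def ev_to_kjmol(value: float) -> float:
    """Convert an energy in eV to kJ·mol⁻¹."""
    return value * EV_TO_KJMOL
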