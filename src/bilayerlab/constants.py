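"""Physical constants and unit conversions.

Internal unit system: lengths in nm, times in ps, energies in kJ/mol,
forces in kJ/mol/nm, temperatures in K.  Conversions to reporting units
(cm^2/s, cm/s, mN/m, J) happen only at I/O and reporting boundaries.
"""

#: molar gas constant, kJ/(mol K)
R_KJ_MOL_K = 8.314462618e-3

#: Boltzmann constant, J/K
KB_J = 1.380649e-23

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: diffusivity: nm^2/ps -> cm^2/s  (1 nm^2 = 1e-14 cm^2, 1 ps = 1e-12 s)
NM2_PS_TO_CM2_S = 1e-2

#: local resistance: ps/nm^2 -> s/cm^2
PS_NM2_TO_S_CM2 = 1e2

#: permeability: nm/ps -> cm/s
NM_PS_TO_CM_S = 1e5


def kBT_kJ_mol(temperature: float) -> float:
    """Thermal energy kB*T on a molar basis, in kJ/mol."""
    return R_KJ_MOL_K * temperature


def kBT_J(temperature: float) -> float:
    """Thermal energy kB*T per molecule, in J."""
    return KB_J * temperature
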