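"""Physical constants and unit conversions (SI unless noted).

Conventions used throughout the package: times in seconds, lengths in µm
(nm for hydrodynamic outputs), volumes in fl (1 fl = 1 µm^3 = 1e-15 L),
concentrations in nM, diffusion coefficients in µm^2/s.
"""

AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K

#: Dynamic viscosity of water at 20 °C (293.15 K), Pa·s.
WATER_VISCOSITY_293K = 1.0016e-3

#: Default absolute temperature, K.
DEFAULT_TEMPERATURE = 293.15

FEMTOLITER_TO_LITER = 1e-15
NM_TO_M = 1e-9
UM2_PER_S_TO_M2_PER_S = 1e-12


def occupancy_to_nM(n_molecules: float, v_eff_fl: float) -> float:
    """Concentration (nM) of ``n_molecules`` in an effective volume (fl)."""
    molar = n_molecules / (v_eff_fl * FEMTOLITER_TO_LITER * AVOGADRO)
    return molar * 1e9
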