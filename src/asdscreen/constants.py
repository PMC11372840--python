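"""Physical constants, σ-grid definition and the universal parameter set.

The universal COSMO-SAC parameters below are the substance-independent
constants of the 2010 three-class hydrogen-bonding variant with the
single-constant Margules dispersion extension, matching the open-source
reference implementation.  They are exposed as a named set so alternative
parameterizations can be pinned in a model configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# --- σ grid: 51 equispaced bins on [-0.025, 0.025] e/Angstrom^2 ------------
N_BINS = 51
SIGMA_MIN = -0.025
SIGMA_MAX = 0.025
SIGMA_GRID = np.linspace(SIGMA_MIN, SIGMA_MAX, N_BINS)
SIGMA_STEP = (SIGMA_MAX - SIGMA_MIN) / (N_BINS - 1)  # 0.001 e/A^2

#: σ-profile surface classes, fixed order used throughout the package.
CLASSES = ("nhb", "oh", "ot")

# --- physical constants ----------------------------------------------------
R_J = 8.31446261815324           # J / (mol K)
R_KCAL = 1.987204258640832e-3    # kcal / (mol K)
BOHR_ANGSTROM = 0.529177210903   # Angstrom per bohr
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class ParameterSet:
    """Universal substance-independent parameters of the segment model."""

    name: str
    a_eff: float          # effective segment area, A^2
    q0: float             # area normalization, A^2
    r0: float             # volume normalization, A^3
    z_coord: float        # coordination number of the lattice
    a_es: float           # electrostatic misfit, kcal A^4 / (mol e^2)
    b_es: float           # misfit T-dependence, kcal A^4 K^2 / (mol e^2)
    c_ohoh: float         # HB exchange coefficients, kcal A^4 / (mol e^2)
    c_otot: float
    c_ohot: float
    sigma_hb: float       # width of the HB switching function, e/A^2
    r_av: float           # charge averaging radius, A
    f_decay: float        # Gaussian decay factor of the averaging kernel
    w_dsp: float          # magnitude of the dispersion Margules weight


#: 2010 three-class parameter set with dispersion (the package default).
PARAMS_2010 = ParameterSet(
    name="2010",
    a_eff=7.25,
    q0=79.53,
    r0=66.69,
    z_coord=10.0,
    a_es=6525.69,
    b_es=1.4859e8,
    c_ohoh=4013.78,
    c_otot=932.31,
    c_ohot=3016.43,
    sigma_hb=0.007,
    r_av=0.5,
    f_decay=3.57,
    w_dsp=0.27027,
)

PARAMETER_SETS = {"2010": PARAMS_2010}

# --- hard-core (van der Waals) volume increments ---------------------------
# Atomic volume contributions in A^3 per atom for the fast bond/ring-corrected
# van der Waals volume scheme based on Bondi radii.
VDW_ATOM_INCREMENTS = {
    "H": 7.24,
    "C": 20.58,
    "N": 15.60,
    "O": 14.71,
    "F": 13.31,
    "Cl": 22.45,
    "Br": 26.52,
    "I": 32.52,
    "P": 24.43,
    "S": 24.43,
    "As": 26.52,
    "B": 40.48,
    "Ge": 28.76,
    "Se": 28.73,
    "Si": 38.79,
    "Sn": 45.54,
    "Te": 36.62,
}
VDW_BOND_CORRECTION = 5.92        # A^3 per bond
VDW_AROMATIC_RING_CORRECTION = 14.7
VDW_NONAROMATIC_RING_CORRECTION = 3.8
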