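"""Physical constants and experiment-design defaults shared across modules.

Every default that has a counterpart in the reference experimental design
(CPMG frequencies, relaxation delays, temperatures, fields, error floor,
classification cuts, probe radii) lives here so the configuration layer can
echo a single authoritative set of values.
"""

import numpy as np

# --- physical constants (SI) ---
R_GAS = 8.314            # J K^-1 mol^-1
K_BOLTZMANN = 1.380649e-23   # J K^-1
H_PLANCK = 6.62607015e-34    # J s

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126e7

# 15N/1H Larmor frequency ratio: a "500 MHz" magnet observes 15N at
# 0.1013 * 500 MHz.  Used to convert ppm chemical-shift differences to rad/s.
N15_TO_H1_RATIO = 0.1013

# amide 15N relaxation geometry (isotropic-rotor spectral densities)
NH_BOND_LENGTH = 1.02e-10    # m
CSA_N15 = -160e-6            # 15N chemical-shift anisotropy, dimensionless
HBAR = 1.054571817e-34       # J s
MU0_OVER_4PI = 1e-7          # T^2 J^-1 m^3

# --- CPMG experiment design defaults ---
T_RELAX_DEFAULT = 0.030      # s, constant-time CPMG relaxation delay
ERROR_FLOOR_FRACTION = 0.03  # minimum R2,eff error as a fraction of R2,eff
NU_CPMG_REFERENCE_HZ = 500.0  # spectrum used for the noise-based error term

NU_CPMG_DEFAULT_HZ = (
    66.7, 133.3, 200.0, 266.7, 333.3, 400.0,
    466.7, 533.3, 600.0, 666.7, 866.7, 1000.0,
)

TEMPERATURES_DEFAULT_K = (298.0, 300.5, 303.0, 305.5, 308.0)
FIELDS_DEFAULT_MHZ = (500.0, 700.0)
N_RESIDUES_DEFAULT = 22

# --- exchange filtering / classification cuts ---
DELTA_R2EFF_THRESHOLD = 5.0   # s^-1, exchange-active residue filter
NU_LOW_DEFAULT_HZ = 66.7
NU_HIGH_DEFAULT_HZ = 1000.0
HETNOE_FLEXIBLE_CUT = 0.65    # Het-NOE below this flags ps-ns flexibility
TCI_HBOND_CUT = -5.0          # ppb/K; slopes more positive indicate H-bonds

# --- transition-state theory ---
KAPPA_DEFAULT = 1.6e-7        # transmission coefficient

# --- backbone relaxation delay grids (s) ---
R1_DELAYS_DEFAULT_S = (0.05, 0.1, 0.2, 0.3, 0.5, 0.6, 0.8, 0.9, 1.0)
R2_DELAYS_DEFAULT_S = (
    0.01696, 0.03392, 0.05088, 0.06784, 0.0848,
    0.10176, 0.11872, 0.13568, 0.20352, 0.23744,
)

# --- titration design ---
P_TOTAL_DEFAULT_M = 80e-6
LIGAND_CONCS_DEFAULT_M = tuple(
    float(x) for x in np.linspace(5e-6, 500e-6, 12)
)
CSP_ALPHA = 0.14              # 15N weighting in the combined CSP

# --- cavity calculation ---
PROBE_SMALL_DEFAULT = 1.3     # Angstrom
PROBE_LARGE_DEFAULT = 3.0     # Angstrom
GRID_SPACING_DEFAULT = 0.5    # Angstrom

# Bondi van der Waals radii, Angstrom
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
VDW_FALLBACK = 1.70


def n15_omega_rad_per_ppm(field_mhz: float) -> float:
    """rad/s per ppm of 15N shift at the given 1H field (MHz)."""
    return 2.0 * np.pi * field_mhz * N15_TO_H1_RATIO
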