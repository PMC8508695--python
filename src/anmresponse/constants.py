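"""Physical constants, unit conversions and the residue-mass table.

All internal dynamics is carried out in SI units (kg, m, s, N, N/m,
rad/s); user-facing interfaces speak the crystallographer's units
(angstrom, amu, ps, THz, angstrom^2).  Every conversion in the package
goes through the factors defined here.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: One unified atomic mass unit, kg.
AMU = 1.66053906660e-27

#: One angstrom, m.
ANGSTROM = 1.0e-10

#: One picosecond, s.
PICOSECOND = 1.0e-12

#: rad/s per THz of ordinary frequency.
RAD_PER_S_PER_THZ = 2.0 * math.pi * 1.0e12


def thz_to_rad_s(f_thz: float) -> float:
    """Ordinary frequency in THz -> angular frequency in rad/s."""
    return f_thz * RAD_PER_S_PER_THZ


def rad_s_to_thz(omega: float) -> float:
    """Angular frequency in rad/s -> ordinary frequency in THz."""
    return omega / RAD_PER_S_PER_THZ


# Average residue masses (amino acid minus one water), amu.  These are the
# masses a residue contributes inside a peptide chain, which is what a
# one-node-per-residue model needs.
RESIDUE_MASSES_AMU: dict[str, float] = {
    "GLY": 57.05,
    "ALA": 71.08,
    "SER": 87.08,
    "PRO": 97.12,
    "VAL": 99.13,
    "THR": 101.10,
    "CYS": 103.14,
    "LEU": 113.16,
    "ILE": 113.16,
    "ASN": 114.10,
    "ASP": 115.09,
    "GLN": 128.13,
    "LYS": 128.17,
    "GLU": 129.12,
    "MET": 131.19,
    "HIS": 137.14,
    "PHE": 147.18,
    "ARG": 156.19,
    "TYR": 163.18,
    "TRP": 186.21,
}

#: Fallback for residue names not in the table (mean of the 20 standard ones).
MEAN_RESIDUE_MASS_AMU = sum(RESIDUE_MASSES_AMU.values()) / len(RESIDUE_MASSES_AMU)

#: Default distance cutoff for spring placement, angstrom.
DEFAULT_CUTOFF_A = 15.0

#: Default absolute temperature for fluctuation (B-factor) predictions, K.
DEFAULT_TEMPERATURE_K = 300.0

#: Default per-component bound of the random force patterns, N.
DEFAULT_FORCE_BOUND_N = 1.0e-10

#: Eigenvalues below this fraction of the largest one count as rigid modes.
ZERO_MODE_RTOL = 1.0e-8
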