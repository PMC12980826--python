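"""Frozen physical constants, element radii and residue category tables.

Everything configurable by the pipeline (probe radius, point density,
radial threshold, contact cutoff, solvent constants) has its default
defined here, in one place, so that run manifests can echo them.
"""

from __future__ import annotations

from scipy import constants as _sc

# --- van der Waals radii, Å (Bondi 1964 element radii; heavy atoms only,
#     crystal structures carry no hydrogens).  Frozen: changing these
#     changes every SASA number downstream.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
#: fallback radius for elements missing from the table (logged when used)
DEFAULT_VDW_RADIUS: float = 1.70

#: backbone atom names; every other heavy atom counts as side chain.
#: GLY therefore contributes no side-chain atoms.
BACKBONE_ATOM_NAMES: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

# --- residue categories used for outer-surface SASA partitioning
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset(
    {"PHE", "ILE", "LEU", "TYR", "TRP", "VAL", "MET", "PRO", "CYS", "ALA"}
)
ACIDIC_RESIDUES: frozenset[str] = frozenset({"ASP", "GLU"})
BASIC_RESIDUES: frozenset[str] = frozenset({"LYS", "ARG"})

#: standard residues that belong to none of the categories above and are
#: deliberately excluded from all category sums
STANDARD_RESIDUES: frozenset[str] = (
    HYDROPHOBIC_RESIDUES
    | ACIDIC_RESIDUES
    | BASIC_RESIDUES
    | frozenset({"GLY", "SER", "THR", "ASN", "GLN", "HIS"})
)

# --- SASA engine defaults
DEFAULT_PROBE_RADIUS: float = 1.4  # Å, water probe
DEFAULT_N_POINTS: int = 960  # golden-spiral points per atom
DEFAULT_RADIAL_THRESHOLD: float = 105.0  # Å from capsid center ("outer" shell)
DEFAULT_CONTACT_CUTOFF: float = 6.0  # Å heavy-atom contact for VP neighbors

# --- electrokinetics
VACUUM_PERMITTIVITY: float = _sc.epsilon_0  # F/m
BOLTZMANN: float = _sc.k  # J/K
ELEMENTARY_CHARGE: float = _sc.e  # C

#: water at 25 °C: dynamic viscosity (Pa·s), relative permittivity,
#: absolute temperature (K)
WATER_VISCOSITY_25C: float = 8.9e-4
WATER_RELATIVE_PERMITTIVITY_25C: float = 78.4
TEMPERATURE_25C: float = 298.15
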