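"""Ideal-geometry constants and algorithm thresholds.

All distances are in Angstrom, all angles in radians unless a name says
otherwise.  The peptide-plate geometry follows Engh--Huber-style ideal
values for an alanine (generic) and a proline peptide unit; templates for
the cis isomers share bond lengths and planar angles with their trans
counterparts and differ only in the omega torsion (0 instead of pi).
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# Peptide-plate internal geometry (Engh-Huber style ideal values)
# ---------------------------------------------------------------------------
# bond lengths [A]
BOND_CA_C = 1.525       # Calpha1 - C'
BOND_C_O = 1.231        # C' - O (carbonyl)
BOND_C_N_GENERIC = 1.329  # C' - N, residue following is not proline
BOND_C_N_PROLINE = 1.341  # C' - N, residue following is proline
BOND_N_CA = 1.458       # N - Calpha2
BOND_N_H = 1.010        # N - amide H (optional atom)

# planar angles [deg] at the carbonyl carbon and the amide nitrogen
ANGLE_CA_C_N_GENERIC = 116.2
ANGLE_CA_C_N_PROLINE = 116.9
ANGLE_O_C_N_GENERIC = 123.0
ANGLE_O_C_N_PROLINE = 122.0
ANGLE_C_N_CA_GENERIC = 121.7
ANGLE_C_N_CA_PROLINE = 122.6
ANGLE_C_N_H = 119.5

# ---------------------------------------------------------------------------
# Chain-level thresholds
# ---------------------------------------------------------------------------
# Consecutive Calpha-Calpha pseudo-bond window: lower bound admits cis
# peptide bonds (~2.9 A), upper bound rejects chain breaks.
CA_CA_MIN = 2.6
CA_CA_MAX = 4.3

# Pseudo-bonds shorter than this are classified as cis peptide bonds.
CIS_THRESHOLD = 3.5

# Minimum chain length: the feature window reaches i +/- 5, plus a plate.
MIN_RESIDUES = 6

# Stereochemistry screen for the training-set quality filter: every
# backbone bond length must lie within this margin of its ideal value.
BOND_TOLERANCE = 0.2
IDEAL_BACKBONE_BONDS = {
    ("N", "CA"): BOND_N_CA,
    ("CA", "C"): BOND_CA_C,
    ("C", "O"): BOND_C_O,
    ("C", "N"): BOND_C_N_GENERIC,  # inter-residue peptide bond
}

# ---------------------------------------------------------------------------
# Secondary-structure assignment from Calpha geometry (H-E-C stand-in)
# ---------------------------------------------------------------------------
# Helix windows on d(i, i+3) and d(i, i+4); a residue is helical when both
# distances fall inside the windows for a run of >= HELIX_MIN_RUN residues.
HELIX_D13_WINDOW = (4.5, 6.0)
HELIX_D14_WINDOW = (5.5, 6.9)
HELIX_MIN_RUN = 3

# Extended geometry: d(i, i+2) above this marks a locally stretched chain.
STRAND_D12_MIN = 6.3
STRAND_MIN_RUN = 2

# Coarse-grained H-bond windows on Calpha-Calpha distances.
HBOND_HELIX_SEP = (3, 4)            # |i-j| for helix-type partners
HBOND_HELIX_WINDOW = (4.5, 6.5)
HBOND_STRAND_MIN_SEP = 3            # |i-j| >= 3 for strand-type partners
HBOND_STRAND_WINDOW = (4.2, 5.6)

# Neighbor-count radii for the packing features [A].
NEIGHBOR_RADII = (4.0, 4.5, 5.0, 6.0)

# ---------------------------------------------------------------------------
# Canonical lambda values of regular secondary structure [rad]
# ---------------------------------------------------------------------------
# Derived once from ideal-dihedral backbones (phi=-57, psi=-47 alpha-helix;
# phi=-139, psi=135 antiparallel beta-strand) built with the constants above
# and measured with lambda_from_backbone; frozen here as configuration.
LAMBDA_HELIX = 1.2370649793660771
LAMBDA_STRAND = 1.9346509344590201

DEG = math.pi / 180.0
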