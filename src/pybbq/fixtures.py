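"""Synthetic ground-truth structures for testing and training.

Every generator returns a SyntheticChain whose Calpha trace, backbone,
lambda series and secondary-structure labels are mutually consistent by
construction: the backbone is realised from the trace and lambdas through
reconstruct_backbone, so lambda_from_backbone recovers the stored values to
machine precision.  A separate ideal-dihedral builder constructs backbones
from phi/psi/omega torsions; it is the independent source from which the
canonical helix and strand lambda constants were derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as K
from .plate_geometry import (BackboneStructure, LambdaSeries, _place_atom,
                             lambda_from_backbone, reconstruct_backbone)
from .structure_io import AMINO_ACIDS_3, AtomRecord, CaTrace, ProteinChain

# Ideal alpha-helix Calpha geometry (radius / rise / twist per residue),
# derived once from a phi=-57, psi=-47 ideal-dihedral backbone built with
# the configured bond constants, then frozen.
HELIX_RADIUS = 2.2758979728593225
HELIX_RISE = 1.5577731774844510
HELIX_TWIST = 1.7340775054467557   # rad/residue (~99.4 deg)

ANGLE_N_CA_C = 111.2  # deg, ideal backbone angle used by the dihedral builder

# Widths of the two lambda modes of make_synthetic_chain [rad]: narrow,
# well-defined plate orientations in helices; broad orientational freedom
# in extended/coil conformations.
LAMBDA_SIGMA_HELIX = 0.10
LAMBDA_SIGMA_EXTENDED = 0.45


@dataclass
class SyntheticChain:
    """A fully self-consistent synthetic protein chain."""

    trace: CaTrace
    backbone: BackboneStructure
    lambdas: LambdaSeries
    sse: list[str]


# ---------------------------------------------------------------------------
# Ideal-dihedral backbone builder (independent of the plate machinery)
# ---------------------------------------------------------------------------

def backbone_from_dihedrals(sequence, phi, psi, omega=None) -> BackboneStructure:
    """Build an ideal backbone from phi/psi/omega torsions (NeRF chaining).

    phi[0] and psi[-1] are not used to place heavy atoms of other residues
    but psi values drive the placement of each residue's carbonyl.  All bond
    lengths and planar angles are the configured ideal constants.
    """
    kk = len(sequence)
    phi = np.broadcast_to(np.asarray(phi, float), (kk,))
    psi = np.broadcast_to(np.asarray(psi, float), (kk,))
    if omega is None:
        omega = np.pi
    omega = np.broadcast_to(np.asarray(omega, float), (kk,))

    a_nca_c = ANGLE_N_CA_C * K.DEG
    a_ca_c_n = K.ANGLE_CA_C_N_GENERIC * K.DEG
    a_c_n_ca = K.ANGLE_C_N_CA_GENERIC * K.DEG
    a_o_c_n = K.ANGLE_O_C_N_GENERIC * K.DEG

    n = np.zeros((kk, 3))
    ca = np.zeros((kk, 3))
    c = np.zeros((kk, 3))
    o = np.full((kk, 3), np.nan)

    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (K.BOND_N_CA, 0.0, 0.0)
    c[0] = ca[0] + K.BOND_CA_C * np.array(
        [-math.cos(a_nca_c), math.sin(a_nca_c), 0.0])
    for i in range(1, kk):
        n[i] = _place_atom(n[i - 1], ca[i - 1], c[i - 1],
                           K.BOND_C_N_GENERIC, a_ca_c_n, psi[i - 1])
        ca[i] = _place_atom(ca[i - 1], c[i - 1], n[i],
                            K.BOND_N_CA, a_c_n_ca, omega[i - 1])
        c[i] = _place_atom(c[i - 1], n[i], ca[i],
                           K.BOND_CA_C, a_nca_c, phi[i])
    for i in range(kk - 1):
        o[i] = _place_atom(ca[i + 1], n[i + 1], c[i], K.BOND_C_O, a_o_c_n, 0.0)
    # last carbonyl: anti to the hypothetical next amide nitrogen
    o[kk - 1] = _place_atom(n[kk - 1], ca[kk - 1], c[kk - 1],
                            K.BOND_C_O, a_o_c_n + 0.0, psi[kk - 1] + np.pi)
    return BackboneStructure(list(sequence), n, ca, c, o)


# ---------------------------------------------------------------------------
# Calpha trace construction helpers
# ---------------------------------------------------------------------------

def _trace_from_internal(bonds, angles, torsions) -> np.ndarray:
    """Chain Calpha pseudo-atoms from pseudo-bond internal coordinates."""
    m = len(bonds)                     # number of pseudo-bonds, K-1
    xyz = np.zeros((m + 1, 3))
    xyz[1] = (bonds[0], 0.0, 0.0)
    if m >= 2:
        a = angles[0]
        xyz[2] = xyz[1] + bonds[1] * np.array(
            [-math.cos(a), math.sin(a), 0.0])
    for i in range(3, m + 1):
        xyz[i] = _place_atom(xyz[i - 3], xyz[i - 2], xyz[i - 1],
                             bonds[i - 1], angles[i - 2], torsions[i - 3])
    return xyz


def _helix_internal():
    """Pseudo-bond length/angle/torsion of the ideal helix Calpha trace."""
    t = HELIX_TWIST
    pts = np.array([[HELIX_RADIUS * math.cos(i * t),
                     HELIX_RADIUS * math.sin(i * t),
                     i * HELIX_RISE] for i in range(4)])
    bond = float(np.linalg.norm(pts[1] - pts[0]))
    v1, v2 = pts[0] - pts[1], pts[2] - pts[1]
    angle = float(math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    from .plate_geometry import torsion as _torsion
    tors = float(_torsion(pts[0], pts[1], pts[2], pts[3]))
    return bond, angle, tors


def _random_sequence(rng, kk: int) -> list[str]:
    return [AMINO_ACIDS_3[j] for j in rng.integers(0, 20, size=kk)]


def _finish_chain(sequence, coords, lambdas: LambdaSeries,
                  chain_id: str = "A") -> SyntheticChain:
    from .trace_features import assign_secondary_structure

    trace = CaTrace(chain_id, list(sequence), np.asarray(coords, float))
    backbone = reconstruct_backbone(trace, lambdas)
    measured = lambda_from_backbone(backbone)
    sse = assign_secondary_structure(trace).labels
    return SyntheticChain(trace, backbone, measured, sse)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_ideal_helix(n_residues: int, chain_id: str = "A") -> SyntheticChain:
    """Ideal alpha-helix: parametric Calpha helix + constant helical lambda."""
    if n_residues < K.MIN_RESIDUES:
        raise ValueError(f"need at least {K.MIN_RESIDUES} residues")
    i = np.arange(n_residues)
    coords = np.stack([HELIX_RADIUS * np.cos(i * HELIX_TWIST),
                       HELIX_RADIUS * np.sin(i * HELIX_TWIST),
                       i * HELIX_RISE], axis=1)
    lams = LambdaSeries(np.full(n_residues - 1, K.LAMBDA_HELIX),
                        np.ones(n_residues - 1, dtype=bool))
    return _finish_chain(["ALA"] * n_residues, coords, lams, chain_id)


def make_ideal_sheet(n_per_strand: int, chain_id: str = "A") -> SyntheticChain:
    """Two-strand antiparallel hairpin with strand-type lambda values.

    Strand Calpha traces are planar zigzags (d(i,i+2) ~ 6.7 A) separated by
    ~4.9 A so that cross-strand pairs fall inside the strand H-bond window.
    """
    if n_per_strand < 4:
        raise ValueError("need at least 4 residues per strand")
    a, b = 3.35, math.sqrt(3.8 ** 2 - 3.35 ** 2) / 2.0
    sep = 4.9
    s1 = [(i * a, b * (-1) ** i, 0.0) for i in range(n_per_strand)]
    x_max = (n_per_strand - 1) * a
    s2 = [(x_max - i * a, b * (-1) ** i, sep) for i in range(n_per_strand)]
    # two turn residues bulging out in +x, placed so that every pseudo-bond
    # along the turn is exactly 3.8 A
    start, end = np.array(s1[-1]), np.array(s2[0])
    mid = 0.5 * (start + end)
    e = (end - start) / np.linalg.norm(end - start)
    half = 1.9 * e
    w = math.sqrt(3.8 ** 2 - float(np.sum((start - (mid - half)) ** 2)))
    turn = [tuple(mid - half + np.array([w, 0.0, 0.0])),
            tuple(mid + half + np.array([w, 0.0, 0.0]))]
    coords = np.array(s1 + turn + s2)
    m = len(coords) - 1
    lams = np.full(m, K.LAMBDA_STRAND)
    # turn plates get a helical-like lambda to bend the carbonyls inward
    lams[n_per_strand - 1:n_per_strand + 2] = K.LAMBDA_HELIX
    series = LambdaSeries(lams, np.ones(m, dtype=bool))
    return _finish_chain(["VAL"] * len(coords), coords, series, chain_id)


def make_synthetic_chain(k: int, cis_fraction: float = 0.0, seed: int = 0,
                         helix_sigma: float | None = None,
                         extended_sigma: float | None = None,
                         chain_id: str = "A") -> SyntheticChain:
    """Random protein-like chain: alternating helix / extended / coil
    segments with segment-dependent lambda noise.

    Lambda values follow a two-mode mixture: a narrow mode at the canonical
    helix value inside helical segments and a broad mode at the canonical
    extended value elsewhere (coil plates draw from either).  Chains with
    any non-bonded Calpha pair closer than 3.0 A are resampled.
    """
    if k < K.MIN_RESIDUES:
        raise ValueError(f"need at least {K.MIN_RESIDUES} residues")
    if helix_sigma is None:
        helix_sigma = LAMBDA_SIGMA_HELIX
    if extended_sigma is None:
        extended_sigma = LAMBDA_SIGMA_EXTENDED
    rng = np.random.default_rng(seed)
    h_bond, h_angle, h_torsion = _helix_internal()
    for _attempt in range(50):
        # segment plan over residues
        seg_types: list[str] = []
        while len(seg_types) < k:
            kind = rng.choice(["H", "E", "C"], p=[0.45, 0.35, 0.2])
            length = int(rng.integers(6, 13)) if kind == "H" else int(rng.integers(4, 9))
            seg_types.extend([kind] * length)
        seg_types = seg_types[:k]

        m = k - 1
        bonds = np.full(m, 3.8) + rng.normal(0.0, 0.01, size=m)
        n_cis = int(round(cis_fraction * m))
        cis_plates = rng.choice(m, size=n_cis, replace=False) if n_cis else []
        bonds[list(cis_plates)] = 2.95
        angles = np.empty(max(m - 1, 0))
        torsions = np.empty(max(m - 2, 0))
        lams = np.empty(m)
        for j in range(m - 1):
            kind = seg_types[j + 1]
            if kind == "H":
                angles[j] = h_angle + rng.normal(0.0, 0.02)
            elif kind == "E":
                angles[j] = math.radians(125.0) + rng.normal(0.0, 0.05)
            else:
                angles[j] = math.radians(rng.uniform(85.0, 140.0))
        for j in range(m - 2):
            kind = seg_types[j + 2]
            if kind == "H":
                torsions[j] = h_torsion + rng.normal(0.0, 0.03)
            elif kind == "E":
                torsions[j] = math.radians(-170.0) + rng.normal(0.0, 0.10)
            else:
                torsions[j] = rng.uniform(-math.pi, math.pi)
        coords = _trace_from_internal(bonds, angles, torsions)
        # self-intersection screen on non-bonded pairs
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        ii, jj = np.triu_indices(k, k=2)
        if np.any(dist[ii, jj] < 3.0):
            continue
        # lambda per plate: narrow helical mode when the plate sits in
        # helical geometry, broad extended mode otherwise.  "Helical" is
        # decided by the same Calpha-only rules the feature extractor uses
        # (plus the generator's own segment plan), so lambda is a noisy but
        # learnable function of observable trace geometry — the premise of
        # the whole reconstruction approach.
        from .trace_features import assign_secondary_structure as _assign

        labels = _assign(CaTrace("A", ["ALA"] * k, coords)).labels
        for p in range(m):
            seg_pair = (seg_types[p], seg_types[p + 1])
            helical = (seg_pair == ("H", "H")
                       or (labels[p] == "H" and labels[p + 1] == "H")
                       or (seg_pair[0] == "C" and seg_pair[1] == "C"
                           and 0 < p < m - 1 and dist[p - 1, p + 2] < 6.0))
            if "E" in seg_pair and not (labels[p] == "H" and labels[p + 1] == "H"):
                helical = False
            if helical:
                lams[p] = rng.normal(K.LAMBDA_HELIX, helix_sigma)
            else:
                lams[p] = rng.normal(K.LAMBDA_STRAND, extended_sigma)
        lams = (lams + np.pi) % (2 * np.pi) - np.pi
        series = LambdaSeries(lams, np.ones(m, dtype=bool))
        return _finish_chain(_random_sequence(rng, k), coords, series, chain_id)
    raise RuntimeError("could not generate a self-avoiding chain "
                       "(retry limit exceeded)")


def perturb_backbone(chain: SyntheticChain, sigma: float = 0.03,
                     seed: int = 0) -> BackboneStructure:
    """Synthetic stand-in for an experimental backbone: ideal-geometry
    coordinates plus isotropic Gaussian noise of width sigma [A] on every
    atom.  The result no longer has exactly planar, ideal plates, so
    true-lambda reconstruction incurs a small geometric error — the same
    error source a deposited crystal structure exhibits.
    """
    rng = np.random.default_rng(seed)
    bb = chain.backbone
    out = BackboneStructure(
        list(bb.residue_names),
        *(bb.coords(nm) + rng.normal(0.0, sigma, size=(bb.n_residues, 3))
          for nm in ("N", "CA", "C", "O")),
        chain_id=bb.chain_id)
    return out


# ---------------------------------------------------------------------------
# Conversions and corruption operators
# ---------------------------------------------------------------------------

def chain_from_backbone(backbone: BackboneStructure,
                        complete_only: bool = True) -> ProteinChain:
    """Convert a backbone into a ProteinChain of AtomRecords.

    With complete_only=True residues missing any backbone atom (the
    reconstruction termini) are dropped, so fixture chains pass the quality
    filter.
    """
    out = ProteinChain(chain_id=backbone.chain_id)
    ordinal = 0
    for i in range(backbone.n_residues):
        names = [nm for nm in ("N", "CA", "C", "O") if backbone.has_atom(i, nm)]
        if complete_only and len(names) < 4:
            continue
        for nm in names:
            out.atoms.append(AtomRecord(ordinal, backbone.residue_names[i],
                                        nm, backbone.coords(nm)[i].copy()))
        ordinal += 1
    return out


def corrupt(chain: SyntheticChain, mode: str, seed: int = 0) -> ProteinChain:
    """Introduce exactly one documented defect into a fixture chain.

    Modes: "delete-residue" (remove one interior residue), "delete-atom"
    (remove one carbonyl O), "stretch-bond" (displace an amide N 0.5 A
    along its peptide bond).
    """
    rng = np.random.default_rng(seed)
    pc = chain_from_backbone(chain.backbone)
    residues = pc.residues()
    n_res = len(residues)
    target = int(rng.integers(2, n_res - 2))
    if mode == "delete-residue":
        pc.atoms = [a for a in pc.atoms if a.residue_index != target]
    elif mode == "delete-atom":
        pc.atoms = [a for a in pc.atoms
                    if not (a.residue_index == target and a.atom_name == "O")]
    elif mode == "stretch-bond":
        atoms_prev = residues[target - 1][2]
        atoms_here = residues[target][2]
        c_pos = atoms_prev["C"].position
        n_rec = atoms_here["N"]
        direction = n_rec.position - c_pos
        direction /= np.linalg.norm(direction)
        n_rec.position = n_rec.position + 0.5 * direction
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return pc
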