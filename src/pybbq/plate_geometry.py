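"""Peptide-plate geometry: the lambda dihedral and backbone reconstruction.

The backbone between two consecutive alpha carbons is modelled as a rigid,
exactly planar peptide unit ("plate") of ideal geometry carrying the
carbonyl carbon and oxygen of residue *p* and the amide nitrogen (optionally
the amide hydrogen) of residue *p+1*.  Given a Calpha trace, the only degree
of freedom left per plate is a single dihedral angle lambda: the rotation of
the plate about the Ca_p -> Ca_{p+1} axis, measured against the plane
through three consecutive alpha carbons.  Knowing the trace and one lambda
per plate, every backbone heavy-atom position follows deterministically.

Plate *p* (0-based) spans Ca_p -> Ca_{p+1}; its reference alpha carbon is
Ca_{p+2} for interior plates and Ca_{p-1} for the final plate, which has no
following residue.  lambda = 0 places the plate inside the reference plane
with the carbonyl oxygen on the side of the reference atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import constants as K


class DegenerateGeometryError(ValueError):
    """Raised when points required to define a frame are (near) collinear."""


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------

def wrap_angle(theta):
    """Wrap an angle (scalar or array) into [-pi, pi)."""
    return (np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi


def torsion(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral angle p1-p2-p3-p4 in [-pi, pi)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise DegenerateGeometryError("central atoms coincide")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear atom triple in dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    return float(wrap_angle(np.arctan2(y, x)))


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float):
    """Place atom X bonded to c with |cX| = bond, angle(X,c,b) = angle and
    torsion(X,c,b,a) = dihedral (natural-extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("collinear frame in atom placement")
    n /= nn
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def classify_isomer(ca_a, ca_b) -> str:
    """cis/trans call for a peptide bond from its Ca-Ca pseudo-bond length.

    Pseudo-bonds shorter than 3.5 A are classified as cis; exactly 3.5 A
    counts as trans (strict inequality).
    """
    d = float(np.linalg.norm(np.asarray(ca_b, float) - np.asarray(ca_a, float)))
    return "cis" if d < K.CIS_THRESHOLD else "trans"


# ---------------------------------------------------------------------------
# Plate templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptidePlateTemplate:
    """Idealised planar peptide unit in a canonical local frame.

    Ca1 sits at the origin, Ca2 on the +x axis, every atom in the z = 0
    plane with the carbonyl oxygen at y > 0.
    """

    residue_class: str          # "generic" | "proline"
    isomer: str                 # "trans" | "cis"
    atoms: Mapping[str, np.ndarray]

    @property
    def ca_ca_distance(self) -> float:
        return float(np.linalg.norm(self.atoms["CA2"] - self.atoms["CA1"]))

    def plate_atom_names(self) -> list[str]:
        return [n for n in ("C", "O", "N", "H") if n in self.atoms]


def make_plate_template(residue_class: str = "generic", isomer: str = "trans",
                        include_h: bool = False) -> PeptidePlateTemplate:
    """Build the ideal peptide-plate template for one residue class/isomer."""
    if residue_class not in ("generic", "proline"):
        raise ValueError(f"unknown residue class {residue_class!r}")
    if isomer not in ("trans", "cis"):
        raise ValueError(f"unknown isomer {isomer!r}")
    pro = residue_class == "proline"
    b_cn = K.BOND_C_N_PROLINE if pro else K.BOND_C_N_GENERIC
    a_ca_c_n = (K.ANGLE_CA_C_N_PROLINE if pro else K.ANGLE_CA_C_N_GENERIC) * K.DEG
    a_o_c_n = (K.ANGLE_O_C_N_PROLINE if pro else K.ANGLE_O_C_N_GENERIC) * K.DEG
    a_c_n_ca = (K.ANGLE_C_N_CA_PROLINE if pro else K.ANGLE_C_N_CA_GENERIC) * K.DEG
    omega = np.pi if isomer == "trans" else 0.0

    ca1 = np.zeros(3)
    c = np.array([K.BOND_CA_C, 0.0, 0.0])
    n = c + b_cn * np.array([-np.cos(a_ca_c_n), np.sin(a_ca_c_n), 0.0])
    ca2 = _place_atom(ca1, c, n, K.BOND_N_CA, a_c_n_ca, omega)
    # carbonyl O: anti to Ca2 across the C-N bond in trans, syn in cis
    o = _place_atom(ca2, n, c, K.BOND_C_O, a_o_c_n, np.pi - omega)
    atoms = {"CA1": ca1, "C": c, "O": o, "N": n, "CA2": ca2}
    if include_h and not pro:
        atoms["H"] = _place_atom(o, c, n, K.BOND_N_H, K.ANGLE_C_N_H * K.DEG, np.pi)

    # canonical frame: Ca1 at origin, Ca2 direction = +x, O at y > 0, z = 0
    x = ca2 / np.linalg.norm(ca2)
    o_perp = o - np.dot(o, x) * x
    y = o_perp / np.linalg.norm(o_perp)
    z = np.cross(x, y)
    rot = np.stack([x, y, z])
    atoms = {name: rot @ pos for name, pos in atoms.items()}
    return PeptidePlateTemplate(residue_class, isomer, atoms)


_TEMPLATE_CACHE: dict[tuple, PeptidePlateTemplate] = {}


def get_template(residue_class: str, isomer: str,
                 include_h: bool = False) -> PeptidePlateTemplate:
    key = (residue_class, isomer, include_h)
    if key not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[key] = make_plate_template(residue_class, isomer, include_h)
    return _TEMPLATE_CACHE[key]


# ---------------------------------------------------------------------------
# Lambda series and backbone containers
# ---------------------------------------------------------------------------

@dataclass
class LambdaSeries:
    """Per-plate dihedral lambda with a defined/undefined mask.

    Entry p describes the plate between Ca_p and Ca_{p+1} (0-based,
    p = 0 .. K-2).
    """

    values: np.ndarray                  # (K-1,), radians in [-pi, pi)
    defined_mask: np.ndarray            # (K-1,) bool
    isomers: list[str] | None = None    # per-plate "trans" | "cis"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.values.shape != self.defined_mask.shape:
            raise ValueError("values and mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.defined_mask])):
            raise ValueError("non-finite lambda at a defined position")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BackboneStructure:
    """Per-residue N/Ca/C/O coordinates; NaN marks an absent atom."""

    residue_names: list[str]
    n: np.ndarray                       # (K, 3)
    ca: np.ndarray                      # (K, 3)
    c: np.ndarray                       # (K, 3)
    o: np.ndarray                       # (K, 3)
    chain_id: str = "A"
    lambdas: LambdaSeries | None = None  # provenance when reconstructed

    _FIELDS = {"N": "n", "CA": "ca", "C": "c", "O": "o"}

    def __post_init__(self):
        kk = len(self.residue_names)
        for name in ("n", "ca", "c", "o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (kk, 3):
                raise ValueError(f"{name} must have shape ({kk}, 3)")
            setattr(self, name, arr)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def coords(self, atom_name: str) -> np.ndarray:
        return getattr(self, self._FIELDS[atom_name])

    def has_atom(self, i: int, atom_name: str) -> bool:
        return bool(np.all(np.isfinite(self.coords(atom_name)[i])))

    def atom_items(self) -> Iterable[tuple[int, str, np.ndarray]]:
        """Yield (residue_index, atom_name, position) for present atoms."""
        for i in range(self.n_residues):
            for name in ("N", "CA", "C", "O"):
                if self.has_atom(i, name):
                    yield i, name, self.coords(name)[i]

    def transformed(self, rotation: np.ndarray, translation) -> "BackboneStructure":
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return BackboneStructure(
            list(self.residue_names),
            self.n @ rot.T + t, self.ca @ rot.T + t,
            self.c @ rot.T + t, self.o @ rot.T + t,
            chain_id=self.chain_id, lambdas=self.lambdas)


# ---------------------------------------------------------------------------
# Frames, placement and extraction
# ---------------------------------------------------------------------------

def plate_frame(ca_p, ca_next, reference_ca):
    """Right-handed orthonormal frame (u, v0, w0) for one plate.

    u points along the rotation axis Ca_p -> Ca_{p+1}; v0 is the in-plane
    direction towards the reference alpha carbon (lambda = 0); w0 = u x v0.
    """
    ca_p = np.asarray(ca_p, float)
    axis = np.asarray(ca_next, float) - ca_p
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError("zero-length plate axis")
    u = axis / norm
    r = np.asarray(reference_ca, float) - ca_p
    v = r - np.dot(r, u) * u
    vn = np.linalg.norm(v)
    if vn < 1e-9:
        raise DegenerateGeometryError("reference Ca collinear with plate axis")
    v0 = v / vn
    return u, v0, np.cross(u, v0)


def place_plate(template: PeptidePlateTemplate, ca_p, ca_next,
                lambda_p: float, reference_ca) -> dict[str, np.ndarray]:
    """Rigidly place one ideal plate: Ca1 onto ca_p, local +x along the
    Ca_p -> Ca_{p+1} axis, then rotate by lambda_p about that axis.

    Returns global positions of the plate atoms (C, O, N and H when the
    template carries one).
    """
    u, v0, w0 = plate_frame(ca_p, ca_next, reference_ca)
    cl, sl = np.cos(lambda_p), np.sin(lambda_p)
    ey = cl * v0 + sl * w0
    ez = cl * w0 - sl * v0
    ca_p = np.asarray(ca_p, float)
    out = {}
    for name in template.plate_atom_names():
        x, y, z = template.atoms[name]
        out[name] = ca_p + x * u + y * ey + z * ez
    return out


def _template_for_plate(sequence: Sequence[str], p: int, isomer: str,
                        include_h: bool = False) -> PeptidePlateTemplate:
    cls = "proline" if sequence[p + 1].upper() == "PRO" else "generic"
    return get_template(cls, isomer, include_h and cls == "generic")


def _reference_index(p: int, n_plates: int) -> int:
    """Reference Ca index for plate p: Ca_{p+2}, or Ca_{p-1} for the last."""
    return p + 2 if p < n_plates - 1 else p - 1


def lambda_from_backbone(backbone: BackboneStructure) -> LambdaSeries:
    """Measure lambda for every plate of a backbone.

    Each plate's lambda is the least-squares rotation of the ideal template
    about the Ca_p -> Ca_{p+1} axis that best overlays the observed C, O and
    N atoms (closed form: a weighted circular mean of their azimuths).  For
    a backbone built from ideal plates this recovers the construction angle
    exactly; for an experimental backbone it is the crmsd-optimal "true"
    lambda.  Plates with no usable plate atom are masked undefined.
    """
    kk = backbone.n_residues
    if kk < 3:
        raise ValueError("need at least 3 residues to define a plate frame")
    n_plates = kk - 1
    values = np.zeros(n_plates)
    mask = np.zeros(n_plates, dtype=bool)
    isomers: list[str] = []
    ca = backbone.ca
    for p in range(n_plates):
        isomer = classify_isomer(ca[p], ca[p + 1])
        isomers.append(isomer)
        tmpl = _template_for_plate(backbone.residue_names, p, isomer)
        try:
            u, v0, w0 = plate_frame(ca[p], ca[p + 1], ca[_reference_index(p, n_plates)])
        except DegenerateGeometryError:
            continue
        num = den = 0.0
        n_obs = 0
        for name, (i, key) in (("C", (p, "C")), ("O", (p, "O")), ("N", (p + 1, "N"))):
            if not backbone.has_atom(i, key):
                continue
            y = tmpl.atoms[name][1]
            d = backbone.coords(key)[i] - ca[p]
            num += y * float(np.dot(w0, d))
            den += y * float(np.dot(v0, d))
            n_obs += 1
        if n_obs == 0 or (abs(num) < 1e-12 and abs(den) < 1e-12):
            continue
        values[p] = wrap_angle(np.arctan2(num, den))
        mask[p] = True
    return LambdaSeries(values, mask, isomers)


def reconstruct_backbone(trace, lambdas: LambdaSeries,
                         include_h: bool = False) -> BackboneStructure:
    """Rebuild all heavy backbone atoms from a Calpha trace and lambdas.

    Plate p contributes C_p and O_p to residue p and N_{p+1} to residue
    p+1; the first residue's N and the last residue's C and O have no plate
    and are left absent.  Ca coordinates are copied from the trace
    unchanged.  Plates with an undefined lambda are skipped (their atoms
    stay absent).
    """
    ca = np.asarray(trace.coords, dtype=float)
    sequence = list(trace.sequence)
    kk = len(sequence)
    n_plates = kk - 1
    if len(lambdas) != n_plates:
        raise ValueError(f"lambda series covers {len(lambdas)} plates, "
                         f"expected {n_plates}")
    isomers = lambdas.isomers
    if isomers is None:
        isomers = [classify_isomer(ca[p], ca[p + 1]) for p in range(n_plates)]
    nan = np.full((kk, 3), np.nan)
    bb = BackboneStructure(sequence, nan.copy(), ca.copy(), nan.copy(),
                           nan.copy(), chain_id=getattr(trace, "chain_id", "A"))
    for p in range(n_plates):
        if not lambdas.defined_mask[p]:
            continue
        tmpl = _template_for_plate(sequence, p, isomers[p], include_h)
        placed = place_plate(tmpl, ca[p], ca[p + 1], lambdas.values[p],
                             ca[_reference_index(p, n_plates)])
        bb.c[p] = placed["C"]
        bb.o[p] = placed["O"]
        bb.n[p + 1] = placed["N"]
    bb.lambdas = LambdaSeries(lambdas.values.copy(),
                              lambdas.defined_mask.copy(), list(isomers))
    return bb
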