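"""Reading, validating and writing protein structures.

PDB and mmCIF input goes through gemmi; output is plain PDB with ATOM
records only.  The module also applies the training-set quality screen:
chains with missing residues, missing backbone atoms, alternate locations
or distorted backbone bond lengths are reported (and can be dropped) before
lambda extraction or training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import constants as K

AMINO_ACIDS_3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


class StructureError(Exception):
    """Base class for structure reading/validation failures."""


class TraceError(StructureError):
    """A Calpha trace violates its invariants (break, too short...)."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass
class AtomRecord:
    residue_index: int          # ordinal position within the chain (0-based)
    residue_name: str           # 3-letter code
    atom_name: str              # PDB atom name: N, CA, C, O, ...
    position: np.ndarray        # (3,) Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""


@dataclass
class ProteinChain:
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    had_alt_locs: bool = False

    def residues(self) -> list[tuple[int, str, dict[str, AtomRecord]]]:
        """Group atoms into (ordinal, residue_name, {atom_name: record})."""
        out: list[tuple[int, str, dict[str, AtomRecord]]] = []
        by_index: dict[int, dict[str, AtomRecord]] = {}
        names: dict[int, str] = {}
        for a in self.atoms:
            by_index.setdefault(a.residue_index, {})[a.atom_name] = a
            names.setdefault(a.residue_index, a.residue_name)
        for idx in sorted(by_index):
            out.append((idx, names[idx], by_index[idx]))
        return out


@dataclass
class CaTrace:
    """Ordered Calpha coordinates plus residue identities for one chain."""

    chain_id: str
    sequence: list[str]         # 3-letter codes, length K
    coords: np.ndarray          # (K, 3) Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError("coords shape does not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ChainQualityReport:
    accepted: bool
    reasons: list[str] = field(default_factory=list)


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def read_structure(path, fmt: str = "auto") -> list[ProteinChain]:
    """Read protein chains from a PDB or mmCIF file.

    Returns one ProteinChain per chain of the first model.  Waters and
    non-amino-acid heteroatoms are dropped; amino-acid residues are kept
    whether deposited as ATOM or HETATM (e.g. MSE).  When a residue carries
    alternate locations for an atom, the highest-occupancy conformer is
    kept and the chain is flagged.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    coor_format = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(fmt)
    if coor_format is None:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    chains: list[ProteinChain] = []
    model = st[0]
    for ch in model:
        out = ProteinChain(chain_id=ch.name)
        ordinal = 0
        for res in ch:
            if not _is_amino_acid(res.name):
                continue
            # collapse alt-locs: highest occupancy wins
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.altloc not in ("", "\0"):
                    out.had_alt_locs = True
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            for name, atom in best.items():
                out.atoms.append(AtomRecord(
                    residue_index=ordinal,
                    residue_name=res.name,
                    atom_name=name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    alt_loc="" if atom.altloc in ("", "\0") else atom.altloc,
                ))
            ordinal += 1
        if out.atoms:
            chains.append(out)
    if not chains:
        raise StructureError(f"{path}: no protein chains found")
    return chains


def extract_ca_trace(chain: ProteinChain) -> CaTrace:
    """Pull the ordered Calpha trace out of a chain and validate it.

    Raises TraceError (reason "too-short" or "chain-break") when the trace
    is shorter than the minimum usable length or a consecutive Ca-Ca
    pseudo-bond falls outside the allowed window.
    """
    sequence: list[str] = []
    coords: list[np.ndarray] = []
    for _, res_name, atoms in chain.residues():
        if "CA" in atoms:
            sequence.append(res_name)
            coords.append(atoms["CA"].position)
    if len(sequence) < K.MIN_RESIDUES:
        raise TraceError("too-short",
                         f"chain {chain.chain_id}: {len(sequence)} residues "
                         f"with Ca, need >= {K.MIN_RESIDUES}")
    xyz = np.asarray(coords, dtype=float)
    d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    bad = np.where((d < K.CA_CA_MIN) | (d > K.CA_CA_MAX))[0]
    if bad.size:
        raise TraceError("chain-break",
                         f"chain {chain.chain_id}: Ca-Ca distance "
                         f"{d[bad[0]]:.2f} A at position {int(bad[0])} "
                         f"outside [{K.CA_CA_MIN}, {K.CA_CA_MAX}] A")
    return CaTrace(chain.chain_id, sequence, xyz)


def chain_quality_filter(chain: ProteinChain) -> ChainQualityReport:
    """Training-set quality screen for one full-atom chain.

    A chain is accepted iff every residue carries all four backbone atoms,
    there is no chain break, no alternate locations were present, all
    backbone bond lengths sit within the stereochemistry window and the
    chain is long enough.
    """
    reasons: list[str] = []
    residues = chain.residues()
    if len(residues) < K.MIN_RESIDUES:
        reasons.append("too-short")
    if chain.had_alt_locs:
        reasons.append("alt-loc")
    for _, _, atoms in residues:
        if any(name not in atoms for name in ("N", "CA", "C", "O")):
            reasons.append("missing-backbone-atom")
            break
    # chain continuity via Ca pseudo-bonds
    breaks: set[int] = set()
    if all("CA" in atoms for _, _, atoms in residues):
        ca = np.array([atoms["CA"].position for _, _, atoms in residues])
        if len(ca) >= 2:
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            breaks = set(np.where((d < K.CA_CA_MIN) | (d > K.CA_CA_MAX))[0])
            if breaks:
                reasons.append("missing-residue")
    # stereochemistry screen: backbone bond lengths near ideal; the peptide
    # bond across an already-detected gap is not re-reported
    if "missing-backbone-atom" not in reasons:
        for i, (_, _, atoms) in enumerate(residues):
            bonds = [(atoms.get("N"), atoms.get("CA"), ("N", "CA")),
                     (atoms.get("CA"), atoms.get("C"), ("CA", "C")),
                     (atoms.get("C"), atoms.get("O"), ("C", "O"))]
            if i + 1 < len(residues) and i not in breaks:
                bonds.append((atoms.get("C"), residues[i + 1][2].get("N"),
                              ("C", "N")))
            for a, b, key in bonds:
                if a is None or b is None:
                    continue
                length = float(np.linalg.norm(a.position - b.position))
                if abs(length - K.IDEAL_BACKBONE_BONDS[key]) > K.BOND_TOLERANCE:
                    reasons.append("stereochemical-error")
                    break
            if "stereochemical-error" in reasons:
                break
    return ChainQualityReport(accepted=not reasons, reasons=reasons)


def backbone_from_chain(chain: ProteinChain):
    """Convert a full-atom chain into a BackboneStructure (NaN = absent)."""
    from .plate_geometry import BackboneStructure

    residues = chain.residues()
    kk = len(residues)
    arrays = {name: np.full((kk, 3), np.nan) for name in ("N", "CA", "C", "O")}
    names: list[str] = []
    for i, (_, res_name, atoms) in enumerate(residues):
        names.append(res_name)
        for atom_name in ("N", "CA", "C", "O"):
            if atom_name in atoms:
                arrays[atom_name][i] = atoms[atom_name].position
    return BackboneStructure(names, arrays["N"], arrays["CA"], arrays["C"],
                             arrays["O"], chain_id=chain.chain_id)


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H"}


def write_backbone(backbone, path) -> None:
    """Write one backbone (or a list of them) as a minimal PDB file.

    ATOM records only, element column filled, residues numbered from 1
    within each chain.
    """
    backbones = backbone if isinstance(backbone, (list, tuple)) else [backbone]
    lines: list[str] = []
    serial = 1
    wrote_any = False
    for bb in backbones:
        chain_id = (bb.chain_id or "A")[0]
        for i, atom_name, pos in bb.atom_items():
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite coordinate for {atom_name} {i}")
            res_name = bb.residue_names[i]
            name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{res_name:>3s} "
                f"{chain_id}{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {_ELEMENTS[atom_name]:>2s}")
            serial += 1
            wrote_any = True
        if wrote_any:
            lines.append(f"TER   {serial:5d}      "
                         f"{bb.residue_names[-1]:>3s} {chain_id}"
                         f"{bb.n_residues:4d}")
            serial += 1
    if not wrote_any:
        raise ValueError("backbone has no atoms to write")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
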