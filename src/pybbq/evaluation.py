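"""Reconstruction accuracy metrics.

crmsd is the coordinate root-mean-square deviation over atoms matched by
(residue index, atom name), computed without superposition: reconstruction
keeps the input Calpha coordinates, so reference and reconstruction already
share a frame.  An optional Kabsch superposition is available for
comparisons with methods that do move the trace.  Per-atom-type and
per-secondary-structure summaries report the mean and the mode of the
per-atom displacement distribution; lambda errors are periodic, folded into
[0, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plate_geometry import BackboneStructure, LambdaSeries, wrap_angle

MODE_BIN_WIDTH = 0.003  # Angstrom; histogram bin for mode estimation

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _matched_displacements(reference: BackboneStructure,
                           reconstructed: BackboneStructure,
                           atom_subset=None):
    """Per-atom displacement lengths for atoms present in both structures.

    Returns (distances, residue_indices, atom_names).
    """
    if reference.n_residues != reconstructed.n_residues:
        raise ValueError("structures differ in residue count")
    subset = tuple(atom_subset) if atom_subset is not None else BACKBONE_ATOMS
    dists, res_idx, names = [], [], []
    for name in subset:
        ref_xyz = reference.coords(name)
        rec_xyz = reconstructed.coords(name)
        ok = np.all(np.isfinite(ref_xyz), axis=1) & np.all(np.isfinite(rec_xyz), axis=1)
        d = np.linalg.norm(ref_xyz[ok] - rec_xyz[ok], axis=1)
        dists.append(d)
        res_idx.append(np.where(ok)[0])
        names.extend([name] * int(ok.sum()))
    return np.concatenate(dists), np.concatenate(res_idx), np.array(names)


def _kabsch_superpose(reference, reconstructed):
    """Best-fit rigid motion of `reconstructed` onto `reference` (matched atoms)."""
    p, q = [], []
    for name in BACKBONE_ATOMS:
        ref_xyz, rec_xyz = reference.coords(name), reconstructed.coords(name)
        ok = np.all(np.isfinite(ref_xyz), axis=1) & np.all(np.isfinite(rec_xyz), axis=1)
        p.append(rec_xyz[ok])
        q.append(ref_xyz[ok])
    p, q = np.concatenate(p), np.concatenate(q)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return reconstructed.transformed(rot, qc - rot @ pc)


def crmsd(reference: BackboneStructure, reconstructed: BackboneStructure,
          atom_subset=None, superpose: bool = False) -> float:
    """Root-mean-square per-atom displacement over matched atoms [A]."""
    if superpose:
        reconstructed = _kabsch_superpose(reference, reconstructed)
    d, _, _ = _matched_displacements(reference, reconstructed, atom_subset)
    if d.size == 0:
        raise ValueError("no matched atoms between the two structures")
    return float(np.sqrt(np.mean(d ** 2)))


def _mode(d: np.ndarray) -> float:
    """Midpoint of the most populated fixed-width histogram bin."""
    if d.size == 0:
        return float("nan")
    edges = np.arange(0.0, d.max() + 2 * MODE_BIN_WIDTH, MODE_BIN_WIDTH)
    counts, edges = np.histogram(d, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


@dataclass
class GroupStats:
    mean: float
    std: float
    mode: float
    n: int


@dataclass
class ReconstructionReport:
    crmsd_all: float
    per_atom: dict = field(default_factory=dict)     # atom name -> GroupStats
    per_sse: dict = field(default_factory=dict)      # H/E/C -> GroupStats
    lambda_error_mean: float | None = None
    n_atoms_compared: int = 0
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {"crmsd_all": self.crmsd_all,
               "n_atoms_compared": self.n_atoms_compared,
               "per_atom": {}, "per_sse": {}, "notes": list(self.notes)}
        if self.lambda_error_mean is not None:
            out["lambda_error_mean"] = self.lambda_error_mean
        for key, group in (("per_atom", self.per_atom), ("per_sse", self.per_sse)):
            for name, st in group.items():
                out[key][name] = {"mean": st.mean, "std": st.std,
                                  "mode": st.mode, "n": st.n}
        return out


def per_group_report(reference: BackboneStructure,
                     reconstructed: BackboneStructure,
                     sse=None, atom_subset=("N", "C", "O")) -> ReconstructionReport:
    """Displacement statistics grouped by atom type and by SSE class.

    Calpha atoms are excluded from the groups by default (they are copied
    from the input and carry no reconstruction error); crmsd_all covers the
    same subset.  Each atom inherits the SSE label of its residue.  Empty
    groups are omitted with a note.
    """
    d, res_idx, names = _matched_displacements(reference, reconstructed,
                                               atom_subset)
    if d.size == 0:
        raise ValueError("no matched atoms between the two structures")
    report = ReconstructionReport(
        crmsd_all=float(np.sqrt(np.mean(d ** 2))),
        n_atoms_compared=int(d.size))
    for name in atom_subset:
        sel = names == name
        if not sel.any():
            report.notes.append(f"no atoms of type {name}")
            continue
        dd = d[sel]
        report.per_atom[name] = GroupStats(float(dd.mean()), float(dd.std()),
                                           _mode(dd), int(dd.size))
    if sse is not None:
        labels = np.array(sse.labels if hasattr(sse, "labels") else sse)
        atom_labels = labels[res_idx]
        for cls in ("H", "E", "C"):
            sel = atom_labels == cls
            if not sel.any():
                report.notes.append(f"no residues in SSE class {cls}")
                continue
            dd = d[sel]
            report.per_sse[cls] = GroupStats(float(dd.mean()), float(dd.std()),
                                             _mode(dd), int(dd.size))
    return report


def lambda_error(true: LambdaSeries, predicted: LambdaSeries):
    """Periodic per-plate error |wrap(true - predicted)| in [0, pi].

    Returns (per-plate errors with NaN at undefined positions, mean over
    the positions defined in both series).
    """
    if len(true) != len(predicted):
        raise ValueError("lambda series differ in length")
    both = true.defined_mask & predicted.defined_mask
    if not both.any():
        raise ValueError("no positions defined in both series")
    err = np.full(len(true), np.nan)
    err[both] = np.abs(wrap_angle(true.values[both] - predicted.values[both]))
    # wrap_angle maps pi to -pi, so |err| <= pi holds exactly
    return err, float(np.nanmean(err[both]))
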