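"""Per-residue input features computed from a Calpha trace alone.

Each residue is described by 37 values:

====== ===== ==============================================================
columns width content
====== ===== ==============================================================
0-20     21  one-hot residue type (20 canonical amino acids + X)
21-26     6  |Ca_i - Ca_{i+-j}| for j = 3, 4, 5 (order -3, -4, -5, +3, +4, +5)
27-30     4  Calpha neighbor counts within 4, 4.5, 5 and 6 A
31-33     3  one-hot secondary structure (H, E, C)
34        1  cis flag for the peptide bond (i, i+1)
35-36     2  helix- and strand-type hydrogen-bond partner counts
====== ===== ==============================================================

Distances out of chain range use the sentinel 0.0, which no real Calpha
pair can attain.  Secondary structure and hydrogen bonds come from
Calpha-only geometric rules (distance-window heuristics standing in for a
dedicated H/E/C assigner and a coarse-grained H-bond potential); their
thresholds live in :mod:`pybbq.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import constants as K
from .plate_geometry import classify_isomer
from .structure_io import AMINO_ACIDS_3, CaTrace

N_FEATURES = 37

FEATURE_COLUMNS = (
    [f"aa_{aa}" for aa in AMINO_ACIDS_3] + ["aa_X"]
    + [f"d_ca_{j:+d}" for j in (-3, -4, -5, 3, 4, 5)]
    + [f"n_within_{r:g}A" for r in K.NEIGHBOR_RADII]
    + ["sse_H", "sse_E", "sse_C", "cis_flag", "hbond_helix", "hbond_strand"]
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS_3)}


@dataclass
class SSEAssignment:
    """Per-residue secondary-structure label in {H, E, C}."""

    labels: list[str]

    def __post_init__(self):
        if any(l not in ("H", "E", "C") for l in self.labels):
            raise ValueError("labels must be H, E or C")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class FeatureMatrix:
    """K x 37 network input with a fixed, documented column layout."""

    values: np.ndarray
    column_names: tuple = tuple(FEATURE_COLUMNS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be K x {N_FEATURES}")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        header = "\t".join(self.column_names)
        np.savetxt(path, self.values, fmt="%.6g", delimiter="\t",
                   header=header, comments="")


def one_hot_residues(sequence) -> np.ndarray:
    """K x 21 one-hot encoding; unknown residue types map to the X slot."""
    out = np.zeros((len(sequence), 21))
    for i, name in enumerate(sequence):
        out[i, _AA_INDEX.get(name.upper(), 20)] = 1.0
    return out


def local_ca_distances(trace: CaTrace) -> np.ndarray:
    """K x 6 distances |Ca_i - Ca_{i+-j}|, j in {3,4,5}; 0.0 out of range."""
    xyz = trace.coords
    kk = len(trace)
    out = np.zeros((kk, 6))
    for col, off in enumerate((-3, -4, -5, 3, 4, 5)):
        for i in range(kk):
            j = i + off
            if 0 <= j < kk:
                out[i, col] = np.linalg.norm(xyz[i] - xyz[j])
    return out


def neighbor_counts(trace: CaTrace) -> np.ndarray:
    """K x 4 counts of other Calpha atoms strictly within each radius."""
    dm = squareform(pdist(trace.coords))
    np.fill_diagonal(dm, np.inf)
    return np.stack([(dm < r).sum(axis=1) for r in K.NEIGHBOR_RADII],
                    axis=1).astype(float)


def _runs_mask(flags: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True positions belonging to a run of >= min_run."""
    out = np.zeros_like(flags)
    i = 0
    kk = len(flags)
    while i < kk:
        if flags[i]:
            j = i
            while j < kk and flags[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def assign_secondary_structure(trace: CaTrace) -> SSEAssignment:
    """H/E/C labels from Calpha-only distance patterns.

    A residue is helical when d(i,i+3) and d(i,i+4) sit inside the helix
    windows over a run of at least three residues.  It is strand when its
    local geometry is extended (d(i,i+2) above the threshold over a run of
    at least two) and a strand-type partner exists in another extended
    region.  Everything else is coil.
    """
    xyz = trace.coords
    kk = len(trace)
    d = local_ca_distances(trace)
    d13, d14 = d[:, 3], d[:, 4]
    lo3, hi3 = K.HELIX_D13_WINDOW
    lo4, hi4 = K.HELIX_D14_WINDOW
    h_raw = (d13 >= lo3) & (d13 <= hi3) & (d14 >= lo4) & (d14 <= hi4)
    helix = _runs_mask(h_raw, K.HELIX_MIN_RUN)

    # extended if any i+-2 window covering residue i is stretched
    d12 = np.linalg.norm(xyz[2:] - xyz[:-2], axis=1)
    stretched = d12 > K.STRAND_D12_MIN
    ext_raw = np.zeros(kk, dtype=bool)
    for s in range(kk - 2):
        if stretched[s]:
            ext_raw[s:s + 3] = True
    ext = _runs_mask(ext_raw, K.STRAND_MIN_RUN)
    dm = squareform(pdist(xyz))
    lo, hi = K.HBOND_STRAND_WINDOW
    strand = np.zeros(kk, dtype=bool)
    for i in np.where(ext & ~helix)[0]:
        js = np.where(ext & (np.abs(np.arange(kk) - i) >= K.HBOND_STRAND_MIN_SEP)
                      & (dm[i] >= lo) & (dm[i] <= hi))[0]
        if js.size:
            strand[i] = True

    labels = ["H" if helix[i] else ("E" if strand[i] else "C")
              for i in range(kk)]
    return SSEAssignment(labels)


def hbond_counts(trace: CaTrace, sse: SSEAssignment) -> np.ndarray:
    """K x 2 counts of helix-type and strand-type H-bond partners.

    Helix partners: |i-j| in {3,4}, Ca distance inside the helix window,
    both residues labeled H.  Strand partners: |i-j| >= 3, distance inside
    the strand window, both labeled E.
    """
    kk = len(trace)
    dm = squareform(pdist(trace.coords))
    lab = np.array(sse.labels)
    sep = np.abs(np.arange(kk)[:, None] - np.arange(kk)[None, :])
    h_lo, h_hi = K.HBOND_HELIX_WINDOW
    s_lo, s_hi = K.HBOND_STRAND_WINDOW
    is_h = lab == "H"
    is_e = lab == "E"
    helix_pairs = (np.isin(sep, K.HBOND_HELIX_SEP) & (dm >= h_lo) & (dm <= h_hi)
                   & is_h[:, None] & is_h[None, :])
    strand_pairs = ((sep >= K.HBOND_STRAND_MIN_SEP) & (dm >= s_lo) & (dm <= s_hi)
                    & is_e[:, None] & is_e[None, :])
    return np.stack([helix_pairs.sum(axis=1), strand_pairs.sum(axis=1)],
                    axis=1).astype(float)


def cis_flags(trace: CaTrace) -> np.ndarray:
    """K x 1 cis flag for the peptide bond between residues i and i+1."""
    kk = len(trace)
    out = np.zeros((kk, 1))
    for i in range(kk - 1):
        if classify_isomer(trace.coords[i], trace.coords[i + 1]) == "cis":
            out[i, 0] = 1.0
    return out


def build_feature_matrix(trace: CaTrace,
                         standardize: bool = False) -> FeatureMatrix:
    """Assemble the full K x 37 feature matrix for one trace.

    Features are raw (Angstrom / counts) by default; standardize=True
    applies per-column standardization (zero mean, unit variance over the
    chain) to the non-one-hot columns, for experimentation.
    """
    sse = assign_secondary_structure(trace)
    sse_onehot = np.zeros((len(trace), 3))
    for i, lab in enumerate(sse.labels):
        sse_onehot[i, "HEC".index(lab)] = 1.0
    blocks = [
        one_hot_residues(trace.sequence),
        local_ca_distances(trace),
        neighbor_counts(trace),
        sse_onehot,
        cis_flags(trace),
        hbond_counts(trace, sse),
    ]
    values = np.concatenate(blocks, axis=1)
    if standardize:
        cols = slice(21, 31)
        sub = values[:, cols]
        std = sub.std(axis=0)
        std[std == 0] = 1.0
        values[:, cols] = (sub - sub.mean(axis=0)) / std
    return FeatureMatrix(values)
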