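# Methods

## Geometry: plates, frames and the λ dihedral

A peptide plate is the rigid planar unit {Cα₁, C, O, N, (H), Cα₂} between
two consecutive alpha carbons.  Templates are built once per
(residue class, isomer) pair from a single table of ideal constants
(`pybbq.constants`): Engh–Huber-style bond lengths (Cα–C 1.525 Å, C–O
1.231 Å, C–N 1.329/1.341 Å generic/proline, N–Cα 1.458 Å) and planar
angles, with ω = 180° (trans) or 0° (cis).  Templates are stored in a
canonical frame — Cα₁ at the origin, Cα₂ on +x, all atoms in the z = 0
plane, O at y > 0 — which fixes every sign convention in one place.  The
trans template's Cα–Cα distance comes out at 3.804 Å and the cis at
2.77 Å, consistent with the 3.5 Å pseudo-bond threshold used to call
cis peptide bonds.

Plate *p* (0-based) spans Cα_p → Cα_{p+1}.  Its reference alpha carbon is
Cα_{p+2}; the final plate, which has none, reuses Cα_{p−1} with the same
frame construction.  The frame is (u, v₀, w₀) with u the unit axis, v₀
the in-plane unit vector toward the reference atom and w₀ = u × v₀.
**Placement** maps the template's +x to u and rotates its +y to
cos λ · v₀ + sin λ · w₀, so λ = 0 lays the plate in the reference plane
with the carbonyl O on the reference side.  **Extraction** is the exact
inverse: the closed-form least-squares rotation of the template about the
axis that best overlays the observed C, O and N atoms,

λ* = atan2(Σₐ yₐ (w₀·dₐ), Σₐ yₐ (v₀·dₐ)),

where yₐ is the template atom's off-axis coordinate and dₐ the observed
offset from Cα_p.  For a backbone built from ideal plates this recovers
the construction angle to machine precision (the round-trip identity that
anchors the test suite); for an experimental backbone it is the λ that
minimises the plate's crmsd, which is the natural "true λ" for measuring
the residual error of the planarity assumption.  Missing atoms simply
drop out of the sums; a plate with no usable atom is masked undefined.

Consequences worth knowing: only Cα₁ and the axis direction are aligned,
so plate-internal bonds keep their exact ideal lengths while the template
Cα₂ may miss the actual next alpha carbon by the Cα–Cα distance mismatch
(a few hundredths of an Ångström in practice).  The first residue's N and
the last residue's C and O have no plate and are never rebuilt; OXT and
side chains are out of scope.

## Features (K × 37)

Columns, per residue: residue one-hot (21, unknown types → X), local
distances d(i, i±j), j ∈ {3, 4, 5} with 0.0 as the out-of-range sentinel,
neighbor counts within 4/4.5/5/6 Å (strict inequality, sequence neighbors
included), H/E/C one-hot, cis flag for bond (i, i+1), and helix-/
strand-type H-bond counts.  Features are raw Ångströms and counts; a
standardization switch exists for experimentation but is off by default.

The secondary-structure assigner and the H-bond counter are deliberately
simple Cα-only stand-ins for a full assigner: H requires d(i,i+3) ∈
[4.5, 6.0] Å and d(i,i+4) ∈ [5.5, 6.9] Å over runs of ≥ 3; E requires
locally stretched geometry (any covering d(i,i+2) window > 6.3 Å, runs of
≥ 2) plus an extended partner at |i−j| ≥ 3 within [4.2, 5.6] Å; the rest
is coil.  H-bond counts reuse the same windows gated by the labels, so
isolated extended chains count zero — the feature that lets the network
separate stretched loops from paired strands.  All thresholds live in
`pybbq.constants`.

## Network and training

Five same-length zero-padded 1D convolutions (kernel sizes 11, 9, 5, 3, 1;
ReLU hidden, linear output; He initialisation), mapping K × 37 to K × 2 =
(sin λ, cos λ) for any K ≥ 1.  Output position *i* carries the plate
between Cα_{i−1} and Cα_i; position 0 is masked.  Loss is MSE over the
two channels restricted to defined plates.  Training is plain Adam, one
chain per step (variable K needs no batching), a 10 % chain-level
validation split, early stopping on validation loss, and is bit-for-bit
reproducible from the config seed.  The arctangent recovery is invariant
to positive rescaling of (sin, cos), so outputs are never renormalised;
an exactly-zero pair is flagged undefined rather than guessed.

The reference width is 1024 kernels per hidden layer.  All shipped tests
and the acceptance script use the same architecture at widths 16–64,
which trains in seconds to half a minute on one CPU core; the width is
the only scaled-down quantity.

## Synthetic data

The generator produces chains whose trace, backbone, λ series and SSE
labels are mutually consistent by construction (the backbone is realised
from the trace and λ through the reconstruction path, so extraction
returns the stored values exactly).  Traces are built from pseudo-bond
internal coordinates in alternating segments: helical segments reuse the
ideal helix geometry (radius 2.276 Å, rise 1.558 Å, twist 99.4°/residue,
derived once from a φ = −57°, ψ = −47° ideal-dihedral backbone), extended
segments use ~125° pseudo-angles, coil segments are random.  Chains with
any non-bonded Cα pair under 3.0 Å are resampled.

λ per plate follows a two-mode mixture tied to geometry: a narrow mode
(σ = 0.10 rad) at the canonical helix value (1.237 rad, measured once
from the ideal-dihedral helix and frozen) when the plate sits in helical
geometry — decided by the same Cα-only rules the feature extractor uses —
and a broad mode (σ = 0.45 rad) at the canonical extended value
(1.935 rad) otherwise.  Tying the mode to observable geometry makes λ a
noisy but learnable function of the features, which is precisely the
working hypothesis of the method; the σ values set the irreducible
prediction error (≈ 0.08 rad in helices).

What the generator does *not* emulate: real φ/ψ statistics and their
residue-type dependence, plate non-planarity and bond-angle variance of
refined structures (available separately as Gaussian coordinate
perturbation, `perturb_backbone`, default σ = 0.03 Å), crystallographic
artifacts, and amino-acid composition bias.  Passing tests therefore
demonstrate the geometric machinery exactly and the learning machinery on
an idealised but honest analogue of the real task — not real-data
accuracy, which requires training on a curated crystal-structure corpus.

## Numerical choices and conventions

* Angles are radians internally, [−π, π); degrees only at the CLI.
* Torsion of collinear points raises a degenerate-geometry error; the
  plate frame requires the reference atom off-axis by > 1e−9 Å.
* Cα–Cα pseudo-bond window [2.6, 4.3] Å (admits cis bonds, rejects
  gaps); exactly 3.5 Å classifies as trans (strict inequality for cis).
* Quality screen: all four backbone atoms per residue, no alternate
  locations (highest-occupancy conformer is kept and the chain flagged),
  no Cα window violation, backbone bond lengths within ±0.2 Å of ideal;
  the peptide bond across an already-detected gap is not double-reported
  as a stereochemical error.  Minimum usable chain length is 6 (the
  feature window reaches i ± 5).
* crmsd uses no superposition (shared Cα frame); a Kabsch superposition
  is available behind a flag for cross-method comparisons.  Per-group
  reports exclude Cα (zero error by construction) and estimate the mode
  as the midpoint of the fullest 0.003 Å histogram bin.
* Insertion-coded residues are distinct residues in file order; only the
  first model of multi-model files is read; amino-acid residues deposited
  as HETATM (e.g. MSE) are kept, waters and ligands dropped.
* Problem sizes in the shipped tests and acceptance script — 200 training
  chains of 50 residues, width-64 network, 20–200 chains per geometric
  property — were chosen so a full run completes in well under a minute
  while leaving every measured quantity stable to the reported precision.

## Known limitations

* Terminal atoms (first N, last C/O, OXT) and all side-chain/Cβ atoms are
  not reconstructed.
* The H/E/C assigner and H-bond counter are heuristic stand-ins; their
  labels are self-consistent within the package but not interchangeable
  with DSSP-class assignments on real structures.
* The chain-break and stereochemistry thresholds of the quality filter
  are package choices; refined structures with unusual but genuine
  geometry can be rejected.
* Predicted-λ accuracy on real proteins depends entirely on the training
  corpus; the shipped configuration demonstrates the pipeline at
  synthetic desk scale.
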