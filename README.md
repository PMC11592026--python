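# pybbq — protein backbone reconstruction from a Cα trace

Coarse-grained protein models, and some experimental pipelines (e.g.
Cα-only traces fitted into cryo-EM maps), represent a protein chain by its
alpha-carbon positions alone.  Downstream tools almost always need the full
backbone.  `pybbq` rebuilds every heavy backbone atom — amide N, carbonyl C
and O — from nothing but the ordered Cα coordinates and the sequence.

## The model

The peptide bond's partial double-bond character keeps the atoms
C*ᵢ*, O*ᵢ*, N*ᵢ*₊₁ (and the amide hydrogen) of each peptide unit in a
single plane.  `pybbq` treats that unit as a rigid, ideally planar
**peptide plate** (Engh–Huber-style bond lengths and angles; separate
templates for generic/proline residues and trans/cis isomers).  With the
two flanking Cα positions fixed, the only remaining degree of freedom per
plate is one dihedral angle **λ**: the rotation of the plate about the
Cαᵢ→Cαᵢ₊₁ axis, measured against the plane through three consecutive
alpha carbons (the Purisima convention).  Given the trace and one λ per
plate, all backbone coordinates follow deterministically — and conversely,
λ can be measured from any full backbone, so the mapping is exactly
invertible.

λ itself is predicted by a five-layer 1D convolutional network from 37
per-residue features computed from the Cα trace alone: a 21-slot residue
one-hot, six local distances |Cαᵢ−Cαᵢ±ⱼ| (j = 3, 4, 5), four neighbor
counts (4/4.5/5/6 Å), an H/E/C secondary-structure one-hot, a cis-peptide
flag (Cα–Cα < 3.5 Å), and helix/strand hydrogen-bond counts.  Because a
dihedral is periodic, the network regresses (sin λ, cos λ) under an MSE
loss and the angle is recovered with the quadrant-aware arctangent.  The
reference architecture uses 1024 kernels of sizes 11, 9, 5, 3 plus a
two-channel 1×1 output layer; narrower same-shape variants train in
seconds on a CPU.

Accuracy is scored as **crmsd**: the root-mean-square per-atom displacement
between the reference and rebuilt backbones in their common frame (the
reconstruction keeps the input Cα positions, so no superposition is
involved), plus a periodic λ error in [0, π].

## Worked example

Everything below uses synthetic chains from `pybbq.fixtures`, so it runs
anywhere.  Train a small model on 40 ideal-geometry chains, then rebuild a
60-residue chain from its Cα trace:

```sh
$ pybbq train train/ -o model.npz --width 32 --epochs 40
trained on 40 chains, final val loss 0.07396

$ pybbq reconstruct ca_only.pdb -m model.npz -o rebuilt.pdb
chain A: K=58, lambda mean 83.3 deg, spread 19.0 deg

$ pybbq evaluate ref/ rec/ -o eval.json
1 chains, mean crmsd 0.244 A
```

The 0.244 Å mean crmsd is the end-to-end reconstruction error of the
predicted-λ pipeline on this chain.  To isolate the geometric error of the
planar-plate assumption itself, rebuild from λ values measured on the
full-atom structure:

```sh
$ pybbq true-lambda full.pdb -o true_rebuilt.pdb -r true_report.json
chain A: K=58, true-lambda crmsd 0.001 A
```

On an ideal-geometry input the true-λ rebuild is exact up to PDB
coordinate rounding (0.001 Å); on experimentally refined structures the
same pipeline leaves a residual of a few hundredths of an Ångström, which
is the cost of assuming ideal planar plates.  The JSON report breaks the
error down by atom type (N/C/O) and secondary structure (H/E/C); carbonyl
O is always the worst-reconstructed atom because it lies farthest from the
rotation axis.

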