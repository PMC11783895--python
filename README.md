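# flexfrag

A toolkit for studying how well machine-learning models recognize **flexible
3D objects**, using protein building blocks as the test bed.  Single amino
acid residues (20 classes) and consecutive dipeptide stretches (20 × 20 = 400
classes) are excised from protein structures, chemically completed to a
uniform neutral free-molecule form, and featurized four ways — raw point
clouds, molecular surface meshes, Gaussian atom-density voxel grids, and 2D
Hilbert-curve images.  Because every in-class difference is purely
conformational (the covalent graph is fixed; only dihedral angles move), a
classifier that succeeds on a conformation-blocked split must have learned to
abstract shape from identity rather than memorize poses.

The package is for researchers benchmarking 3D featurizations and classifier
architectures: it needs **no downloads** — a synthetic conformer generator
builds ideal-geometry ensembles of any class by dihedral sampling, so the
entire pipeline (extract/generate → featurize → block → store → train →
evaluate) runs self-contained on a laptop CPU.

## The core methods

**Chemical completion.**  Fragments are normalized to the neutral free
molecule: NH₂ amine, COOH acid (`OXT`/`HXT` added), His fixed to the
Nδ-protonated neutral tautomer, Cys with its thiol hydrogen.  This forces the
printed per-class atom counts (e.g. Met/His/Gln 20, Leu/Ile 22, Pro/Thr 17
atoms) and makes every class topologically homogeneous.  Missing hydrogens
and terminal atoms are rebuilt from per-residue internal-coordinate
templates anchored on the existing heavy atoms, which pass through
untouched.

**Gaussian voxelization.**  With uniform atom weight *w* = 1 (no hidden
element encoding), the density at voxel center **v** is

    ρ(v) = Σ_atoms w · exp( −d(v, atom)² / 2σ² ),   d ≤ r_cut

on a 32×32×32 grid over a 16 Å cube (0.5 Å spacing), σ = 1 Å,
r_cut = 12 Å, after moving the fragment's geometric center to the box
center.

**Hilbert images.**  The 32³ grid is flattened along the order-5 3D Hilbert
curve (2¹⁵ cells), downsampled 2× by pair means, and folded along the
order-7 2D curve into a 128×128 image.  Consecutive curve cells are always
lattice neighbors, so 3D locality survives the dimension change far better
than row-major flattening.

**Conformation blocking.**  Per class: pairwise heavy-atom RMSD (optimal
rigid superposition, capped at 5,000 samples) → Butina leader clustering at
0.75 × mean RMSD → bottom 25% of the size-ranked clusters go exclusively to
the test set → clusters larger than 30 are subdivided by t-SNE (on the RMSD
metric) + Ward agglomeration into 10 subclusters, from which ≤ 10 train /
≤ 5 test samples are drawn; small clusters get a random 2:1 split of at
most 15 samples.

**Training protocol.**  Cross-entropy, Adam (β = 0.9/0.999), initial lr
10⁻³ halved every 30 epochs, ≤ 120 epochs, batch 64, He-normal conv
initialization, early stop once test accuracy exceeds 99.5%.  Baseline
models: a PointNet-style point-cloud classifier, a VoxNet-style 3D CNN with
parametric rectifiers, and an 18-layer residual image CNN — implemented on
a compact numpy training core, so everything runs (and is exactly
reproducible) on one CPU.

## Worked example

```bash
# 1. synthesize a 5-class single-residue dataset (no downloads)
flexfrag synth --classes ALA,SER,THR,VAL,LEU --n 300 --seed 1 --out demo.h5

# 2. featurize: prepared point clouds, voxels, Hilbert images
flexfrag featurize --in demo.h5 --rep voxel --rep hilbert --rep points

# 3. conformation-blocked split
flexfrag split --in demo.h5 --mode baseline --seed 0 --out demo_split.json

# 4. train the small voxel CNN on a random 80/20 split
flexfrag train --store demo.h5 --rep voxel --arch voxnet_small --epochs 15 --seed 0
```

The four commands print:

```
wrote 1500 conformers -> demo.h5
collections now: ['coord', 'hilbert', 'points', 'voxel']
276 train / 154 test -> demo_split.json
final test accuracy: 100.00% (early stop)
```

The voxel CNN assigns the correct residue class to all 300 held-out
synthetic conformers and triggers the 99.5% early-stopping rule before the
epoch budget — the five classes are distinguished entirely from shape,
since the density kernel deliberately hides element types.  The blocked
split (step 3) is the stringent alternative: of the 1,500 conformers it
keeps 276 for training and 154 for testing, tags everything with cluster
provenance, and draws test samples deliberately from low-likelihood
conformations.

## Layout

| module | role |
| --- | --- |
| `flexfrag.chemistry` | residue/dipeptide templates, internal coordinates |
| `flexfrag.extraction` | PDB parsing, fragment harvesting, completion |
| `flexfrag.featurize` | point clouds, voxels, Hilbert images, surfaces |
| `flexfrag.hilbert` | n-dimensional Hilbert curves |
| `flexfrag.split` | RMSD superposition, Butina clustering, blocked splits |
| `flexfrag.store` | indexed HDF5 feature storage + loaders + benchmark |
| `flexfrag.nn`, `flexfrag.harness` | training core, models, protocol, confusion analysis |
| `flexfrag.generator` | synthetic conformer ensembles |
| `flexfrag.workflows`, `flexfrag.cli` | store-level pipelines and the CLI |

See `docs/methods.md` for the scientific details and design choices.
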