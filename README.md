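# atlasfuse

Multi-atlas segmentation of 3-D brain MRI with **graph-based atlas
selection** and **weighted majority-voting label fusion**.

## The problem

Transferring labels from a single expert-segmented atlas to a new subject
through deformable registration fails when the atlas is anatomically far
from the subject. Using *many* atlases and fusing their propagated labels
averages out registration and labelling errors, but an atlas population
with over-represented anatomical sub-types biases the vote. `atlasfuse`
addresses both issues: it clusters the atlas population *per subject* on a
cost graph and lets each cluster contribute exactly one exemplar
("neighboring template") to the vote, so every anatomical mode is
represented once and the templates actually used are the ones closest to
the subject.

## The method

All atlases and the subject are pairwise co-registered (any deformable
registration tool can supply the displacement fields; a built-in
demons-style registrator handles phantom-scale work). A directed graph is
built over the atlases and the subject where edge *i → j* costs

```
e_ij = w1 · M̂_ij + w2 · Ĥ_ij        (defaults w1 = 0.2, w2 = 0.8)
```

* `M_ij` — mean squared voxel-wise intensity difference between image *j*
  and image *i* warped onto it: `M_ij = (1/N) Σ_m (i_m − j_m)²`;
* `H_ij` — harmonic energy of the *i → j* displacement field: the mean
  Frobenius norm of the Jacobian of the displacement (0 for the identity);
* each term min–max normalized to [0, 1] over all edges (the hat).

Floyd–Warshall shortest paths from every atlas to the subject (bottleneck
path cost by default — see `docs/methods.md`) induce the clustering:
atlases whose shortest paths share a vertex belong to one cluster. Each
cluster's member closest to the subject becomes its exemplar, with voting
weight `1 − e(exemplar → subject)`. Exemplar labels are warped to the
subject grid (nearest-neighbour) and fused per voxel by weighted majority
vote.

Segmentations are scored with Dice overlap
(`DSC = 2|A∩B| / (|A|+|B|) × 100%`), symmetric mean absolute surface
distance (MAD, mm) and symmetric Hausdorff distance (mm).

Inputs are assumed preprocessed: bias-corrected, rigidly co-aligned to a
common space, and skull-stripped.

## Worked example

No clinical data is needed: the package ships a phantom generator that
produces an atlas population with known cluster structure (three
anatomical "modes" of three members each, deformed at two scales) plus a
subject with ground-truth labels.

```sh
atlasfuse simulate --out demo --seed 5          # population + ground-truth fields
atlasfuse run --config demo/config.yaml         # full pipeline
```

prints (seed 5):

```
exemplars: ['atlas00', 'atlas03', 'atlas08'] (weights [0.4, 0.457, 0.4])
fused labels written to demo/results/fused_labels.nii.gz
 label name  dsc_percent   mad_mm  hausdorff_mm  present_in_ref
     1    1    96.562500 0.155768      1.000000            True
     2    2    92.121212 0.150463      1.414214            True
     3    3    95.501730 0.120773      1.000000            True
     4    4    93.172691 0.136380      1.000000            True
    -1 mean    94.339533 0.140846      1.103553            True
```

Exactly one exemplar was picked from each of the three simulated modes
(atlases 0–2, 3–5, 6–8); the fused segmentation overlaps the ground truth
at 92–97% Dice per structure with sub-voxel mean surface error. The same
flow is available stage-by-stage (`register-all`, `build-graph`, `select`,
`fuse`, `evaluate`), with every intermediate artifact (pairwise fields,
cost matrices as CSV, selection JSON, confidence map) persisted for audit,
and precomputed fields from any external registration tool can be injected
via `backend: external`.

As a library:

```python
import atlasfuse as af

pop  = af.make_population(af.PopulationSpec(seed=5))
regs = af.oracle_registrations(pop)                      # ground-truth fields
g    = af.build_graph(pop.subject_image, [m[0] for m in pop.members], regs)
pt   = af.floyd_warshall(g)
sel  = af.select_exemplars(af.cluster_atlases(pt, g), pt, g)
stack = af.propagate_labels(sel, {f"atlas{i:02d}": m[1] for i, m in enumerate(pop.members)}, regs)
fused = af.weighted_majority_vote(stack)
print(af.evaluate_all(fused, pop.subject_labels, [1, 2, 3, 4]))
```

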