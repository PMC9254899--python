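# serialmerge

Two-stage clustering and merging of serial-crystallography wedge datasets.

Serial crystallography assembles complete diffraction data from hundreds to
thousands of tiny crystals, each contributing only a still or a small
rotation wedge of a few percent completeness. When the crystals are not all
the same species — different ligand soaks, different near-isomorphous
forms — the wedges must first be sorted into homogeneous groups before
merging. Reflection-intensity correlations are the most discriminating
signal for this, but they are meaningless between two wedges that share
almost no reflections. `serialmerge` implements the staged strategy that
resolves this chicken-and-egg problem:

1. **Stage 1 — cluster on unit cells.** Each dataset's cell
   (a, b, c, α, β, γ) is embedded in the six-dimensional metric-tensor
   space G6 = [a², b², c², 2bc cos α, 2ac cos β, 2ab cos γ], Niggli-reduced
   to remove basis ambiguity, and compared with a Niggli-cone distance
   (NCDist) that heals the discontinuities of naive cell comparison (the
   original PCA/Euclidean cell distance is also available). Ward
   clustering of this distance matrix is cut as early as possible: the
   lowest non-overlapping dendrogram nodes whose pooled completeness
   reaches a cutover (default 10%) are selected and merged, each into one
   reflection set (inverse-variance weighting, optional linear scaling).
2. **Stage 2 — cluster on reflections.** Merged sets now share enough
   common hkl indices for a Pearson correlation CC, computed over
   symmetry-unique (Laue-group ASU) indices after mean-centring and
   norm-scaling — the cosine of the angle between the two intensity
   vectors, invariant to the unknown per-dataset scale. It is converted to
   the distance `SFDist = sqrt(2(1 − CC)) + w·f_unmatched`, where the
   penalty on the unmatched index fraction activates when the common
   fraction drops below 90%. Ward clustering of this matrix separates
   crystal forms whose cells are indistinguishable.

The package also ships a synthetic-experiment generator (`serialmerge
simulate`) that builds multi-form wedge experiments with known ground
truth — Wilson-distributed reference intensities, form-specific cell and
intensity perturbations, random low-completeness wedges, measurement
noise — so the whole pipeline is testable end to end without beamline data.

## Worked example

Generate a four-form experiment (200 wedges of 3–8% completeness; forms
N and B share a unit cell and differ only in intensities), run the
two-stage pipeline, and score it against the ground truth:

```sh
serialmerge simulate --preset paper-like --n-per-form 50 --out demo/data
printf 'stage2_cut_mode: count\nstage2_cut_value: 4\n' > demo/run.yaml
serialmerge run --config demo/run.yaml --cells demo/data/cells.csv \
    --truth demo/data/truth.csv --out demo/out
serialmerge report --assignment demo/out/assignment.tsv --truth demo/data/truth.csv
```

which prints

```
200 datasets -> 63 stage-1 clusters -> 4 stage-2 clusters; artifacts in demo/out
 cluster  size   purity majority_label  B  G  GB  N
       0    54 0.648148             GB  0 19  35  0
       1    16 1.000000              G  0 16   0  0
       2    52 0.615385              N 20  0   0 32
       3    20 0.950000              B 19  0   0  1
mean purity: 0.8034
```

Reading this: 200 wedges were clustered on cells into 63 small clusters
that reach the 10% completeness cutover (58 stragglers are dropped and
logged), each cluster was merged, and the 63 merged sets were re-clustered
on intensity correlations into 4 groups. Mean purity 0.80 — against 0.52
for a cell-only clustering cut to the same four groups, because the B/N
pair is invisible to cell parameters. On the full benchmark (1000 wedges,
250 per form) the two-stage pipeline produces 100%-pure clusters of 62–89
datasets for every form, while the cell-only four-way split produces none.

Outputs per run: Newick/JSON dendrograms for both stages, `selection.tsv`
(stage-1 clusters at the cutover), `assignment.tsv`
(dataset → stage-1 node → stage-2 cluster), `purity.tsv` (when truth is
given) and `run_log.txt` with the input/selected/merged bookkeeping.
All defaults: `serialmerge config --show`.

## Library layout

| module                    | contents                                                       |
| ------------------------- | -------------------------------------------------------------- |
| `serialmerge.lattice`     | `UnitCell`, G6 embedding, Niggli reduction, NCDist, PCA cell distance, LCV |
| `serialmerge.reflections` | SHELX HKL4 I/O, Laue groups, ASU mapping, completeness, merging, CC, SFDist |
| `serialmerge.clustering`  | Ward linkage, dendrogram annotation/selection/serialization    |
| `serialmerge.pipeline`    | `RunConfig`, two-stage orchestration, purity reports           |
| `serialmerge.synthetic`   | ground-truth experiment generator and the four-form preset     |

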