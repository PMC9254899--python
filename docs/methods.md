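# Methods

This note records the models, conventions and numerical choices behind
`serialmerge`, and what the synthetic benchmark does and does not show.

## Lattice comparison

**G6 embedding.** A cell is represented by its metric tensor with the
cross terms doubled, g = [a², b², c², 2bc cos α, 2ac cos β, 2ab cos γ]
(Å² throughout; angles are degrees in all I/O and radians internally).
The embedding is exactly invertible for positive-definite metrics;
`g6_to_cell` rejects singular or indefinite inputs (e.g. three 120°
angles with equal axes, which has zero volume).

**Niggli reduction** uses the classic Krivy–Gruber stepwise algorithm:
axis ordering (A ≤ B ≤ C with |ξ|/|η|/|ζ| tie-breaks), sign
normalization of the angle terms (all positive or all non-positive, with
a tracked zero component absorbing the parity of sign flips), the four
boundary steps (|ξ| ≤ B, |η| ≤ A, |ζ| ≤ A, body-diagonal condition), all
compared with a relative tolerance (default 1e-5 of the largest diagonal
element) so near-degenerate cells — type I/II boundaries, near-cubic
cells — are resolved consistently. The 3×3 integer basis transform is
accumulated and every iteration recomputes the G6 components from
M·G₀·Mᵀ, so the returned transform exactly reproduces the reduced
metric. A step budget (default 1000) guards termination; exceeding it
raises an error carrying the partial result. Verified properties:
idempotence, volume conservation, invariance under random unimodular
basis changes, and agreement with gemmi's independent Gruber reduction.

**NCDist.** The distance between two lattices is the minimum Euclidean
G6 distance between their reduced vectors over a configurable transform
set applied to either argument. The default set is the group of 24 axis
permutation/sign-flip operators that map reduced cells to equivalent
representations (improper operations coincide with proper ones in G6,
since −I fixes the metric). Because the set is an orthogonal group, the
one-sided minimum equals the full two-sided minimum, the distance is
symmetric, and — the identity being a member — it never exceeds the
plain Euclidean distance between the reduced vectors. This is an upper
bound on the exact Niggli-cone geodesic: the full boundary analysis of
the embedding space (and Delaunay/Selling S6 reductions) is out of
scope. Consequently cluster heights are comparable within a run but not
numerically to other NCDist implementations.

**Original PCA cell distance.** The six raw cell parameters are centred,
decomposed by SVD, components with ≥ 1% explained variance (configurable)
are retained, and Euclidean distances are computed in that subspace.
With zero total variance the distance matrix is zero.

**LCV / aLCV.** For each pair of cells in a cluster and each cell face
(b–c with α, a–c with β, a–b with γ) we compare the longer face diagonal
d = sqrt(x² + y² + 2xy|cos θ|); LCV is the maximum over faces of the
percentage spread 100·(dmax − dmin)/dmin and aLCV the corresponding
absolute spread in Å. The diagonal/denominator convention is one
consistent choice among several in circulation; LCV values are used as
isomorphism annotations, not as decision thresholds.

## Reflection handling

**Format.** Reflections are read and written as fixed-width SHELX HKL4
records (3I4, 2F8.2) with the 0 0 0 terminator. On writing, sigmas are
floored at 0.01 — the smallest positive value the F8.2 field represents —
and intensities are quantized to two decimals; this ~1% quantization is
far below the synthetic measurement noise and irrelevant to the
scale-invariant correlation comparison.

**Symmetry.** Built-in Laue groups: −1, 2/m, mmm, 4/m, 4/mmm (operator
matrices generated by closure, Friedel inversion always included);
arbitrary groups load from a text file of 3×3 integer matrices. The
canonical ASU representative of an index is its lexicographically
greatest image under the group — idempotent, and constant on orbits by
construction (verified exhaustively for |h|,|k|,|l| ≤ 4 for every
built-in group).

**Completeness** is the fraction of symmetry-unique indices with
d ≥ d_min present in a set, with the denominator enumerated from the
set's own cell (reciprocal-metric d-spacings, half-sphere Friedel
convention, (0,0,0) excluded). Dendrogram annotation computes each
node's completeness as the union of member ASU index sets over the
denominator of the members' mean cell; denominators are cached on a
0.1 Å / 0.1° rounded cell, which moves the sphere count by far less
than the cutover granularity and makes annotating a 999-leaf tree take
seconds rather than a minute.

**Merging** pools observations after ASU mapping with inverse-variance
weights (two observations 10±1 and 20±2 merge to 12.0±0.894). With
`scale_mode: linear`, each incoming set is first multiplied by a
least-squares scale fitted against the running reference on common
indices (falling back to unscaled when fewer than two indices overlap or
the fit degenerates); `none` pools as measured. The merged cell is the
unweighted mean of member cells, and members must agree within a
configurable LCV bound (default 2%). Full error-model refinement and
outlier rejection à la XSCALE/AIMLESS are out of scope.

**CC and SFDist.** The Pearson correlation is computed over common
unique indices (≥ 3 required; zero variance raises an error), optionally
on amplitudes sqrt(max(I, 0)) instead of intensities. The distance is the
chord between the two unit vectors whose angle-cosine is CC,
sqrt(2(1 − CC)) — zero at CC = 1, √2 at CC = 0, 2 at CC = −1 — with
sqrt(1 − CC²) available behind `sfdist_base: sine` since the literature
does not fix a single form. The unmatched-reflection penalty is
`penalty_weight · f_unmatched` with f_unmatched the fraction of the
index union not in common; using the fraction rather than the raw count
keeps the distance size-invariant. The penalty activates only when the
common fraction falls below `sfdist_activation` (default 0.90). Pairs
failing the CC preconditions receive a sentinel distance (default 10,
larger than any attainable SFDist) and are reported in the run log
rather than dropped.

## Clustering

**Ward linkage** is implemented directly as the Lance–Williams
recurrence on squared distances with heights being square roots, so two
singletons merge at exactly their input distance; ties break on the
lowest (row, column) pair, making runs deterministic. Heights agree with
the scipy reference implementation to < 1e-9 and are monotone
(no inversions) on metric inputs. The matrix update is vectorized; a
999-leaf linkage runs in about half a second.

**Selection at the cutover.** A node is selected iff its completeness
meets the threshold and no strict descendant's does — the minimal
qualifying antichain. Selected member sets are therefore pairwise
disjoint; leaves whose every qualifying ancestor was disqualified by a
deeper qualifying sibling subtree are reported unassigned and excluded
from stage 2 (with low-completeness wedges none of them can qualify on
its own). This is the "cluster only just far enough" reading of the
cutover: it favours the smallest mergeable groups, maximizing the chance
each is a pure species.

**Stage-2 flat cut.** Default `gap`: sort the merge heights and cut at
the largest gap, but only when that gap exceeds the smallest merge
height — otherwise the heights form one continuum with no convincing
separation and the tree is left as one cluster (this is what a
homogeneous single-form input produces). Ties take the lowest gap,
favouring more, smaller clusters. Fixed-count and fixed-height cuts are
available; for known K, `count` is the sharper choice, and the flat cut
is deliberately conservative because the hierarchical structure itself
(see purity reporting) carries more information than any single cut.

**Purity reporting** supports two views: flat-assignment purity
(per-cluster composition, max label fraction, mean purity) and the
largest 100%-pure cluster per form counted over all dendrogram nodes —
the latter matches how overlapping hierarchical clusters are inspected
in practice (one picks the best pure node, not a partition).

## Synthetic experiments

The generator emulates the statistical shape of a multi-form serial
experiment, not its physics. Reference intensities are exponential
(Wilson) with unit mean — the scale is irrelevant to CC — and σ = 5% of
I. A form perturbs a random fraction of unique indices by
I·(1 + scale·u), u ~ U[0.5, 1], and sets its own mean cell. A wedge is a
uniform random subset of the unique indices at a target completeness
with relative Gaussian measurement noise and a cell jittered per form
(σ defaults: 0.05 Å lengths, 0.02° angles). Random subsets rather than
geometric rotation slices: the clustering consumes only index sets and
intensities, and random subsets reproduce the completeness statistics
that drive the method. Not modelled: partiality, radiation damage,
geometric correlation of wedge coverage, indexing ambiguity, twinning,
anomalous signal. Passing tests therefore demonstrate the method's
statistical machinery, not robustness to those real-data effects.

**The four-form benchmark preset** (Laue 4/mmm, 79×79×38 Å tetragonal
cell, d_min 2.5 Å → 4507 unique reflections, wedges at 3–8%
completeness, 250 wedges per form, canonical seed): form N is the
native reference; G expands a and b by 0.3% and perturbs intensities; B
keeps the native cell (the cell-degenerate pair) and perturbs
intensities; GB does both. Every ligand-bearing form carries an
intensity perturbation — a bound ligand always changes structure
factors, and a cell-only form would make native/G stage-2 clusters
indistinguishable by construction. Effect sizes were chosen from the
analytic CC budget before running the pipeline: 30% of indices scaled by
1.5–3× gives cross-form CC ≈ 0.66–0.82 against within-form CC ≈ 0.99,
comfortably resolvable from the ~50 common reflections two 12%-complete
merged sets share; the 0.3% cell shift is ~5× the per-dataset cell noise
yet keeps LCV below the 1% isomorphism guideline. On this benchmark the
two-way (N vs GB) cell-only split is exact; the four-way cell-only cut
has ~0.51 mean purity with no 100%-pure cluster of ≥ 5 datasets for the
cell-degenerate form; the two-stage pipeline yields 100%-pure clusters
of ≥ 62 datasets for every form, and at a four-cluster cut its mean
purity is ≈ 0.81 vs ≈ 0.52 for cells alone. All numbers above are
recomputed by `scripts/acceptance.py` and the test suite.

## Problem sizes and determinism

Test-suite and acceptance problem sizes — 100-pair distance oracles,
200-cell invariance checks, 50 Ward reference instances, 1000-wedge
benchmarks — were chosen so the full suite runs in well under a minute
apiece while leaving each statistical margin wide. Every stochastic
component draws from an explicit seed through `numpy` SeedSequence
spawning; regenerating an experiment from its recorded spec and seed is
bit-identical, and a full pipeline run writes byte-identical artifacts
given identical inputs and configuration.

## Known limitations

- NCDist is an upper bound (24-operator set, single pass), not the exact
  Niggli-cone geodesic; absolute Ward heights are implementation-specific.
- No MTZ support; HKL4 fixed width limits |I|, σ < 10⁶ and quantizes to
  0.01.
- Laue groups beyond the five built-ins must be supplied as operator
  files; space-group (as opposed to Laue) logic, indexing-ambiguity
  resolution and image integration are out of scope.
- The merging model is deliberately simple (linear scale, no B-factor or
  resolution-dependent scaling, no outlier rejection).
- The largest-gap cut is a heuristic; for data with known K prefer a
  fixed-count cut, and inspect the dendrogram rather than trusting any
  flat partition.
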