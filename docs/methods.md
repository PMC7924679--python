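# Methods

## Distance-matrix images

A protein is represented by its α-carbon trace (atoms named `CA`, file
order preserved); a ligand by all of its atoms — ligands are typically too
small for a Cα-only view to carry information. The pairwise Euclidean
distance matrix is mapped to 8-bit grayscale by per-image min–max scaling,
`pixel = round(255·(d − d_min)/(d_max − d_min))`, with a constant matrix
mapping to zero. Min–max scaling is deterministic and parameter-free but
removes absolute scale: two structures differing only by a uniform dilation
produce identical images. A fixed-cap mode (`matrix_to_image(...,
mode="clamp", cap=...)`) is available when absolute distances should matter.
The full symmetric matrix is imaged, not a triangle.

Images are rescaled to a common 128×128 by bicubic interpolation
(`skimage.transform.resize`, `order=3`, edge-padded so constant images stay
constant, no anti-aliasing), values rounded and clipped back to [0, 255].
1×1 images — single-atom ligands — are rejected at this stage and the
structure is excluded; the exclusion propagates as a typed error
(`SingleAtomImageError`) rather than a silent drop.

## Texture descriptors

**LBP.** Each pixel's eight 3×3 neighbors are compared with the centre,
clockwise from the top-left, the first-visited neighbor being the most
significant bit; a bit is 1 when the neighbor is ≥ the centre (a tie counts
as 1, so a flat patch codes 255). Borders are zero-padded. The reading
direction is fixed by the construction; the MSB assignment and the tie rule
are our conventions, chosen once and frozen — every test oracle uses the
same convention independently re-implemented.

**Uniform patterns.** A code is uniform when its circular 8-bit pattern has
at most two 0↔1 transitions; exactly 58 of the 256 codes qualify (2
constant patterns + 8 rotations × 7 run lengths). The 59-bin histogram
gives each uniform code its own bin, ascending by numeric value, with one
catch-all bin (index 58) for the rest.

**Gabor.** The real Gabor kernel
`g(x, y) = exp(−(x′² + γ²y′²)/(2σ²))·cos(2πx′/λ + φ)`, with
`x′ = x cosθ + y sinθ`, `y′ = −x sinθ + y cosθ`, is evaluated on a 31×31
grid (≈ 6σ + 1) with λ = 10, θ = 0, φ = 0, γ = 0.02, σ = 5. With these
parameters the filter is a horizontal band-pass with a very elongated
envelope. The image is convolved (zero-padded) and the response min–max
rescaled to [0, 255] before the LBP stage, so LBP always sees valid
intensities; clipping instead of rescaling is config-exposed.

**SRM filter.** The image is tiled by non-overlapping 3×3 blocks B; each
block becomes `(B·B) // 100` clamped to 255 — row i of the result is row i
of B multiplied by B, each cell divided by 100 with integer floor (the
transform is defined on integer-valued images). Since 128 mod 3 = 2, the
last two rows and columns of a 128×128 image are not covered by a complete
block and pass through unchanged.

**NBS filter.** Two 3×3 blocks are neighbors when their centres are one
column apart, so neighboring blocks share two columns. Subtracting each
block from its right-hand neighbor, with all differences computed on the
original image and negatives replaced by 0, collapses to the per-pixel
closed form `out(x, y) = max(0, in(x, y) − in(x, y+1))`, with the last
column zero. Only the horizontal neighbor relation is implemented;
vertical/diagonal variants would be straightforward but are not part of the
descriptor as specified.

## Atom-bond features (group C)

Element composition is computed over a fixed vocabulary, default
[C, N, O, S] — the heavy atoms of a standard protein backbone and side
chains — so vector lengths are reproducible across datasets;
`derive_vocabulary` offers a dataset-scan alternative. Atoms outside the
vocabulary count toward the denominator only. The mass block takes the
standard atomic masses (IUPAC 2021 abridged values, shipped as
`data/atomic_masses.json`) of the first 100 atoms in file order,
zero-padded. The bond census declares a bond between two vocabulary atoms
at distance ≤ 2.0 Å — a cap covering heavy-atom covalent bonds (C–C 1.54 Å,
C–S 1.82 Å) while excluding 2.4 Å+ non-bonded contacts; the threshold is
config-exposed since reasonable chemistry arguments support values between
1.9 and 2.2 Å. A structure with no bonds yields the zero vector rather than
an error so that small ligands remain usable. With defaults the group is
4 + 100 + 10 = 114 long, making the hybrid vector 744; corpora with richer
element inventories will produce longer vectors through the dataset-scan
mode.

## SMOTE protocol

Minority classes are oversampled by `(x − y)/y · 100` percent, which lands
every class exactly at the majority count (up to rounding). Each synthetic
point is `s + u·(nn − s)`: base samples are cycled in order (even
coverage), the neighbor is drawn uniformly from the 5 nearest same-class
neighbors, and `u ~ U[0, 1]`. Balancing happens strictly inside each
cross-validation iteration on the training folds; the harness returns
per-fold synthetic counts and test indices so the absence of synthetic
instances in test folds is auditable, not just conventional.

## Negative-pair generation

The binding corpus provides positives only. Random undersampling draws
unseen (protein, ligand) pairs uniformly from the complement of the
positive set. Clustering-based undersampling k-means-clusters the positive
pair-feature vectors (k = 10 by default; the clustering algorithm is our
choice, as only the cluster count is prescribed) and accepts random unseen
pairs, assigned to their nearest centroid, until every cluster holds as
many negatives as positives; exhaustion of candidates raises an error
naming the unfilled clusters. No distance cap is applied when assigning
unseen pairs to centroids.

## Binding predictor

Related sets are built from the positive interaction list: the ligands
bound by the query protein's k nearest training proteins, and symmetrically.
k = 3 by default. Nearest-neighbor search uses the same metric as the
category being evaluated, with ties broken by stable id order. All eight
categories vote by default (`vote_scheme="categories"`); the coarser
two-vote reading — one internally aggregated vote per side — is available
as `vote_scheme="sides"`. Ties break positive: sensitivity is the primary
measure for this task because only the positive pairs are experimentally
grounded. A pair for which both sides lack related structures is surfaced
as an explicit undecidable outcome rather than silently labelled.

Threshold fitting is the least-specified part of the procedure and was a
genuine design decision. The default (`threshold_protocol="pooled"`)
computes, for every training pair, the same category distance prediction
would compute (related sets from the positive list) and sets each
category's threshold to the grand mean over positive and negative training
pairs together. Positive pairs contribute binding-scale distances,
negatives non-binding-scale ones, so the mean separates the two regimes —
on well-separated synthetic groups each threshold falls strictly between
the within-group and between-group mean distances (tested). The
alternative reading, where each training pair's related sets are derived
from the opposite-label pair list, is kept as
`threshold_protocol="opposite"`; it yields thresholds at the non-binding
scale and materially worse specificity, which is why it is not the default.

## Synthetic data

The generator emulates the statistical structure the methods assume, not
biophysics. Proteins are Cα chains with consecutive spacing 3.8 Å (the
canonical trans-peptide value): ideal helices (rise 1.5 Å/residue, turn
100°/residue, radius derived so the step is exact) give periodic
distance-matrix texture, random walks give irregular texture; each residue
also carries N/C/O decoy atoms at covalent offsets so the CA filter and the
bond census are both exercised. Ligands are compact clusters with ~1.5 Å
spacing. Isotropic coordinate noise (default σ = 0.05 Å) provides
within-class variation.

The planted binding dataset defaults to 5 groups with 20 proteins and 20
ligands each: group g's helices have turn angle 100° + 8°·separation·(g −
(G−1)/2) and its ligands morph between a shared template and a
group-specific one with weight min(separation, 1); positives are
within-group pairs only (40 training and 10 held-out per group, disjoint),
held-out negatives are cross-group pairs. At separation 1 the geometry
differences dominate the noise; at separation 0 all groups are generated
from identical parameters and no signal exists, so a correct predictor
must fall to chance. Because training negatives are sampled from *unseen*
pairs, a minority of them are within-group (ground-truth binders) — the
same contamination a real positives-only corpus suffers — and the
predictor must tolerate it.

What passing these tests does **not** show: real SCOPe domains differ from
ideal helices/walks in length distribution, multi-domain texture and
composition; real ligands have chemistry, not just geometry; and real
binding is not transitive within similarity clusters. Results on the
synthetic conditions validate the machinery and its contracts, not
benchmark-level accuracy.

## Numerical and protocol choices

* Classifier registry (structural-class harness): polynomial-kernel SVM
  with C = 1 and degree 1, AdaBoost over unpruned decision trees (50
  rounds), 100-tree random forest, brute-force 5-NN with uniform weights,
  Gaussian naive Bayes; features min–max normalised on the training folds
  inside each pipeline. Multi-class sensitivity/specificity/F1 are
  support-weighted one-vs-rest averages; binary matrices use the plain
  positive-class convention.
* Problem sizes in tests and the acceptance script (5×(20+20) binding
  structures of 48 residues, 80 proteins of 40–80 residues for
  classification) were chosen as the smallest sizes at which the planted
  effects are comfortably estimable from held-out counts of ~50–100.
* PDB coordinates are rounded to 3 decimals on parsing — the column format
  carries exactly 3 — so generator logs round-trip bit-exactly.
* All randomness flows through explicit integer seeds; fixtures and
  datasets are bit-reproducible.

## Known limitations

* Only the horizontal NBS neighbor relation is implemented (see above).
* Group C's length is vocabulary-dependent; published corpus-derived
  vectors of other lengths cannot be reproduced without the corpus.
* The binding predictor stores its feature dictionaries in memory; corpora
  of ~10⁴ structures fit easily, but no out-of-core path exists.
* `rescale_image` uses scikit-image's bicubic spline, which can overshoot
  by one quantum on steep ramps; tests allow that single-level wobble.
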