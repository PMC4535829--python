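# Methods

## The score

A fragment is the ordered trace of its Cα coordinates (Å), N ≥ 2. Its
internal distance matrix D is symmetric, nonnegative, zero-diagonal, and
invariant under every isometry of the trace, mirroring included. The
amplitude spectrum |ℱD| applies the unitary 2D DFT and keeps entry-wise
moduli; the amplitude spectrum distance is the Frobenius distance between
two such spectra.

Choices that everything else depends on:

- **Normalization.** The DFT carries the 1/N prefactor (numpy's
  `norm="ortho"` for a square matrix), so ‖ℱM‖₂ = ‖M‖₂ exactly. All
  constants below (2Nε, √(N(N−1))) assume this convention; an unnormalized
  FFT would scale every score by N.
- **Padding.** The default `asd` zero-pads both matrices to dimension
  N_P + N_Q (original block top-left; placement is immaterial because
  amplitude spectra are invariant to circular shifts of the padded matrix,
  and a test checks this). Equal-length inputs are padded too (to 2N), so
  one convention covers every pair; `pad=False` gives the raw form.
  `asd_unpadded` exists separately because the circular-permutation
  identity ASD(P, P≫s) = 0 and the RMSD_d bound are statements about raw
  matrices.
- **Truncation.** `asd_truncated(p, q, k)` keeps the top-left k×k block of
  the padded spectra — frequency indices 0…k−1 in both dimensions,
  including the DC term, which dominates and carries the gross distance
  scale. Conjugate-symmetric partner frequencies are *not* added, so the
  truncated value is nondecreasing in k and reaches `asd` exactly at full
  k. Default k = 5 in the CLI.

Exact invariances (all tested to 1e-6/1e-8 absolute on double precision):
isometry and mirror (properties of D); sequential reversal (reversing the
trace reverses both matrix axes, a permutation with unchanged amplitude
spectrum); circular index shift for the unpadded form. Pseudometric axioms
follow from the reverse triangle inequality on spectra; zero distance does
not imply identity (mirrors, reversals), so this is not a metric.

Quantitative guarantees asserted by the suite:

- Deforming one fragment by at most ε per point changes any variant by at
  most 2Nε, with N the padded dimension (the conservative reading when the
  transform size is ambiguous between fragment length and padded size).
- For same-length fragments, ASD ≤ ‖D_P − D_Q‖₂ = √(N(N−1))·RMSD_d. The
  √(N(N−1)) constant is the provable one: the symmetric matrix counts each
  residue pair twice, and a tighter constant without that factor √2 is
  already violated at N = 2 (ASD = √2·|d_P − d_Q|, RMSD_d = |d_P − d_Q|).
- For two overlapping windows of one structure, the padded score is at most
  the Frobenius mismatch of the padded matrices in their best circular
  alignment.

`nasd` divides each spectrum by ‖D‖₂ before differencing. Normalized
spectra are unit vectors with nonnegative entries, hence values in
[0, √2]; uniform coordinate scaling cancels. The price is a mild
information loss; ranking experiments here use the unnormalized form.

## Reference scores

`rmsd` is the closed-form Kabsch/SVD solution restricted to proper
rotations (det = +1). Mirror improvement is never absorbed into the fit;
it is reported separately as `chirality_sign`, the sign of det(PᵀQ) on
**centered** coordinate matrices — uncentered products are
translation-dependent and would make the test meaningless. Centering makes
it the sign of the Kabsch covariance determinant; rotation of either
fragment cannot change it. Near-degenerate geometry (third singular value
below 1e-9 of the first, e.g. coplanar traces) yields an explicit 0
("indeterminate"), never a silent ±1. Collinear inputs leave the optimal
rotation non-unique; `rmsd` still returns the (well-defined) minimum and
sets a `degenerate` flag. `rmsd_d` is the root-mean-square internal
distance difference over the C(N,2) residue pairs.

## Retrieval

Rankings sort ascending with ties broken by fragment id, for bit-stable
reruns. Precision-recall curves carry one point per rank position; the area
is average precision (sum of precision at each relevant hit over the number
of relevant items), which avoids the linear-interpolation bias of
trapezoidal integration in PR space. The jack-knife driver uses every
positive as the seed; the seed stays in its own bank by default (its score
0 makes it a trivial first hit) and `include_seed=False` gives the
leave-one-out variant. `rank_asdasym` sorts positive-chirality hits first,
mirror hits second, each block by `asd`; indeterminate chirality lands in
the first block, flagged through the hit record.

Because the padded score obeys the triangle inequality,
|d(q, pivot) − d(pivot, x)| lower-bounds d(q, x); `nn_search_ti` skips
candidates whose bound exceeds the current best and is exact for any pivot
choice (identical pivots merely prune nothing).

## Clustering

`complete_linkage` delegates the standard agglomeration to scipy
(max-pairwise inter-cluster distance, monotone heights); a naive O(n³)
oracle in the tests confirms the merge heights. The Davies-Bouldin index
needs cluster centers, which a pseudometric does not provide, so clusters
are represented by **medoids** (member minimizing the summed in-cluster
score): scatter = mean score to the medoid, separation = medoid-to-medoid
score, DB = mean over clusters of the worst (Sᵢ + Sⱼ)/Mᵢⱼ ratio. The
dendrogram is cut at the first local minimum of the DB-vs-k profile;
profile endpoints count as local minima when the profile rises away from
them (two clean families otherwise could never select k = 2), and a flat
profile falls back, flagged, to the global minimum. Agreement with a
reference labeling is the matched fraction under the optimal one-to-one
cluster correspondence (Hungarian assignment; brute-force permutation
search cross-checks it in the tests). `classical_mds` is the Torgerson
double-centering embedding, for plots only; eigenvalues below 1e-12 of the
leading one are treated as zero, and a warning fires when more than half
the eigenvalue mass is negative.

## Synthetic data

Generators produce traces with known ground truth, seeded through
numpy's PCG64 (`default_rng`), so every property test is reproducible
bit-for-bit:

- `make_random_walk`: 3.8 Å fixed steps (the trans Cα–Cα spacing), uniform
  directions, 1.0 Å clash floor between non-consecutive points enforced by
  resampling. Compact, irregular traces.
- `make_helix`: ideal helical trace — radius 2.3 Å, rise 1.5 Å/residue,
  twist 100°/residue — optionally in a seeded random pose.
- `make_stiff_walk`: directionally persistent walk (stiffness 3), an
  extended strand-like trace.
- Exact transforms (rotation, translation, mirror, reversal, circular
  shift), ε-ball perturbations (uniform by radius-cubed inversion, so the
  displacement bound ‖x − f(x)‖ ≤ ε holds by construction), and single
  indels (an inserted point sits 3.8 Å from both flanking residues).

`make_family` builds the desk-scale retrieval benchmark: a base walk, six
ε = 0.5 Å perturbed copies (thermal-scale deformation), three single-indel
variants, and forty decoys cycling through the three structural classes —
the class diversity mirrors how a representative background fragment set
is sampled. The suite asserts a *mean* PR AUC above 0.9 over 20 seeded
banks: single-indel variants score between the perturbed copies and the
nearest compact-walk decoys (indel tolerance of the spectral score is
gradual, not absolute), so per-seed AUC fluctuates while the mean is
stable.

What the generators do **not** emulate: dihedral statistics, secondary
structure mixtures within one fragment, packing constraints beyond the
clash floor, or the distance-scale diversity of real folds. Real fragment
banks spread further apart in spectrum space than clash-only walks do, so
passing retrieval/clustering tests here demonstrate correctness of the
machinery and the qualitative behavior of the score, not the
discrimination levels reachable on curated structure sets.

## Structure input

PDB reading goes through gemmi: first model only, author-numbered
inclusive ranges (`file.pdb:A:95-117` is 23 residues — off-by-one here
would silently corrupt every comparison), insertion-coded residues kept in
file order, HETATM Cα (MSE) accepted, calcium ions named CA excluded by
element. Residues with alternative Cα locations abort under the default
strict policy or resolve to the highest-occupancy location under
`altloc="occupancy"`. A missing Cα in the range raises a gap error listing
the culprits. The bundled writer emits minimal CA-only records (fixed
3-decimal precision, hence the 1e-3 Å round-trip tolerance).

## Problem sizes

The test and acceptance runs use fragments of 8–40 residues, banks of up to
~60 fragments, 500 pseudometric triples, 100–1000 sampled pairs per bound,
and 20-seed benchmark repetitions — sizes at which every check is exact or
tightly tolerated while the whole suite stays interactive on one core.

## Known limitations

- Zero distance between mirror images or reversed chains is a feature for
  retrieval but means the score alone cannot certify topological identity;
  combine with `chirality_sign` (as `rank_asdasym` does) when handedness
  matters.
- Padded scores of fragments with very different lengths are dominated by
  the spectral mass difference; `nasd` mitigates but does not remove this.
- An interior indel misaligns the trailing sub-block of the distance
  matrix in index space; the score degrades gradually rather than
  re-aligning, which is exactly the traded-off flexibility (no alignment
  search, no parameters, triangle inequality preserved).
- The Davies-Bouldin adaptation (medoids) and the agreement matching
  (Hungarian) are standard dissimilarity-only surrogates, but other
  adaptations exist; absolute index values are not comparable across
  conventions.
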