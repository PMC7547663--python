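# Methods

## Problem and sample formulation

γ-carboxylation converts specific glutamate (E) residues into
4-carboxyglutamate (Gla). The predictor treats every E in a protein as a
candidate and represents it by a fixed-length peptide window: 20 residues
upstream, the candidate at 1-based position 21, 20 residues downstream
(41 residues in total). Windows that would cross a terminus are padded with
`X` so the fixed-length contract always holds; `X` maps to code 0 in every
downstream encoding and is excluded from frequency denominators and PRIM
accumulation. Every unannotated E is treated as a negative candidate —
an assumption inherited from how such benchmark sets are built, and a known
source of label noise in real data (unobserved sites are not guaranteed
unmodified).

Coordinates in annotation files are 1-based. The canonical residue order is
alphabetical by one-letter code (A, C, D, …, Y), used consistently for
integer codes (A=1 … Y=20), PRIM axes and frequency-matrix rows.

## Feature extraction

Three matrices are built per window:

**Window matrix.** The 41 integer codes are written row-major into a 7×7
grid (49 cells; the trailing 8 are zero). Seven is the smallest side length
whose square holds 41 cells. The mapping from residues to codes is ordinal,
not metric: the moments below therefore measure the *arrangement* of codes,
and two chemically similar residues are not numerically close by design.
This is a deliberate property of the encoding family, not an oversight.

**PRIM.** The 20×20 position relative incidence matrix. Entry (i→j) sums,
over every occurrence of residue j strictly after the *first* occurrence of
residue i in the window, the offset (position of j − position of first i).
Rows for residues absent from the window are zero. This semantics — offsets
relative to first occurrences — is one of several consistent readings of
"relative position of each amino acid residue" and is flagged here as an
interpretation; it is deterministic, O(41²), and sensitive to both
composition and ordering.

**RPRIM.** The PRIM of the reversed window; captures arrangement features
that are asymmetric around the centre (identity: RPRIM(w) = PRIM(reverse(w)),
property-tested).

### Moment reduction

Each matrix is reduced to 24 numbers: raw, central and Hahn moments, 8 each,
over the fixed order set {(0,0),(0,1),(1,0),(1,1),(1,2),(2,1),(3,0),(0,3)} —
the seven orders with total order ≤ 3 plus (0,0) (total mass), which brings
each family to 8 and the per-matrix total to the stated 24. Orders beyond
total order three are rejected. Raw and central moments index cells from 1;
the Hahn transform indexes from 0 — each follows its defining sum.

Central moments are taken about the intensity centroid (x̄ = M10/M00,
ȳ = M01/M00), which makes n10 = n01 = 0 identically and orders ≥ 2
translation-invariant; for an all-zero matrix the centroid falls back to the
matrix centre ((n+1)/2, (n+1)/2), logged.

### Hahn basis: normalization choice

`hahn_polynomial` evaluates the three-Pochhammer series

    h_n^{u,v}(r,N) = (N+v−1)_n (N−1)_n ·
        Σ_k (−1)^k (−n)_k (−r)_k (2N+u+v−n−1)_k / [(N+v−1)_k (N−1)_k k!]

term by term, with each term derived from the previous one by a ratio of
small factors (sign-exact, no overflow at any N used; N=20 is needed for the
PRIM reduction). As printed in the sources this package follows, that series
is *not* numerically orthogonal under the classical Hahn weight in any
rising/falling-factorial reading we tested; it is, however, degree-graded
(h_n is a polynomial of degree n in r). `HahnBasis` therefore scales the raw
rows by the square root of the Hahn weight
ρ(r) ∝ C(u+r, r)·C(v+N−1−r, N−1−r) and orthonormalizes them by QR in degree
order. Orthonormalization of a degree-graded polynomial family under a fixed
inner product determines the orthonormal family uniquely up to sign (signs
fixed so each diagonal of R is positive), so the resulting basis is the
normalized discrete Hahn family regardless of constant factors in the
series. For the default u = v = 0 the weight is uniform and the basis
coincides with the orthonormal discrete Chebyshev polynomials. Verified
properties: rows orthonormal to machine precision at N ∈ {3, 7, 20}; the
full-order transform reconstructs random matrices to < 1e−6.

Hahn parameters u, v default to 0 and are configurable; they shift the
weight toward one end of the support and were not needed for any result
here.

### Feature vector and scaling

Concatenation order is fixed: window-matrix moments, PRIM moments, RPRIM
moments → 72 features, with named columns (`win_raw_00` … `rprim_hahn_03`)
and recorded segment boundaries. The order set is configurable, giving an
extensibility hook for richer compositions.

Two scaling modes: standard (mean 0, variance 1 per feature) — the default —
and min–max (training range → [0, 1]). Statistics are always fitted on
training data only, inside each validation protocol. Constant features scale
to 0 in both modes (no division by zero). Scaling is exactly invertible for
non-constant features; parameters serialize to JSON.

## Classifiers

The primary model is a feed-forward MLP: one hidden layer of 100 units,
logistic sigmoid activations, adam, up to 800 iterations, fixed seed
(scikit-learn `MLPClassifier`). The hidden width and activation are design
choices — the architecture family is specified but not its size — and are
configurable. Baselines: L2-regularized logistic regression (C = 1) and a
100-tree random forest, both seeded. Scores are positive-class
probabilities; the decision threshold is 0.5 with ties predicted positive.
Training validates that both classes are present and features are finite;
prediction validates the feature count against the fit.

## Validation protocols

* **Independent set test** — one stratified shuffled 80/20 split
  (1160 → 232 test samples at the default benchmark size).
* **Self-consistency** — fit and evaluate on the identical full dataset;
  optimistically biased by construction and reported for comparability.
* **k-fold** (default k = 10) — stratified folds (560/600 split 10-fold gives
  116 per fold); headline Sn/Sp/Acc/MCC are *unweighted fold means* (the
  prose convention followed here; pooling is the other defensible choice),
  while the confusion matrix and AUC are pooled over all held-out
  predictions. With k = n the partition degrades to leave-one-out, making
  the pooled result identical to the jackknife for a deterministic model.
* **Jackknife** — leave-one-out: n fits, each scoring its held-out sample;
  one pooled confusion matrix (consistent with single reported values).

MCC is defined as 0 when any denominator factor vanishes (the limit
convention, logged); sensitivity or specificity is reported as missing when
its class is absent. AUC is the rank statistic over all thresholds; F1 is
2TP/(2TP+FP+FN).

## Synthetic benchmark

The generator emulates the statistical shape of the curated benchmark —
560 positive and 600 negative glutamate-centred windows — without
reproducing real sequences. Each sample is emitted as its own protein:
25 residues of background padding, the 41-mer window, 25 more padding
residues, so no window needs terminal padding and the planted site sits at
position 46. Positive windows carry a positional motif: at each designated
flank position the motif residue appears with probability `motif_strength`
(0 = null, classes identically distributed; 1 = deterministic motif).

Two coupled design choices keep the window-count contract exact. The
background distribution is uniform over the 19 non-E residues, and the motif
contains no E, so every glutamate in the output is a planted centre and
extraction yields exactly the configured class counts. The default motif is
tandem rare aromatics — W at window positions 17, 18, 24, 25 and Y at 19
and 23 — chosen because the benchmark's purpose is to exercise the moment
pipeline: repeated rare, high-code residues produce a signature visible in
both the window-matrix moments and the PRIM offsets, loosely echoing the
conserved aromatic/hydrophobic positions of real Gla domains. At full
strength the pipeline recovers the motif at ≈95% held-out accuracy /
AUC ≈ 0.99; at strength 0 AUC sits at chance; seed-averaged AUC is monotone
in strength.

What the generator does *not* emulate: homology structure between proteins
(every sample is independent, whereas real benchmarks contain residual
relatedness even after 90% identity filtering), realistic amino-acid
background frequencies, multiple Gla sites per protein (real Gla domains
cluster up to a dozen modified glutamates), and label noise from
under-annotation. Passing tests on this benchmark therefore demonstrate that
the pipeline's machinery is correct and that it can recover a planted
positional signal — not that the same accuracy would be obtained on curated
UniProt data.

## Problem sizes and numerical notes

The shipped validation runs use the full benchmark size (1160 windows) for
the independent, self-consistency and ten-fold protocols, and a stratified
subsample of 120 windows for the jackknife, whose cost is one model fit per
sample; the subsample size is reported alongside the result. The
motif-strength sweep averages over three seeds. Moment agreement with
brute-force double summation is tested to 1e−9 on integer-valued matrices;
Hahn orthonormality to 1e−8 and reconstruction to 1e−6; scaling round-trips
to 1e−12.

## Known limitations

* The PRIM entry semantics is an interpretation (see above); alternative
  readings (all-pairs offsets, per-occurrence rows) would give different —
  also 400-coefficient — encodings.
* The feature composition is the derivable 72 = 3 × 24 layout; published
  totals for related encodings are larger and not reconstructible from their
  described components, so the layout here is kept explicit and extensible
  rather than padded to an undocumented width.
* Moment features compress 41 positions into 72 aggregate descriptors;
  weak single-position motifs can be information-theoretically invisible to
  them even when sequence-level classifiers would separate the classes.
* No real carboxylation benchmark is bundled; conclusions about real-data
  accuracy require the user's own annotated sequences.
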