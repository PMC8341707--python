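# Methods

## Problem and approach

T-cell receptor (TCR) repertoires are usually summarized through three
loosely coupled descriptors: the CDR3 amino-acid sequence of each clone, its
V-gene usage, and its clone size. `elate` unifies them in a single
real-valued representation: each clone is one-hot encoded (CDR3 positions as
21-blocks — 20 amino acids plus a stop symbol — right zero-padded to the
corpus maximum length, optionally concatenated with a V-gene one-hot block)
and projected by an autoencoder into a 30-dimensional space. On that
projection, local repertoire density is defined by Gaussian kernel density
estimation (KDE): the density of one sample's clones with respect to
another's (cross-density), or a sample against itself with each point's own
kernel term removed (self-density). Cross-densities give a sample-by-sample
similarity matrix for hierarchical clustering; the frozen encoder plus a
small classification head gives one-vs-all clone classification.

## Encoding

The stop symbol occupies index 20 of every 21-block; the encoded layout is
`AA_1 … AA_l, stop, zero-padding, [V]`, with `n = 21·(m+1) + n_V` total
dimensions for maximum CDR3 length `m`. Decoding takes the per-block argmax
(ties broken toward the lowest index) and cuts at the leftmost stop block;
everything right of it is ignored. Two useful consequences that the tests
assert: decode∘encode is the identity on valid clones, and the squared
Euclidean distance between encodings of equal-length CDR3s is exactly twice
their Hamming distance. `m` is fixed by the training corpus; a longer CDR3
at inference raises an error rather than being truncated, since silent
truncation would corrupt every distance built on the encoding. Rows whose
CDR3 contains any character outside the 20 standard amino acids (X, \*, _,
# and the like) are dropped at load time, after uppercasing.

## Autoencoder family

Encoder: fully connected layers of 300, 100 and 30 nodes, Elu activations,
dropout 0.1 between the hidden layers. The 30-dimensional code itself is
kept intact by default (`bottleneck_dropout=False`): noising the exact
representation that every downstream analysis consumes measurably slows
reconstruction learning; the switch restores the literal
dropout-after-every-layer variant. Decoder mirrors the encoder
(30→100→300→n) and ends with a softmax applied separately to each 21-block
and to the V block, so every block is a probability vector over symbols.

Training minimizes the reconstruction MSE (mean over batch *and* vector
components — the convention only rescales the learning rate) with Adam at
learning rate 1e-4, batch size 50. The distance-maintaining flavors (EM,
VEM) add a loss over all pairs in a batch,

    loss_dis = Σ_{i<j} ( ||z_i − z_j|| − D_ij )²,

where `D_ij` is the Euclidean distance between the one-hot inputs, computed
per batch on the fly (entry-wise identical to slicing a precomputed
full-corpus distance matrix, without the O(N²) memory). As printed, the
loss mixes a squared embedded distance with an unsquared input distance; the
default compares unsquared Euclidean distances on both sides — distance
conservation is the stated goal — and `dis_squared=True` gives the literal
mixed form. The total objective is `mse + λ·loss_dis/n_pairs` with λ
(`dis_weight`) defaulting to 1 after per-pair normalization, which makes the
two terms scale-comparable across batch sizes.

The four flavors are E (reconstruction only), VE (+V gene), EM (+distance
loss), VEM (+both). When V is encoded it participates in both the
reconstruction loss and `D_ij`. Dropout is disabled at inference, so
embeddings and reconstructions are deterministic; the whole training loop
draws from one seeded generator and reproduces bit-for-bit.

Reconstruction accuracy at mismatch tolerance k is the fraction of clones
whose decoded reconstruction has the correct length and at most k differing
positions; a length mismatch counts as an error at every k. Distance
preservation is quantified by the Spearman correlation between one-hot and
embedding pairwise distances over all unordered pairs of a held-out set.

The neural-network machinery itself (dense layers, Elu/Tanh/sigmoid,
inverted dropout, per-block softmax, Adam) is a small seeded numpy core with
manual backpropagation (`elate._nn`) — deliberately minimal, float32, and
fully deterministic given a seed.

## Density estimation

For query x and reference set {y_1…y_R},

    f_h(x) = 1/(R·h) · Σ_i w_i · K((x − y_i)/h),    K(u) = (2π)^{−Z/2} e^{−||u||²/2}

with Z = 30, w_i = 1 or w_i = freq_i when clone sizes weight the reference,
and bandwidth h = 1.06·STD(S)·|S|^{−1/5}, where STD(S) is the mean of the
per-dimension standard deviations of the reference (switchable to the
global flattened std). The 1/(R·h) prefactor reproduces the published
formula; `fully_normalized=True` substitutes 1/(R·h^Z), the constant that
makes f_h integrate to one in Z dimensions. All comparative quantities
(orderings, correlations, cluster structure) are invariant to this choice.
Densities are computed and stored in log space; with the radial Gaussian
kernel they are strictly positive. Self-density excludes the i=j term, so
it is bounded above by the self-inclusive density pointwise.

Sample-level KDE similarity subsamples a constant number of clones per
sample (default R = 100, seeded, without replacement — a constant size
avoids sample-size bias), embeds both sides, takes the bandwidth from the
reference sample, and averages the query densities. It is directional;
for linkage the matrix is converted to a distance by −log (floored at the
smallest positive float, shifted to be nonnegative) and symmetrized by
averaging the two directions.

## Alternative similarities, clustering, entropy

KL similarity compares V-usage distributions of two seeded subsamples with
D(p‖q) = Σ p(v)·log(p(v)/q(v)) (natural log) after an additive pseudocount
of 1 on the V counts over the union support, so q(v)=0 never occurs. Edit
distance similarity builds the R×R Levenshtein matrix (via `edlib`; a
textbook dynamic-programming implementation serves as the oracle in tests)
and averages row minima, excluding the diagonal for self-comparison.
Clustering is average-linkage agglomeration (scipy) on the distance form of
the chosen matrix, cut into k = number of distinct category labels when
entropies are computed. Cluster entropy is the Shannon entropy (base 2) of
each label's distribution across clusters, reported per label plus an
unweighted mean.

## Classification

The head is four fully connected layers of 30, 15, 10 and 1 nodes, Tanh
activations except a final sigmoid, dropout 0.1 after the second and third
layers. (The source description of the head is internally inconsistent —
"three layers" in one place, four layer sizes in the methods — this package
implements the explicit four-size specification.) It trains on frozen
embeddings with weighted binary cross-entropy (inverse class frequency, the
one-vs-all negative pool being much larger than the positive class), Adam
at 1e-4, default 100 epochs with early stopping on a 10% validation split
(patience 20). The frozen-encoder contract — encoder parameters bitwise
identical before and after head training — is asserted in tests. The
standard split takes 500 clones per sample into training and leaves the
rest (the vast majority) as test; AUC is computed on the test fraction.

## Synthetic data

The generator emulates the structure of real beta-chain repertoires rather
than drawing letters independently: each CDR3 is a mosaic

    CAS + V-extension + N1 + D-fragment + N2 + J-suffix

with the V extension from a small catalogue (0–2 residues), N1/N2
junctional insertions of 0–4 residues from a glycine/serine-biased usage,
the D fragment from a catalogue of short germline-like glycine-rich
fragments with truncations, and the suffix one of the 13 amino-acid endings
of the human TRBJ segments (left-truncated by up to 2, all ending in the
conserved F). Total lengths are rejection-sampled into the configured range
(default 8–18), yielding a unimodal length distribution peaking near 14–15.
This mosaic structure is what makes the generated data behave like real
repertoires for the analyses here: pairwise edit distances between
unrelated clones concentrate well above 2 (<1% of mass at ≤2), while
held-out generalization of the autoencoder is possible because clones share
templated segments — a property i.i.d. random cores lack.

Clone sizes follow a discrete Pareto law P(size ≥ s) = s^−(α−1) with tail
exponent α = 2.5 by default; V genes are drawn from a rank-biased (1/rank)
catalogue of 30 names. Host structure: samples are split evenly over hosts,
each host owns a disjoint public pool (default 100 clones) and every sample
of that host carries each pool clone independently with the sharing
probability (default 0.5). Specificity classes for classification copy a
consensus core with a per-position mutation rate: rate 0 gives identical
cores, rate 1 redraws every position from the background usage, making
classes statistically indistinguishable.

What the generator does not emulate: nucleotide-level V(D)J recombination
(insertion/deletion profiles, convergent recombination), allele-level V
calling, sequencing error, and the cross-dataset heterogeneity of real
cohorts. Passing tests on this data therefore demonstrate the mechanics and
the relative orderings of the methods (E vs EM accuracy, within- vs
between-host similarity, motif-class separability), not clinical-grade
performance on any particular cohort.

## Problem sizes and numerical choices

The performance checks train on 5,000 deduplicated clones and evaluate on
1,000 held-out clones — the package's standard desk-scale benchmark — with
500 epochs for EM (its distance correlation plateaus early) and 900 for E
(safely past the onset of its accuracy plateau; a decayed learning-rate
phase was evaluated and does not move the plateau).
Ordering properties are asserted as means over ≥5 seeds at smaller scale
(hundreds of clones, tens of epochs), where the orderings are already
stable. Other conventions: argmax ties in decoding break toward the lowest
block index; a zero embedded pairwise distance contributes zero gradient to
the distance loss; KDE with a degenerate (zero-spread) reference raises
rather than returning an infinite bandwidth; subsampling is always seeded
and without replacement; t-SNE is scikit-learn's, seeded, with PCA
initialization.

## Known limitations

* The distance-maintaining flavors trade reconstruction for geometry by
  design; at equal budget E reconstructs better and EM preserves distances
  better, and no single flavor wins both.
* The KDE prefactor follows the published 1/(R·h) form by default, so
  absolute density values are not normalized probability densities in 30
  dimensions (use `fully_normalized` for that); only comparisons are
  meaningful.
* Levenshtein-based sample distances scale as R² string alignments per pair
  of samples; R = 100 keeps this trivial, but the method is not meant for
  full-repertoire all-vs-all use.
* The numpy training loop is single-threaded and CPU-bound; it is sized for
  10³–10⁴-clone corpora, not the 10⁶-clone regime.
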