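# Methods

This note documents the models, numerical conventions and design choices
behind `thermoseq`, and what the synthetic benchmarks do and do not show.

## Problem setting

Binary classification of protein sequences into thermophilic (positive,
source organism OGT ≥ 60 °C) and mesophilic (negative, OGT ≤ 37 °C)
classes. Sequences in the 37–60 °C band are excluded from dataset
construction: the positive class is deliberately restricted to
hyperthermophile-grade proteins, which sharpens the class contrast.
Only the 20 standard residues are handled; records containing B, J, O, U,
X or Z are rejected rather than imputed, because every descriptor family
assumes the 20-letter alphabet and silent substitution would corrupt
compositions. The practical sequence-length window is 31–1500 residues:
the lower bound comes from the lag-30 descriptor preconditions, the upper
bound from the dataset length filter.

## Descriptor panel (797 features)

Families are concatenated in fixed order AAC(20), DPC(400), CTD(147),
QSO(100), PAAC(50), APAAC(80) with family-prefixed, globally unique names.

* **AAC/DPC** — residue and overlapping-dipeptide frequencies; each block
  sums to 1.
* **CTD** — seven attribute partitions (hydrophobicity, normalized
  van-der-Waals volume, polarity, polarizability, charge, secondary
  structure, solvent accessibility), three groups each, the standard
  Dubchak-style tables. Composition: 3 group fractions per attribute.
  Transition: adjacent-pair group-change frequencies over the L−1 windows,
  counted irrespective of direction. Distribution: chain positions
  (percent of L) of the first, ⌈25%⌉-th, ⌈50%⌉-th, ⌈75%⌉-th and last
  occurrence of each group; a group absent from the sequence contributes
  five zeros, keeping all values bounded in [0, 100].
* **QSO** — coupling numbers τ_d = Σ_i d(r_i, r_{i+d})² for d = 1..30
  under two 20×20 distance matrices, combined with residue frequencies as
  X_r = f_r/(Σf + wΣτ) and X_{20+d} = wτ_d/(Σf + wΣτ), w = 0.1. The first
  matrix is a physicochemical distance built in-package: Euclidean
  distance between residues in the z-scored (hydrophobicity,
  hydrophilicity, side-chain-mass) property space, rescaled to [0, 1].
  The second is the Grantham (1974) amino-acid difference matrix, also
  rescaled to [0, 1] so both halves of the descriptor live on one scale.
* **PAAC** — λ = 30, w = 0.05; property scales (hydrophobicity,
  hydrophilicity, side-chain mass) are z-scored over the 20 residues with
  the population SD; θ_j is the mean over positions of the mean squared
  scale difference at lag j. All 50 entries sum to 1 by construction.
* **APAAC** — the amphiphilic variant keeps hydrophobicity and
  hydrophilicity correlations separate and uses the product form
  h(r_i)·h(r_{i+j}), two pseudo components per lag (2λ = 60). Individual
  pseudo components can be negative; the 80 entries still sum to 1
  because the numerators sum to the common denominator. Note this means a
  homopolymer does *not* have vanishing pseudo components (its lag
  correlation is h(r)² ≥ 0) — unlike PAAC, whose squared-difference form
  vanishes on homopolymers.

The lag lengths and weights (nlag = λ = 30, w = 0.1/0.05) are the standard
parameterizations and the unique ones reproducing the 100/50/80 block
dimensions.

## Sequence encodings

Two integer token streams per sequence, padded with 0 on the right:
alphabetical residue ranks (A=1 … Y=20) and six physicochemical groups in
listing order hydrophobic(V,I,L,F,M,W,Y,C)=1, negatively charged(D,E)=2,
positively charged(R,K,H)=3, conformational(G,P)=4, polar(N,Q,S)=5,
other(A,T)=6. Integer tokens feeding an embedding layer are the standard
reading of "each residue maps to a specific number"; token 0 is reserved
for padding in both channels and its embedding contribution is masked to
zero. With the default Lmax = 1500 (the dataset length cap) no accepted
sequence is ever truncated.

## Network

Per channel: embedding (dim 128) → dropout → three convolutions
(128/64/64 filters, kernel 3, stride 1, ReLU, zero `same` padding) each
followed by width-2 max pooling → BiLSTM (64 units per direction) →
single-head self-attention. Choices made where the architecture was
genuinely open:

* **Masking discipline.** Activations past a sequence's true length are
  forced to zero after every convolution; pooling pads up to a multiple of
  the window so real positions are never dropped and window boundaries are
  independent of total padding; the LSTM freezes hidden and cell state
  across masked steps; attention adds −10⁹ to padded key scores before the
  softmax. On top of this, the forward pass trims every batch to its
  longest true length before any arithmetic, which makes scores *exactly*
  (bit-for-bit) invariant to trailing padding rather than invariant up to
  float summation order.
* **BiLSTM combination.** Per position, Hm = tanh(Cf·W4 + Cb·W6)
  (dimension 2·64 = 128); the per-channel summary H concatenates the final
  forward and backward hidden states, giving the two 128-dimensional
  vectors H1, H2. Attention consumes the full Hm sequence.
* **Attention.** Q = E·WQ, K = E·WK, V = E·WV with a single linear map per
  channel (one head); raw scores are the plain dot products K·Q with *no*
  √d scaling (a `scaled_attention` flag enables the scaled variant for
  comparison); softmax normalizes over the key axis so each query's
  weights sum to 1; the attended sequence is mean-pooled over unmasked
  query positions into one vector per channel.
* **Fusion and head.** Plain concatenation [H1, H2, A1, A2, B] (B = the
  z-scored biological features, statistics fitted on the training split
  only), then a 256/128/64 ReLU MLP with interleaved dropout and a sigmoid
  output. The two channels use separate, untied weights.
* **Training.** Binary cross-entropy on logits, Adam (lr 10⁻³), batch 64,
  up to 50 epochs with early stopping (patience 5 on validation loss) and
  best-validation-weight restoration; forget-gate biases initialized to 1;
  all randomness (init, shuffling, dropout) flows from one seed, so a
  fixed seed reproduces loss curves exactly.

Hyperparameters not pinned down by the architecture constraints
(embedding dim, kernel and pool sizes, attention dim 64, MLP widths,
dropout 0.3, optimizer settings) are standard values consistent with every
stated constraint. `ModelConfig.compact()` (embed 16, filters 32/16/16,
LSTM 16/direction, attention 16, MLP 32/16/8) is the configuration used by
the tests and benchmarks; it exercises the identical code paths at desk
scale.

The network and its reverse-mode autodiff engine are implemented in
NumPy inside the package (`thermoseq.nn`): tensors are float64, gradients
are exact (verified against central differences), and execution is
single-threaded deterministic.

## Feature selection

`rfecv` wraps scikit-learn's RFECV with a LightGBM classifier scored by
total split gain — the standard gradient-boosting importance, robust to
feature scale. Defaults: 10 stratified folds, step 8 (797 → ~1 in ~100
eliminations), AUC scoring, ties broken toward the smaller subset.
Constant columns are tolerated but flagged. The selected-subset size is
data-dependent output, not a contract; the tests assert the procedure
(recovery of planted informative features, selected-vs-full CV parity
within 0.01 AUC), not a particular count.

## Dataset pipeline

Order: OGT class assignment → fragment drop → length filter → identity
clustering → balancing; re-running with the same seed is byte-identical.
Boundary semantics are inclusive at 60 and 37 °C and strict at 1500
residues. "Fragment" records are identified by the case-insensitive token
`fragment` in the description line, the UniProt convention. The built-in
clustering is greedy longest-first: a record joins the first cluster whose
representative it matches at ≥ 40% identity (matches / alignment columns
under BLOSUM62 global alignment with affine gaps, open −10, extend −0.5),
else founds a new cluster. It is quadratic and intended for fixtures and
tests; `use_cdhit=True` delegates to the external CD-HIT program for
production-scale corpora (word size 2 below 50% identity). Whether
clustering should run within or across classes is left to the caller; the
pipeline clusters the pooled collection, which is the conservative choice
against cross-class homology leakage.

## Metrics

Confusion counts use score ≥ threshold (default 0.5) as positive. Ratios
with zero denominators are reported as NaN and flagged; MCC is 0-guarded
with a flag when any marginal vanishes. AUC uses the ascending-rank
formula with average ranks for tied scores — the unique convention that
makes it equal the probability a random positive outranks a random
negative with half credit for ties, and therefore invariant under strictly
monotone score transforms. AP is the step-wise sum over descending
distinct-score thresholds with Recall₀ = 0. Both are cross-checked in the
tests against brute-force oracles (pairwise enumeration; threshold
enumeration) and scikit-learn's implementations.

## Synthetic data

`generate_corpus` draws residue-i.i.d. sequences from class-specific
composition profiles. The negative profile is uniform; the positive
profile multiplies the 13 hydrophobic/charged/aromatic residues
{V,I,L,F,M,W,Y,C,D,E,R,K,H} by exp(+s/2) and the rest by exp(−s/2)
(renormalized), with signal strength s = 1 by default and s = 0 giving
identical classes (verified by Monte-Carlo calibration of a chi-square
composition test). Lengths are lognormal (meanlog 4.7, sdlog 0.35; median
≈ 110 residues) clipped to [40, 1500], chosen so every record satisfies
the descriptor preconditions while keeping desk-scale runtimes. OGT
annotations are drawn uniformly inside each class's temperature band.
`generate_feature_table` plants `n_informative` class-shifted Gaussian
columns (Cohen's d = 1) among shared-noise columns and returns the ground
truth names.

**What passing these benchmarks shows — and does not.** The generator
produces compositional class signal with no positional structure, no
phylogenetic correlation, no length–class dependence and no annotation
noise. End-to-end success (held-out AUC ≥ 0.95 at 400 sequences/class,
shuffled-label control at chance) demonstrates that the full pipeline —
descriptors, encodings, network, training loop, evaluation — is wired
correctly and can learn a real signal, not that comparable accuracy would
be reached on natural sequence corpora, where class signal is weaker and
homology structure matters.

## Numerical conventions and degenerate inputs

* Descriptors are deterministic; identical input gives bit-identical
  output.
* Sequences shorter than 31 residues are rejected by the full panel (the
  error names the lag families), never zero-padded.
* An all-padding (empty) model input raises; a batch record failing
  descriptor preconditions in `predict_batch` is reported per-record and
  the batch continues.
* Softmax masking uses a −10⁹ additive bias; masked weights underflow to
  exactly 0.
* Max pooling routes gradients to the first maximum on ties.
* CSV feature tables are written with shortest round-trip float
  representation and read back with the round-trip parser, so write→read
  is bit-exact.
* Checkpoints are single `.npz` archives holding weights, the full model
  configuration, descriptor names and standardization statistics.

## Benchmark problem sizes

The repository's benchmarks run at sizes chosen to exercise every code
path on a single CPU: end-to-end training uses 400 sequences per class
(80/20 split, compact architecture, 10 epochs); selection recovery uses a
400 × 100 table with 10 informative columns (10-fold CV, step 8); metric
and attention property checks use 100 and 50 random instances.

## Known limitations

* The built-in identity clustering is O(n²) alignments; use CD-HIT beyond
  a few thousand sequences.
* The NumPy network trains at desk scale; it is not a GPU training stack,
  and the full-width default configuration is practical for inference and
  shape checks rather than large-corpus training.
* QSO's first distance matrix is the package's own standardized-property
  construction (documented above), not the Schneider–Wrede table; values
  are on the same [0, 1] scale but not numerically identical to
  implementations that ship that table.
* Single-head attention only; no transformer blocks, no multi-head
  variant.
* No structure-derived features (hydrogen bonds, salt bridges, disulfide
  bonds): the predictors are sequence-only.
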