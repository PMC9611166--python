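# Methods

## Problem and model

Cocrystal screening asks whether an active pharmaceutical ingredient
(API) and a candidate coformer will crystallize together.  We treat it
as binary classification on a *pair graph*: the union of the two
molecules' heavy-atom graphs, with bonding information split into two
m × m binary matrices (m = total atom count, API atoms indexed first):

- **A_C** (covalent): the bond adjacency of each molecule in its own
  diagonal block; intermolecular blocks zero.
- **A_NC** (noncovalent): 1 for every intermolecular atom pair, 0
  within each molecule.  The model is given *all possible*
  intermolecular contacts and must learn which matter.

Both matrices are symmetric, zero-diagonal, and have disjoint supports.
No self-loops are added and the adjacencies are not degree-normalized
by default (the residual connections carry self-information; symmetric
normalization is available behind `Hyperparameters.normalize_adjacency`).

The network is a five-module GCN over the atom-feature matrix X_in
(all activations ReLU):

    h_NE = relu(b2 + relu(b1 + X_in W1) W2)        node embedding
    h_C  = h_NE + relu(A_C  h_NE W_C)              covalent convolution + residual
    h_NC = h_C  + relu(A_NC h_C  W_NC)             noncovalent convolution + residual
    h_GP = 1ᵀ h_NC                                 global sum pooling
    p    = sigmoid(b_FC2 + relu(b_FC1 + h_GP W_FC1) W_FC2)

Sum pooling follows the literal all-ones-vector formulation; a mean
variant is available (`mean_pool=True`) since the (1/T)-scaled reading
is also defensible.  Because pooling sums over all atoms and the
adjacency blocks are symmetric, the prediction is invariant to atom
relabeling within either molecule and to swapping the API/coformer
argument order — both are asserted in tests.

Ablation variants keep exactly one convolution: `use_covalent=False`
skips the A_C step (h_C = h_NE), `use_noncovalent=False` skips the A_NC
step.  At least one must remain enabled.

## Atom features (28 per atom)

Element one-hot over {C, N, O, S, F, Cl, Br, I, P, other}; heavy-atom
degree one-hot 0–5; total hydrogen count one-hot 0–4 (clipped);
formal charge (numeric); aromaticity flag; ring-membership flag;
hybridization one-hot {sp, sp2, sp3, other}.  Hydrogens are implicit.
This is the de-facto feature set of small molecular GCNs; the exact
composition is a design choice here, recorded in `FEATURE_DIM`, and any
fixed-width alternative is drop-in.

## Training

Binary cross-entropy (probabilities clipped at 1e-7) minimized with
Adam (β₁=0.9, β₂=0.999).  Defaults: embedding widths 64/64,
convolution width 64 (tied to the embedding width by the residuals), FC
hidden 128, learning rate 1e-3, batch size 64, 100 epochs, the
checkpoint with the best validation AUC returned.  Weights are
Glorot-uniform from a seeded generator; shuffling uses the same seed,
so training is bit-reproducible.

The implementation is NumPy with hand-derived gradients: the
architecture is fixed and small, so explicit backprop through the eight
weight matrices is simpler and lighter than an autodiff framework.  A
finite-difference check in the test suite validates every gradient.
Batches are zero-padded to the largest pair in the batch with an
explicit node mask multiplied in after every activation, so padded rows
(which biases would otherwise make nonzero) contribute exactly zero to
pooling; a test asserts batched and unbatched forwards agree.

## Evaluation

Confusion counts at a 0.5 probability cutoff (standard for balanced
data; the cutoff is an argument), giving accuracy, precision
TP/(TP+FP) and recall TP/(TP+FN); a metric with a zero denominator is
reported as `None`, never as 0.  AUC is rank-based (Mann–Whitney, ties
contributing ½), cross-checked against scikit-learn in tests.
Cross-validation is k independent random 8:1:1 train/validation/test
resplits — re-randomized each repetition rather than a partitioned
k-fold — with per-fold and mean metrics reported.  Splits are
stratified by label (class balance within one pair per class), using
largest-remainder rounding within each class.

## Dataset construction and rebalancing

Pair identity is unordered and canonical-SMILES-based (cocrystal
formation is symmetric).  Deduplication keeps the first occurrence of
each {a,b}-with-label combination.  Negative generation samples
distinct unordered pairs uniformly outside a forbidden set.

Rebalancing replaces part of the generated negatives with experimental
negatives while flattening compound over-representation: compounds are
ranked once by (frequency among generated negatives − frequency among
positives), descending, ties broken lexicographically.  Walking down
that ranking, a compound whose surviving generated frequency M exceeds
its positive frequency N keeps only a MaxMin-diverse subset of its
pairs; the deficit counts toward the removal total, and the last
compound is truncated so the total is hit exactly.  Frequencies of
later compounds are recomputed over surviving pairs at their turn (the
ranking itself is not recomputed).  The experimental negatives are then
appended unchanged, so |output| = |generated| − removed +
|experimental| exactly.

MaxMin uses distance = 1 − Tanimoto similarity of the pair's two
1024-bit ECFP (radius 2) fingerprints concatenated in sorted canonical
order; the greedy start is the first item in input order and ties break
to the lowest index, making selection fully deterministic (the
fingerprint, distance and start rule are design choices — diversity
selection needs *a* molecular distance, and ECFP/Tanimoto is the
field's default).

## Synthetic data

The generator emulates the statistical shape of a curated
cocrystal training set without any licensed data.  Molecules come from
a fragment grammar — alkyl/aryl scaffolds decorated with hydrogen-bond
donor motifs (carboxylic acid, alcohol, phenol, primary amide),
acceptor motifs (pyridine/pyrazine nitrogen, ester), or neither — so
every SMILES is valid by construction; each class is verified by SMARTS
matching and the three class pools are disjoint (84/56/82 molecules).
The planted rule mirrors the heterosynthon concept: a pair is positive
iff one member is a donor molecule and the other an acceptor molecule.
Label noise is symmetric flipping, the simplest stand-in for the
false-negative problem of randomly generated negatives.  An optional
Zipf-like `skew` parameter concentrates negative sampling on a few
molecules, creating the over-represented compounds that rebalancing
targets.

Defaults — 150 molecules (35% donor / 35% acceptor / 30% motif-free),
1200 positive + 1200 negative pairs, 5% label noise — define the
package's reference study: 2000 pairs to train (1800 train + 200
validation for checkpoint selection) and 400 held out.  What passing
tests on this data show: the full pipeline can recover a known
structure-determined pairing rule end to end, and the attribution
method points at the rule's atoms.  What they do not show: performance
on real crystallographic data, whose chemistry is far more diverse,
whose "rule" is not a clean substructure predicate, and whose negatives
are not uniform random pairs.

## LRP attribution

The pre-sigmoid logit (not the probability — conservation only holds
before the output nonlinearity) is redistributed backwards with the
epsilon-stabilized z-rule: each neuron passes relevance to its inputs
in proportion to their contributions z_ij to its pre-activation, with
denominator Σ_i z_ij + ε·sign(Σ).  Bias terms are excluded from the
denominator, so at ε = 0 every step is exactly conservative and the
atom relevances sum to the logit (asserted to 1e-4); ε > 0 (default
1e-6) damps instabilities at near-cancelling denominators at the cost
of absorbing some relevance.  Adjacency multiplications are fixed-weight
linear layers (relevance flows along edges); residual additions split
relevance between skip and convolution branches in proportion to their
forward contributions — both are our design choices where the LRP
literature offers several variants, and both are swappable at the
`lrp_linear` level.  Relevance passes through ReLU unchanged.  Per-atom
relevance is the row sum of the input-feature relevances.

Heat maps shade atoms on a symmetric diverging scale centered at zero:
red positive, blue negative, intensity |relevance| normalized by the
per-pair maximum.

## Screening

Every candidate is paired with the API, scored by the trained model,
and sorted by descending probability with ties kept in input order
(stable sort); unparseable candidates are logged and excluded rather
than aborting a campaign.  `top_k` truncates the returned list; the
written table always contains every parseable candidate.

## Problem sizes and numerical choices

The reference study (2400 pairs, three trained models at 100 epochs)
runs in a few minutes on one CPU; examples use 20-epoch budgets.
Float64 throughout.  Degenerate inputs: empty molecules, empty
datasets, single-class training sets, all-zero pooling masks, k outside
[1, n], and exhausted pair pools all raise with messages naming the
limit; unsupported elements fall into the "other" feature bucket rather
than raising.

## Known limitations

- The atom feature set and hyperparameters are conventional choices,
  not tuned; no hyperparameter search is implemented.
- The synthetic rule is learnable to AUC ≈ 0.95 under 5% label noise
  (the noise bounds the ceiling); it cannot certify real-data accuracy.
- `generate_negative_pairs` enumerates candidate pairs, which is
  exact but memory-heavy beyond ~10⁴ molecules.
- LRP is the only attribution method provided; no gradient or
  attention baselines.
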