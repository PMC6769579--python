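# Methods

## Problem and model

`lncdis` predicts candidate lncRNA–disease associations from a heterogeneous
network over three node types: lncRNAs, diseases and miRNAs. The inputs are
three binary relation matrices — lncRNA–disease associations `A` (Nl × Nd),
lncRNA–miRNA interactions `B` (Nl × Nm), disease–miRNA associations `C`
(Nd × Nm) — and three within-type similarity networks `L`, `D`, `M`. The
network adjacency is the symmetric block matrix

    U = [[L,  A,  B ],
         [Aᵀ, D,  C ],
         [Bᵀ, Cᵀ, M ]],      N = Nl + Nd + Nm.

Row `u_i` of `U` is node *i*'s full relational profile and serves as its
topology feature vector.

Two learners score a pair (lncRNA *i*, disease *j*) and their probabilities
are fused as `score = λ·scoreˡ + (1−λ)·scoreʳ` with λ = 0.8 by default.

**Network-representation branch (left).** A feature-level attention module
computes per-node weights `αᵢ = softmax(H_att · tanh(W_att uᵢ + b_att))` and
enhanced features `xᵢ = αᵢ ⊙ uᵢ`. A one-layer graph-convolution autoencoder
embeds the nodes, `Z = softmax_rows(Ũ X W_enco)` with
`Ũ = E^(−1/2)(U+I)E^(−1/2)` the symmetrically normalised self-looped
adjacency (`E` its degree matrix), and reconstructs
`X̂ = σ(Ũ Z W_deco)` under the mean-squared error `‖X−X̂‖²/N²`. A 2-class
softmax head on the concatenation `[z_i ; z_{Nl+j}]` produces `scoreˡ`.

**Local-representation branch (right).** The pair embedding `P_{ij}` stacks
rows `i` and `Nl+j` of `U` (2 × N); a ring of zeros gives the 4 × (N+2)
input so the convolution sees the margins. Three
convolution + ReLU + stride-1 max-pool stages (20/30/40 filters; the first
filter window 3 × 11, later ones 2 × 11 with one zero row appended so 2-row
maps can chain; 1 × 2 pooling) feed a flattened vector through dropout
(p = 0.5) into a 2-class softmax head, yielding `scoreʳ`. Convolution is
cross-correlation (no filter flip), valid, stride 1. Dropout is classical
(non-inverted): activations are zeroed with probability 0.5 in training and
all activations are scaled by 0.5 at inference.

Both branches are NumPy implementations with hand-derived backpropagation
and an Adam optimizer; the gradients of every trainable tensor are verified
against central finite differences in the test suite, and every forward
operation against literal scalar-loop references.

## Similarities

* **Disease similarity** is DAG-based semantic similarity: each disease
  contributes 1 to itself and `Δ·contribution(child)` (maximised over paths,
  Δ = 0.5) to each ancestor term; two diseases' similarity is the sum of
  both contributions over shared ancestors divided by the sum of their total
  semantic values.
* **lncRNA and miRNA similarity** is best-match-average functional
  similarity over the disease sets they are associated with (from `A` and
  `Cᵀ` respectively). Entities with no associated disease get similarity 0
  to every other entity and 1 to themselves — the no-information prior.
* Similarity weights enter `U` continuously (no thresholding); the
  association blocks are 0/1.

## Training schedule and defaults

| parameter | default | notes |
|---|---|---|
| λ (fusion weight) | 0.8 | weight of the network branch |
| n (embedding width) | 100 | |
| filters per stage | 20, 30, 40 | |
| first filter window | 3 × 11 | later stages 2 × 11, one padded row |
| pooling window | 1 × 2 | stride 1 |
| lr (left branch) | 0.001 | Adam, both phases |
| lr (right branch) | 0.0005 | Adam |
| dropout | 0.5 | flattened CNN features only |
| epochs: reconstruction | 200 | full batch |
| epochs: pair classification | 100 | full batch |
| epochs: CNN branch | 15 | minibatch 64 |

The left branch trains in two phases: (1) attention + encoder + decoder
minimise the reconstruction loss; (2) the head and the encoder weights
minimise the pair cross-entropy. Whether phase 2 should also update the
attention parameters is genuinely open; a sensitivity analysis on validation
folds (fold seeds disjoint from those used for evaluation) showed that
fine-tuning the ~2N² attention parameters on a few hundred labelled pairs
makes held-out AUC drift downward with epochs, while freezing them is stabler
and never worse. The default therefore freezes attention in phase 2
(`finetune_attention=True` restores the joint variant). Reconstruction in
phase 1 uses the attention-enhanced features current at each step (a moving
target, accepted). Epoch counts are not part of the model definition; the
defaults above were chosen where the training losses plateau at the standard
problem size while keeping a full five-fold evaluation in the minutes range
on one CPU, and all are config-exposed. The CNN branch trains in single
precision; the left branch and all evaluation are double precision.

Parameter initialisation is Glorot-style uniform with caller-supplied seeds;
one root seed is split deterministically into per-component seeds
(initialisation, batch shuffling, dropout, negative sampling, folds,
permutation control), making every pipeline run bit-reproducible in eval
mode.

## Evaluation protocol

Positives are the known associations; an equal number of negatives is drawn
uniformly without replacement from the zero cells of `A`. Both classes are
split into five folds. For each fold the held-out positives are removed from
`A` and the lncRNA similarity is **recomputed from the remaining
associations** before the network and the pair embeddings are built, so no
test label leaks into training inputs (disease and miRNA similarities are
not recomputed). A pair is predicted positive when its fused score exceeds a
threshold θ; sweeping θ over every distinct score yields the ROC and PR
curves. AUC is the trapezoid area (identical to the Mann–Whitney pairwise
estimator with ties counted ½ — asserted to 1e−12 in tests); precision at
TP+FP = 0 is defined as 1, anchoring the PR curve at recall 0. Top-k recall
ranks, per disease, all lncRNAs without a training association and reports
the fraction of held-out positives in the top k, averaged over diseases (k
values exceeding a disease's candidate count are dropped). Reports include
both pooled (all test scores merged) and macro (fold-averaged) AUC/AUPR. A
label-permutation control (100 permutations of the pooled test labels)
estimates the chance level.

## Synthetic data

The generator plants a block structure resembling curated association
databases: each entity is assigned one of G latent blocks; associations are
Bernoulli(p_in) within matching blocks and Bernoulli(p_out) otherwise, for
all three bipartite matrices. The disease ontology is generated with one
anchor chain of depth `dag_depth` per block under a common root; each
disease attaches to a random anchor of its block's chain, so same-block
diseases share deep ancestors and cross-block diseases share only the root.
Disease similarity for synthetic runs is computed from this DAG through the
same code path as real data. Defaults: Nl = 60, Nd = 80, Nm = 50, G = 5,
p_in = 0.3, p_out = 0.02 — about 380 positive associations over a 190-node
network.

What the generator does **not** emulate: heavy-tailed degree distributions,
correlated annotation noise, name ambiguity, and — by construction — any
marginal (per-node) association propensity: blocks are uniform and
symmetric, so only the block-match *interaction* carries signal. This has a
consequence worth stating plainly: the network branch's pair head is linear
on the concatenation of the two node embeddings, i.e. additive in the nodes,
and an additive scorer cannot express an interaction. On this generator the
network branch alone therefore performs near chance (≈0.5–0.6 AUC; a
logistic regression on the same concatenated profiles gives ≈0.46), whereas
the CNN branch, whose 2-row filters see both profiles jointly, reaches
≈0.75–0.83, and the fused score is pulled between the two by λ. On real
association data, where node degree is strongly informative, the additive
branch is far more useful — passing integration tests here demonstrates
correct mechanics and recoverable planted signal, not real-data performance
figures.

## Numerical choices and edge cases

* Softmax rows are computed with max-shift; the decoder uses the standard
  logistic `1/(1+e^(−t))`.
* Isolated nodes are harmless in normalisation: the self-loop guarantees
  degree ≥ 1.
* Score-file ties are broken lexicographically by (lncRNA, disease) so
  outputs are deterministic.
* Duplicate edges in input files collapse to one with a logged warning;
  unknown entity names are an error in strict mode, skipped with a warning
  otherwise.
* `sample_negatives` refuses to sample more negatives than zero cells;
  `make_folds` requires at least one pair per fold in both classes.
* Cross-entropy clips probabilities at 1e−300 before the log; training
  aborts with a diagnostic on non-finite losses or gradients.

## Known limitations

* The additive network-branch head limits what the left branch can learn on
  interaction-only data (see above); λ is deliberately left at its standard
  0.8 rather than re-tuned per dataset.
* Single graph-convolution encode/decode (no deeper stacks) and a single
  attention layer, as the model defines.
* Dense matrices throughout; fine for N of a few thousand, not for much
  larger catalogs.
* The evaluation re-samples negatives once per run; variance across negative
  samples is visible across seeds rather than averaged within a run.
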