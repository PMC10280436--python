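# Methods

## Dataset construction

Coordinates are 1-based inclusive throughout (the Ensembl convention).
A transcript annotation row carries `transcript_id`, `chromosome`, `strand`,
`transcript_start`, `transcript_end` and `tss`; rows with a null value in any
relevant field are dropped and counted by the BioMart-export adapter.

**Window geometry.** The TSS base plus the two following bases (in
transcript orientation) form the TSS codon. A window concatenates
`upstream_flank` bases before the codon, the codon, and `downstream_flank`
bases after it; the defaults 700/3/300 give 1,003 nucleotides with the TSS
base at window position 701. Windows are reported 5′→3′ on the transcript's
strand; minus-strand reference spans are reverse-complemented. The paperless
corner cases are resolved as follows: windows containing a character outside
{A,C,G,T} are discarded and counted in the dataset provenance (the 4-symbol
one-hot encoding cannot represent them); transcripts sharing a TSS each
contribute a positive by default (an optional dedup flag collapses them).

**Negative sampling.** For each transcript, anchors are drawn uniformly
without replacement from positions inside `[transcript_start,
transcript_end]` that (a) are not an annotated TSS on that chromosome
(exclusion radius 0 by default, configurable) and (b) admit a full window on
the transcript's strand. If fewer than the requested `n` positions are
eligible, all of them are used and a warning is logged. The default ratio is
10 negatives per positive; the test partition always keeps that ratio, which
is approximately what real data shows.

**Splits.** Partitioning is by whole chromosomes (defaults: chromosome 16
validation; 1, 3, 13, 19, 21 test; everything else train), which prevents
positional leakage between partitions. Because chromosome-holdout rules out
classical k-fold cross-validation, repeated evaluation uses five seeded
repetitions instead: neural models are re-initialized and re-shuffled,
cascade SVMs re-randomize their level-0 subsets.

## Encoding

Each base maps to a binary indicator vector under the fixed alphabet order
A, C, G, T (lowercase input is accepted and uppercased). A window of length
L becomes an L×4 matrix whose rows each sum to 1; row-major flattening gives
the 4L-dimensional feature vector used by numeric models — 4,012 features
for the standard window.

## Kernels

The weighted-degree kernel of order d scores two equal-length sequences by
their positionally matching k-mers:

    K(s_i, s_j) = Σ_{k=1}^{d} β_k Σ_{l=1}^{L−k+1} 𝕀[u_{k,l}(s_i) = u_{k,l}(s_j)],
    β_k = 2 (d − k + 1) / (d (d + 1)),   Σ_k β_k = 1.

It is positional: no shift or mismatch tolerance, matching the printed
formula. The gram builder uses an exact reformulation: with c_l the length
of the run of consecutive base matches ending at position l, the kernel
equals Σ_l B(min(c_l, d)) where B(m) = Σ_{k≤m} β_k. This evaluates each pair
in O(L) independent of d, vectorizes across blocks of pairs, and is
bit-identical to the direct double loop (tested against it). Self-grams are
exactly symmetric because entries (i,j) and (j,i) perform identical
operations. Row-block decomposition is the parallelization contract: any
partition of the rows yields a bit-identical matrix. Gram values are not
normalized (no K/√(K_ii·K_jj)), matching the formula as printed. An optional
on-disk cache keys gram matrices by (d, sequence-list hash).

The RBF kernel K(x, x′) = exp(−γ‖x−x′‖²) operates on flattened one-hot
vectors; the gram is delegated to scikit-learn's pairwise implementation.

## Cascade SVM

Level 0 splits the training set into 2^p random subsets, stratified by class
(with 1:10 imbalance an unstratified subset can lose the minority class
entirely) and seeded. Each level fits one SVM per set and keeps only its
support vectors; adjacent support-vector sets merge pairwise until a single
SVM remains. Its support set is fed back into every level-0 subset and the
pass repeats. Convergence criterion: the global support-index set is
unchanged between consecutive passes (the cheapest faithful reading of
"repeated until convergence"); a budget of 5 global passes bounds the loop.
With one subset the scheme reduces exactly to a single SVM fit.

Per-node fitting uses scikit-learn's SVC on a precomputed gram sub-matrix
(the full train gram is computed once per kernel and sliced per node), with
solver tolerance 1e−3 and no class weighting. The final model is the
support-vector expansion f(x) = Σ_s α_s K(x_s, x) + b; hard labels threshold
at 0. Because cross-entropy needs probabilities, a monotone sigmoid
calibration (logistic regression on decision scores) is fitted on the
validation split; probabilities are clipped to [1e−15, 1−1e−15]. Grid search
trains one cascade per cell, selects by validation AUC-ROC, and breaks ties
toward smaller C, then smaller d (or γ).

## Neural architectures

All five models take an L×4 one-hot window and end in a single sigmoid unit:

| name | stack |
|---|---|
| cnn | 3 × [conv1d(32 filters, width 5, stride 1) → maxpool(4)] → dense(1024) → drop 0.2 → dense(512) → drop 0.2 → dense(128) → drop 0.2 → dense(1) |
| lstm | LSTM(128) → dense(64) → drop 0.5 → dense(1) |
| blstm | BLSTM(128 per direction, concatenated) → dense(64) → drop 0.5 → dense(1) |
| cnn_lstm | conv1d(64, width 3) → maxpool(3) → drop 0.25 → LSTM(64) → drop 0.8 → dense(1) |
| cnn_blstm | same with BLSTM(64 per direction) |

Open choices were resolved as: valid (no) convolution padding with pooling
stride equal to pool size; ReLU hidden activations; "bidirectional layer of
128 units" read as 128 per direction with concatenated outputs (the common
convention); recurrent layers return only their final state.

The numeric backend is a compact numpy engine authored here: explicit
forward/backward passes for dense, 1-D convolution, max pooling, inverted
dropout and (bi)directional LSTM layers (gate order i, f, g, o; forget bias
initialized to 1; Glorot-uniform weights), verified against central-difference
numerical gradients to ≤1e−5 relative error. Training: Adam (β₁ 0.9, β₂
0.999, ε 1e−8), learning rate 0.001, batch size 32, binary cross-entropy
computed stably on logits, at most 100 epochs, early stopping after 10
epochs without validation-loss improvement with best-validation weights
restored. The loss is not reweighted for class imbalance — imbalance is
handled through data ratios only. All randomness (initialization, shuffling,
dropout) derives from explicit seeds; repeated runs with one seed reproduce
losses exactly.

## Metrics

Acc = (TP+TN)/N; Precision = TP/(TP+FP); Recall = Sn = TP/(TP+FN);
F1 = 2PR/(P+R); Sp = TN/(FP+TN). Zero-denominator ratios return 0 and are
flagged "undefined" rather than raising — degenerate classifiers are then
reported with near-zero F1 instead of an error. Binary cross-entropy uses
the natural logarithm with probabilities clipped to [1e−15, 1−1e−15]; the
clip explains the large finite values miscalibrated SVM scores produce.
AUC-ROC is the Mann–Whitney statistic computed from average ranks (ties
count one half), equal to the trapezoidal ROC area; it requires both classes
and is checked against exhaustive pair counting and scikit-learn. Hard
labels threshold probabilities at 0.5.

## Experiment harnesses

The ratio experiment trains one arm on the full 1:10 train partition and one
on an undersampled 1:1 copy (negatives subsampled uniformly without
replacement, positives untouched), evaluating both on the identical 1:10
test partition. An external oversampler hook (e.g. a SMOTE wrapper) can add
a third arm; none is bundled. The fraction experiment trains on stratified
subsets of ⌊f·n⌋ instances per class; for a fixed seed each class's indices
are permuted once and prefixes taken, so the 10% subset is nested inside the
50% subset. Cross-species evaluation applies an already-fitted model to
another dataset with no retraining, after checking window-length
compatibility. `repeat_with_seeds` runs a task at seeds base, base+1, …,
and aggregates mean and standard deviation recomputably from per-repeat
rows.

## Synthetic genome generator

Chromosomes are i.i.d. background with P(G) = P(C) = gc/2, P(A) = P(T) =
(1−gc)/2. Each transcript gets a strand (balanced, shuffled), a TSS placed
so that full extraction windows exist on either side, and a span containing
the TSS. The consensus motif is written on the transcript's strand starting
at the TSS (reverse-complemented into the reference on the minus strand);
each motif base is independently replaced by a uniform random base with
probability `motif_noise`, so a base survives with probability
1 − noise + noise/4. The fixture emulates exactly what the pipeline
contracts need — coordinates, strands, flanks, a learnable signal — and none
of what real genomes add: exon/intron structure, CpG islands, isoform-level
TSS clusters, soft masking, N runs, or realistic promoter composition.
Passing tests therefore demonstrate correctness of the machinery and
learnability of a planted signal, not expected performance on a real genome.

## Desk-scale study conditions

The learnability study (used by tests, examples and the acceptance script)
fixes: a 16-base motif (`TATAAAGGCCGATCGC`) at 5% per-base noise; a 20-base
window (4 upstream + codon + 13 downstream) so the motif spans most of the
window; background GC 0.5 so base composition carries no class signal; five
20 kb chromosomes with 100 transcripts; 10 negatives per positive;
chromosome 4 held out for validation and 5 for test (~680 train instances at
1:10). The short window is what makes the study desk-scale: a final-state
LSTM trained on ~60 positives cannot escape the majority-class prior within
a CPU-feasible epoch budget when the motif occupies a small fraction of a
long window, whereas with the motif dominating the window both model
families recover it within the standard training protocol.

Cross-species transfer regenerates the genome with a different seed. The
shared-signal species keeps the motif; the null species sets motif
corruption to 1, planting an independent random 16-mer at every TSS and
hence sharing no signal with the learned one. A single fixed alternative
motif is deliberately not used as the null: whatever its chance resemblance
to the learned motif, it shifts every positive's score by the same amount,
and the measured AUC lands far from 1/2 in either direction; per-site
randomization is the null whose transferred-model AUC is centred at chance.

## Known limitations

* The numpy backend is single-threaded and desk-scale; full-genome training
  (10⁶ windows of length 1,003) is out of its reach by design.
* The cascade's final decision function comes from the last merge node;
  pathological non-separable data may need more than 5 global passes to
  stabilize (the budget then returns the last pass's model, flagged
  `converged=False`).
* The WD kernel is positional only; shift- or mismatch-tolerant variants and
  spectrum kernels are not implemented.
* Negative anchors are excluded only from exact TSS coordinates by default;
  biological near-TSS ambiguity (clustered initiation) is not modeled.
* `read_biomart_export` reads the genomic span of a transcript; spliced
  transcript coordinates are not supported.
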