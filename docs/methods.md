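# Methods

## The prediction problem

Given a protein sequence and a candidate lysine, decide whether that lysine
is propionylated. Training data are site tables (protein id, 1-based lysine
position, positive/negative label) over a FASTA collection; negatives are
lysines with no recorded modification, sampled to a 1:1 class balance.
Because annotated propionylation sites are scarce, the model is first
trained on the much larger malonylation site collection (the *source*
task) and then fine-tuned on propionylation (the *target* task) — the two
acyl modifications overlap heavily at the site level, so representations
learned on one transfer to the other.

## Peptide windows

Each candidate site is represented by the window of 2n+1 residues centered
on the lysine. Overhang past either protein terminus is padded with `X`,
which is also the 21st symbol of the integer-encoding vocabulary (the 20
standard amino acids in alphabetical order, then `X`; non-standard input
letters B, J, O, U, Z are mapped to `X` on ingestion). The residue-to-index
assignment is arbitrary up to a permutation of embedding rows; the fixed
alphabetical order makes encodings reproducible across runs and platforms.
Window sizes are odd by construction; the conventional search range is
21–41, and the `window_size_sweep` utility cross-validates each size.

## The recurrent feature extractor

Layer stack, input to output:

| layer | default size | notes |
|---|---|---|
| embedding | 21 × 32 | integer residue index → dense vector |
| biLSTM | 64 units/direction | returns full sequences |
| biLSTM | 64 units/direction | returns full sequences |
| biGRU | 32 units/direction | returns full sequences |
| dropout | rate 0.5 | training only; inference uses all units |
| flatten | (2n+1)·64 | concatenates per-position states |
| fully connected | 64 units, ReLU | **the feature layer** |
| output | 1 unit, sigmoid | binary site score |

Both LSTM stages and the GRU are bidirectional so each position's state
summarizes the window in both reading directions. The fully connected
layer immediately before the output is the penultimate layer; its
activations, computed in inference mode, are the learned features handed
to the SVM. A one-unit sigmoid output with binary cross-entropy is used
for the two-class task (a two-unit softmax is mathematically equivalent).

Training is mini-batch Adam on binary cross-entropy with per-epoch
shuffling, an optional validation split (default 10%) with early stopping
(patience 5, best weights restored), and a fine-tuning phase that updates
*all* layers at `finetune_learning_rate` (default 1e-4, one tenth of the
pretraining rate; an optional flag freezes the embedding). The pretraining
output head is reused at fine-tuning since the task shape is unchanged.
Every stochastic element — weight initialization, shuffling, dropout masks,
validation split — draws from generators fanned out deterministically from
the single config seed, so a full pretrain → fine-tune → extract run is
bitwise reproducible.

The network and its reverse-mode autodiff are implemented directly on
numpy (`proptl.nn`): fused gate weights per direction (LSTM gate order
i, f, g, o, forget bias 1; GRU with update/reset gates and a candidate
state), Glorot input weights, orthogonal recurrent weights, and a
numerically stable logit-space cross-entropy. Analytic gradients are
verified against central finite differences in the test suite. Float64 is
used throughout; the cost is negligible at these model sizes and it makes
gradient checks sharp.

## SVM stage

Features are standardized column-wise with statistics fitted on training
data only (constant columns map to zero); the same scaler object is applied
to any test data. The classifier is a soft-margin kernel SVM — penalty
factor C trades the margin term against slack misclassification — solved by
scikit-learn's `SVC` (polynomial degree fixed at 3, `scale`/`auto` gamma
following the usual conventions 1/(d·Var X) and 1/d). The hyperparameter
grid C × kernel × gamma is scored by mean accuracy over one stratified
k-fold split shared by all combinations (a paired comparison, witnessed by
a fold hash); ties break toward smaller C, then kernel and gamma listing
order. The default kernel list is {linear, poly, rbf} (54 combinations);
`SVMGridSpec.extended()` adds sigmoid, which historically also appears in
published result tables for this task. Selection by MCC instead of
accuracy is available via the model interface's grid result table.

## Evaluation protocol

`confusion`/`metrics` compute SN, SP, ACC and MCC exactly as defined above;
any zero denominator factor defines the affected metric as 0 and records
it in a `flags` field (this matters only for degenerate folds such as
leave-one-out). MCC is algebraically the Pearson correlation of the two
binary vectors, and the ROC trapezoid AUC equals the tie-corrected
Mann–Whitney pair statistic; both identities are enforced numerically in
the tests against brute-force oracles.

`kfold_cv` cross-validates the *pipeline*, not just the classifier: within
each stratified fold the extractor is (fine-)tuned, the scaler fitted, and
the SVM trained on the k−1 training folds only. When a source batch is
supplied, pretraining happens once per CV run — the source task contains
no target windows, so this leaks nothing — and only fine-tuning repeats
per fold. Each fold records the exact index sets every stage was fitted
on, making leakage auditable after the fact; `k = n` runs leave-one-out.
A cheaper protocol (`refit_extractor=False`) fits the extractor once on
all windows and refits only the SVM per fold; it is provided for sweeps
where per-fold extractor refits would dominate the cost, with the caveat
that the extractor then sees held-out windows. Both mean-of-folds and
pooled-confusion summaries are returned; the mean is primary.

Folds are stratified at the window level by default, with the independent
test always split at the *protein* level (4/5 of proteins to train,
rounded half away from zero), so no protein contributes windows to both
partitions. Negative sampling runs after the protein split, separately
within each partition, which is how the canonical 304+304 / 104+104 site
counts are matched exactly.

## Synthetic data: what it emulates and what it does not

The generator builds proteomes of i.i.d. uniform residues (lengths 80–200
by default, minimum lysine fraction 0.02 — rarely binding, so composition
stays uniform to within 1%), then plants a *motif*: a set of
(offset, residue) constraints applied to each positive site's flanks with
probability `signal_strength` per constraint. Negatives are untouched
lysines. Site selection is greedy over a shuffled lysine pool so that no
site's motif footprint can overwrite another chosen site's center — every
annotation still points at a lysine after mutation, which the data layer
re-validates.

A *transfer pair* couples a large source task and a small target task
whose motifs share a chosen fraction of constraints; the non-shared
constraints are disjoint in offset and residue. This is the synthetic
analogue of the malonylation/propionylation site crosstalk. The
benchmark-scale dataset reproduces the bookkeeping of the real data (189
proteins, 151/38 split, 304+304 train, 104+104 test, 816 windows) with
planted positives and sampled negatives.

Standard study conditions, fixed in `proptl.experiments`: motifs of six
constraints at signal strength 0.45; source 1,500–2,000 positives per
class; target 300 training and 100 test positives per class; window size
21; a compact extractor (embedding 8, LSTM 12/direction, GRU 8/direction,
dense 16, dropout 0.3, batch 256, 12 epochs with early stopping, learning
rate 1e-3 for both phases). Signal strength 0.45 puts the target task in
the regime where 300 positives are genuinely limiting — test MCC lands
around 0.2–0.5, comparable to real acylation predictors, rather than
saturating. Pretraining and fine-tuning share one learning rate here so
the fine-tuned and from-scratch arms receive the same optimization budget
on the target task; with that symmetry, pretraining on a 70%-overlap
source raises mean test MCC by ≈0.14 over five seeds, while with a
0%-overlap source the difference shrinks within ±0.1 of zero — the
transfer benefit tracks task relatedness, not extra computation.

What the generator does **not** emulate: real amino-acid composition,
positional dependence between motif constraints, homology structure
between proteins (no sequence families), or any mass-spectrometry noise
model. Passing the synthetic checks therefore demonstrates that the
pipeline's machinery is correct and that the transfer mechanism behaves as
designed — not that any particular accuracy will be achieved on real
proteomes. On real data, published results for this task additionally
depend on architecture hyperparameters that are not derivable from the
data themselves; the defaults above are reasonable, documented choices.

## Numerical and design notes

- Round-half-away-from-zero for the train split size (4/5 of 189 → 151).
- Negative sampling is uniform over all eligible lysines across the whole
  partition, not a per-protein quota — the simplest reading of "random
  unmodified lysines from these proteins".
- MCC zero-denominator convention: 0, flagged.
- Grid combinations that fail to fit are recorded with NaN accuracy and
  excluded from ranking, with a warning.
- CD-HIT redundancy reduction (identity 0.7) is an external preprocessing
  hook (`cdhit_reduce`) that shells out to a user-installed `cd-hit`
  binary and parses its `.clstr` output; the package never reimplements
  the clustering and its own tests use pre-deduplicated input.
- Dropout sits between the GRU and the flatten, per the layer order above;
  training-mode forward passes differ across calls, inference passes are
  identical.
- Checkpoints are an `.npz` of weights plus a JSON sidecar (config,
  provenance, loss history); feature matrices and all metric tables are
  TSV.

## Known limitations

- Training is CPU-bound pure numpy; it is sized for datasets of 10³–10⁴
  windows, not proteome-scale pretraining corpora.
- Window-level (not protein-grouped) CV folds are the default for the
  training-set cross-validation, matching common practice for this task;
  protein-grouped folds would give more conservative estimates and can be
  had by splitting proteins upstream.
- The polynomial kernel's degree and coefficients are fixed rather than
  searched.
- `predict` scores every lysine of the input proteins independently; it
  does not aggregate evidence across sites or proteins.
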