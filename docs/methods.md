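# Methods

## Problem and data model

A record is one missense mutation in a protein–DNA complex: complex id,
chain, wild-type residue, 1-based sequence position, mutant residue, the
experimental binding free-energy change ΔΔG (kcal/mol; positive =
destabilizing binding), a binding-class label (DSB = double-stranded,
SSB = single-stranded DNA-binding protein) and a train/independent
partition label. Binding classes and partitions are *inputs*: this
package neither classifies proteins nor re-curates thermodynamic
databases. Positions index the supplied chain sequence directly; any
mapping from author/PDB numbering is the data preparer's responsibility,
and the package validates only that the declared wild-type residue
matches the sequence at the stated position.

ΔΔG categories used in reporting follow the common convention: > 2.0
strongly destabilizing, 0.5–2.0 moderately destabilizing, −0.5–0.5
negligible, < −0.5 stabilizing.

## Reverse augmentation

For every forward record a reverse record is appended with wild-type and
mutant swapped and the label negated, reflecting the antisymmetry
ΔΔG(wt→mut) = −ΔΔG(mut→wt). Augmentation exactly doubles a dataset and
makes the pairwise label sum exactly zero. Augmenting an already
augmented set is refused. Fold splitting defaults to *pairwise*
grouping, so a forward record and its reverse always share a fold —
otherwise the regressor could trivially leak a pair across the
train/test boundary; complex-level grouping is available for stricter
evaluation. Duplicate rows (same complex/chain/position/mutation) are
kept but flagged, since conflicting measurements across source databases
are a data-curation question the tool does not adjudicate.

## Window-length selection by entropy

Windows of odd length L are centered on the mutation site and padded
with `X`. Across a grid of lengths (default 21, 41, …, 501) the package
computes, over the pooled symbols of all n windows:

* Shannon entropy H (bits) of the 21-symbol distribution,
* the valid (non-`X`) symbol fraction P_aa,
* the valid-residue rate between consecutive lengths,
  V_aa^k = (P_aa^{k−1} L_{k−1}) / (P_aa^k L_k) − 1,
* the relative entropy change (H_k − H_{k−1}) / H_{k−1}.

V_aa is exactly zero once no chain contributes new residues; before that
point the printed ratio is non-positive while valid counts grow, so a
sign-flipped `conventional` orientation is also provided for readers who
expect a literal "increasing rate" decaying to zero. The default is the
ratio as printed above.

The recommendation rule — smallest grid length with |V_aa| ≤ 0.01 and
non-increasing entropy — formalizes a joint inspection of the V_aa and
entropy curves; the threshold is configuration (`--v-threshold`), and an
explicit user-chosen length always wins. Entropy is computed on
wild-type windows only: mutant windows differ in one symbol per record,
a negligible perturbation of the pooled counts.

## Embedding channels

Three adapters are declared with their native per-residue widths: ESM-2
(1280), ESM-1v (1280), ProtTrans (1024). They require external model
weights and raise a capability error when absent — synthetic output is
never substituted silently. The deterministic synthetic backend produces
row i = f(residue_i) + g(i) with f a fixed injective per-residue table
(seeded standard normal) and g a small sinusoidal positional term;
padding rows are all-zero (`zero_row`) or g alone (`model_token`,
mimicking models that embed an unknown-residue token). A directory cache
keyed by backend, width, window length, variant and a content hash of
the window string makes embeddings reusable across runs.

**Channel variant.** The input fed to each channel can be the `mutant`
window embedding, the `wildtype` embedding, or their `difference`
(default). The difference is the only variant that is antisymmetric
under reverse augmentation — a reverse record's input is exactly the
negation of its forward partner's — matching the antisymmetry of the
label. With mutant-only inputs the wild-type residue is invisible
(it has been replaced at the center and does not appear elsewhere), so
the wt-dependent half of the label variance is unrecoverable in
principle; the difference variant removes that ceiling. Both alternate
variants remain selectable for ablation.

## Regressor

Per channel: two affine layers with a ReLU between them project L × D to
L × 256 (`projected_dim`, default 256, divisible by the 4 attention
heads); a fixed sinusoidal positional encoding is added; a dedicated
two-layer post-norm transformer encoder (4-head scaled-dot-product
self-attention, feedforward width 512, dropout 0.1, residual connections
and layer normalization) contextualizes the window. The encoders of the
three channels share no parameters. The mutation-site (center) rows are
concatenated into a 3 × 256 = 768-d vector and an MLP head
(256 → 128 → 1, ReLU) outputs ΔΔG.

Choices the architecture description leaves open, fixed here: ReLU
activations; fixed (not learned) sinusoidal positional encoding;
feedforward width 512; dropout 0.1; He fan-in weight initialization from
a config seed. The network and its gradients are implemented on a small
NumPy reverse-mode autodiff core (`plmddg.nn`); every primitive's
backward pass is checked against central finite differences in the test
suite, and eval-mode inference is bit-deterministic.

**Loss.** Pseudo-Huber, L_δ(a) = δ²(√(1 + (a/δ)²) − 1) with
a = y_true − y_pred; δ defaults to 1.0 kcal/mol (the transition from
quadratic to linear behavior at roughly the dataset's noise scale).

## Training and evaluation

Defaults: up to 150 epochs, early stopping with patience 40 on the
validation loss (validation PCC selectable), 10% pair-aware validation
split, Adam, batch 32. The reference protocol's optimizer, learning rate
and batch size are not published; defaults are recorded in every
EvalReport. Learning rate defaults to 1e-4 at reference width; the
scaled-down synthetic experiments (below) use 3e-3, which the smaller,
better-conditioned problem tolerates and needs to converge within the
epoch budget. Early-stopping arithmetic: the best epoch's weights are
restored; a metric frozen from epoch 1 stops training at epoch 41.

k-fold cross-validation (default k = 10, pairwise grouping) reports
per-fold PCC/MAE/RMSE/MSE, their mean ± std, *pooled* metrics over the
concatenated out-of-fold predictions (the two conventions differ
slightly; both are standard), metrics on the top-10% most extreme |ΔΔG|
records (ranked by |y_true|, ties broken by input order), and an
antisymmetry diagnostic: the correlation between forward predictions and
negated reverse predictions (reported, not asserted). Independent
evaluation refuses complex-id overlap with the training set unless
explicitly overridden.

PCC is flagged undefined (NaN in reports, `pcc_defined: false`) when
either vector is constant; error metrics are still computed.

## Embedding-landscape analysis

Per-record mutation-site embedding rows are projected to 2-D with t-SNE
(fixed seed; perplexity recorded in the output metadata and clipped
below the sample count), clustered with DBSCAN using eps = the median
distance to the 15th nearest neighbor and min_samples = 15, and profiled
per cluster by mean/min/max ΔΔG. Representative clusters are taken at
evenly spaced ranks of the mean-ΔΔG ordering (3–5 of them). t-SNE cluster
counts are illustrative, not reproducible targets: they depend on
projection parameters the upstream description does not fix.

## Synthetic benchmark generator

`plmddg.fixtures.generate` emulates the *shape* of a curated mutation
benchmark: i.i.d. uniform sequences, uniform mutation sites, and labels

ΔΔG = w·(f(mut) − f(wt)) + c·w_ctx·mean(f(flank ±2)) + N(0, σ²)

with f the synthetic backend's residue table. The weight vector w is
normalized so the main effect has exactly `signal_scale` = 1.5 kcal/mol
standard deviation over all ordered substitutions — the generator's
signal-to-noise is a design constant rather than a per-seed draw — with
σ = 0.3 kcal/mol noise and a context term at 10% weight (c = 0.1,
mildly informative flank contribution). Defaults: 20 complexes of
60–120 residues, 5 mutations each (100 forward records, 200
augmented).

Because the main term equals the planted weights dotted with the center
row of the *difference* channel input, the signal is linearly
recoverable from the mutation-site embedding: center-row extraction — the
architecture's key step — is necessary and sufficient. A held-out linear
probe on the center row reaches PCC ≈ 0.97 (the noise ceiling is ≈
0.98), and the full model's 10-fold pooled PCC ≥ 0.9 is the package's
recovery criterion. With σ = 0 and c = 0 the labels are *exactly* linear
in the center row and least squares fits with zero residual. Note the
context term lives in the flanking residues, which cancel in the
difference input, so it acts as a small additional noise floor for the
regressor.

What passing these tests does and does not show: they demonstrate that
the pipeline — augmentation, windowing, embedding, site-extraction,
fusion, training — recovers a signal placed where the architecture
assumes it lives. Real mutation effects are not linear functionals of
any embedding row, real sequences are evolutionarily correlated, and
real ΔΔG labels carry inter-laboratory noise; benchmark-level accuracy
on curated data is therefore *not* implied.

## Scaled-down problem sizes

The packaged experiments run the full three-channel architecture at
reduced width so they complete quickly on one CPU: window length 21,
synthetic channel widths (64, 64, 48), projection 32, feedforward 64,
4 heads, 2 encoder layers. The reference-width configuration
(181-residue windows, 1280/1280/1024 channels, projection 256) is the
library default and is exercised shape-wise in the tests.

## Known limitations

* Sequence-only: tertiary/quaternary context enters only through the
  PLM embeddings; no structure is read.
* The real-adapter path (ESM/ProtTrans) is an interface with declared
  widths; weights must be supplied by the user and are not validated
  beyond shape.
* The entropy-based length rule is a heuristic formalization; on data
  whose valid-count curve never flattens it falls back to the largest
  grid length with a warning.
* DBSCAN/t-SNE outputs depend on projection parameters; only the eps
  heuristic and the clustering itself are contract-tested.
* Training is single-threaded and deterministic given seeds; wall-clock
  performance, not numerical behavior, is the cost of the NumPy core.
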