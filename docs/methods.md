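# Methods

This note documents the models and procedures implemented in `mixdta`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Data model and label scales

A dataset is a registry of drugs (SMILES strings) and proteins (amino-acid
sequences) plus an ordered list of observed (drug, protein, label) pairs.
Duplicate (drug, protein) rows are a hard error rather than being averaged:
no aggregation rule is universally right (replicate assays, different assay
types), so the caller must resolve duplicates explicitly.

Kd-type labels in nanomolar are harmonized to pKd by
`−log10(min(Kd, cap) · 10⁻⁹)` with a default cap of 10 000 nM. The cap models
the assay's measurement ceiling and produces the hard floor at exactly
pKd = 5.0 that dominates Kd-type kinase panels. Integrated bioactivity scores
(KIBA-style) are passed through unchanged. Labels are stored as 64-bit reals;
range statistics use closed intervals.

## Splits

`warm` shuffles pairs; `cold_drug`/`cold_target` partition the *entity* set so
no held-out entity appears in training in any role. The train:valid:test
ratio defaults to 6:2:2. k-fold assignments are k independent seeded shuffles
(seed + fold index): a 6:2:2 ratio cannot be realized by rotating five fixed
quintiles, and independent shuffles keep every fold exchangeable. Block sizes
use largest-remainder apportionment, so they deviate from the exact ratios by
less than one unit. Cold splits apportion by entity count, not pair count;
pair counts per entity are unequal and entity-count apportionment is the
convention that keeps the held-out entity sets comparable across folds.

## Neighborhood scenarios and partner sampling

Pair nodes are connected under six scenarios (none, all-pair, same-drug,
same-protein, either, neither). Edge weights use the similarity kernel
`exp(−|Δy|/τ)` with τ = 1.0 pKd units by default: the kernel is the simplest
monotone map from label distance to (0, 1], and τ = 1 means a one-log-unit
affinity difference costs a factor e in sampling weight. Weighting applies in
every non-`none` scenario. Neighborhoods are restricted to the training block
of the active fold in all scenarios, so augmentation can never leak validation
or test labels. Self-pairing is excluded.

The index is lazy. Same-entity scenarios materialize their (small) neighbor
lists; `all_pair` and `complement` switch to rejection sampling above 10⁴
candidates — uniform proposal over the training block, rejection of invalid
candidates, acceptance with probability equal to the edge weight — which
samples the exact weight-proportional distribution without ever building an
N² adjacency. If 10⁴ consecutive proposals fail (pathologically small
weights), the sampler falls back to the exact path.

## Mixup

`λ ~ Beta(α, α)` with α = 0.5, drawn independently per sample per epoch.
Mixing happens by default in the pooled-representation space: token matrices
of two pairs have different lengths, and pooling first avoids inventing a
length-reconciliation rule. A `padded_token` mode (zero-pad to the longer
length, mix token-wise) is provided for experimentation. λ ∈ {0, 1} endpoints
are returned exactly (no floating-point residue), so the `none` scenario's
training stream is bit-identical to the unaugmented stream. Mixed samples
replace the clean sample for non-`none` scenarios; isolated nodes pass
through clean.

## Encoder

Character-level tokenization for both SMILES and protein sequences keeps the
full string without truncation. Three embedders share one interface: a
trainable per-character lookup table, a fixed seeded-hash embedder (the
default; deterministic across processes, used throughout the synthetic
benchmark), and a file embedder serving precomputed per-entity token matrices
from an HDF5 archive (the adapter for molecule/protein language-model
embeddings).

Attention-free aggregation projects queries, keys and values per side
(`d_in × d` each, single head), softmax-weights the context tokens per
embedding dimension by `exp(K⁰)`, averages their values, and gates the result
with `σ(Q⁰)` per query token. The exponent is shifted by the per-dimension
maximum of `K⁰` before exponentiation — the softmax is invariant to the shift,
so the output is unchanged while overflow is impossible. Cost is linear in
the context length. The multi-head attention variant is standard scaled
dot-product cross-attention and serves as the quadratic-cost ablation.

Both sides are aggregated cross-wise (drug tokens query protein context and
vice versa), max-pooled per dimension over tokens, and concatenated to a
length-2d pair representation. One cross-aggregation block is used; the depth
is not stacked. The default hidden width is d = 256 with a
[2d → d → d/2 → 1] ReLU head and dropout 0.1; the desk-scale benchmark uses
d = 24 with a [48 → 24 → 1] head (see below).

Residue attribution counts, per residue, the number of embedding dimensions
whose protein-side max-pool lands on it; votes always sum to d. Ties go to
the lowest residue index (determinism), positions are reported 1-based
(biological convention), and k is clamped to the protein length with a
warning.

All forward/backward passes are NumPy with analytic gradients; the test suite
checks every gradient against central finite differences, including the
max-pool routing (up to the measure-zero argmax switches).

## Training

Stage 1 trains one encoder per scenario with MSE on the augmented stream,
mini-batch Adam (defaults: 200 epochs, batch 64, learning rate 10⁻³, early
stopping patience 20 on unmixed validation MSE, best-epoch weights restored).
The scalar output bias is initialized to the training-label mean so the
optimizer fits structure instead of spending its budget on the global offset.
All randomness (init, shuffling, partner draws, λ, dropout) derives from one
seed via split seed sequences; identical configs reproduce identical loss
trajectories.

Stage 2 freezes the members bitwise and extracts, per pair, the element-wise
sum of the six pooled representations concatenated with the six scalar
predictions (summing six scalars into a 2d vector is dimensionally ambiguous,
so embeddings are summed and predictions appended). Features are z-scored
with training-block statistics — embedding sums and label-scale predictions
live on very different scales. The meta MLP shares the member head's layer
plan and is parameterized as a *residual correction on top of the mean member
prediction*: its output layer is zero-initialized, so the untrained meta
equals the plain prediction average, and early stopping on validation MSE can
only move away from that baseline when the correction genuinely helps. The
meta uses decoupled weight decay 10⁻³. This stacking parameterization is the
standard remedy for meta-learners fit on few samples; with abundant data it
reduces to the unconstrained meta-predictor.

## Synthetic data generator

The generator emulates the three properties of real affinity panels that the
method addresses:

- **scarcity** — only a `density` fraction (default 0.4) of the 20 × 15 grid
  is observed;
- **sparsity/skew** — observed labels are left-censored at 5.0 around a
  baseline of 6.0, producing the characteristic floor point mass (~25% of
  labels at default noise);
- **shared-entity correlation** — the clean label is
  `μ + a_d + b_p + 0.7 · u_d·v_p` with per-entity biases (SD 1.0) and
  two-dimensional latent factors, giving a within-shared-entity label
  correlation of ≈ 0.2–0.25. Main effects dominate the interaction
  (≈ 2:1 variance split), mirroring real Kd panels where drug promiscuity and
  target druggability explain more variance than pair-specific selectivity.

Observation noise SD is 0.3 pKd units. Entity strings are deterministic
functions of the latent state: each latent coordinate *and* the entity bias is
quantized into one symbol of the entity alphabet (16 SMILES-like symbols for
drugs, the 20 amino acids for proteins) and emitted as a run, so a
character-level embedder can in principle recover everything except the
quantization residue and the observation noise.

What the generator does **not** emulate: chemically valid SMILES, protein
families or motif structure, position-dependent sequence effects, assay
heterogeneity, and non-random missingness. Passing the synthetic benchmark
therefore shows that the pipeline's machinery (neighbor sampling, mixing,
encoding, stacking) works and that the GBA mechanism helps when its premise
holds — it does not certify performance on real panels.

## Desk-scale benchmark

`mixdta.experiments.run_benefit_experiment` trains the full six-scenario
ensemble and the plain (`none`) backbone on one warm 6:2:2 fold of the default
generator, for five independent replicates, and compares test MSE. Problem
sizes are chosen so one replicate trains in under a minute on one CPU while
leaving enough capacity for the bilinear signal: hidden width d = 24,
[48 → 24 → 1] head, 250 epoch cap, patience 25, batch 16, learning rate
2·10⁻³ (selected on member validation loss). Under these conditions the
ensemble beats the plain backbone in ≥ 4 of 5 replicates, with mean test MSE
reductions of roughly 10–20%.

## Numerical choices and degenerate inputs

- Softmax exponents (AFA keys, MHA scores) are max-shifted; sigmoids use the
  overflow-safe piecewise form.
- Concordance index: only distinct-truth pairs count; tied predictions score
  0.5. The O(n log n) Fenwick path accumulates the same integer counts as the
  O(n²) loop and performs the same final division, so the two agree exactly,
  ties included.
- rm² uses |r² − r0²| under the root (guards rounding-negative arguments);
  r0² is the coefficient of determination of observed regressed on predicted
  through the origin.
- AUPR uses step interpolation (average precision) with `y_true ≥ threshold`
  as the positive class — the threshold is closed.
- Zero-variance inputs: CI and rm² raise; `regression_metrics` returns error
  metrics and `None` for the undefined correlation fields.
- Mixup endpoints return exact copies; max-pool argmax and attribution ties
  break to the lowest index.

## Known limitations

- The built-in embedders carry no pretrained knowledge; on real panels the
  file embedder with language-model token matrices is the intended path, and
  absolute performance with the hashed embedder is not meaningful.
- Training is single-threaded NumPy: suitable for the desk-scale benchmark
  and small panels, not for 100k-pair datasets.
- The meta-predictor's residual parameterization assumes the member
  predictions are on the label scale.
- Cold-start splits hold out one entity type at a time; jointly-blind splits
  are out of scope.
- Statistical comparisons between models (paired tests, bootstrap CIs) are
  not provided.
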