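# mixdta

Drug–target affinity (DTA) regression with **guilt-by-association (GBA) mixup
augmentation**, an **attention-free cross-aggregation (AFA)** twin encoder, and
**multiview meta-prediction** — a tested, model-agnostic NumPy library plus CLI,
exercisable end to end on synthetic data.

## The problem

DTA prediction estimates a continuous binding strength (pKd, KIBA score) for a
small molecule and a protein. Affinity panels are *scarce* (only a small
fraction of the drug × protein grid is measured) and *sparse* (labels pile up
in a narrow band with a hard floor at the lowest measurable affinity, e.g.
pKd = 5 for a 10 µM assay cap). Both properties starve regression models of
signal exactly where predictions matter.

## The method

**Pair-node neighborhoods.** Every observed (drug, target) pair is a node
labeled with its affinity. Six neighborhood *scenarios* connect nodes by shared
components: `none`, `all_pair`, `drug` (same drug), `protein` (same target),
`protein_or_drug`, and `complement` (sharing neither). Edges are weighted by
affinity similarity, `w(i,j) = exp(−|y_i − y_j| / τ)`.

**GBA mixup.** During training, each sample draws a partner from its scenario
neighborhood with probability ∝ `w`, a coefficient `λ ~ Beta(α, α)`, and
contributes the interpolated sample

    x_mix = λ x_i + (1 − λ) x_j,   y_mix = λ y_i + (1 − λ) y_j,

where `x` is the pooled pair representation. Partners always come from the
training block only.

**AFA twin encoder.** Token embeddings of the drug (SMILES characters) and the
protein (residues) cross-attend through attention-free aggregation: per
embedding dimension *m*,

    Y[t, m] = σ(Q⁰[t, m]) · Σ_t′ softmax_m(K⁰)[t′] · V⁰[t′, m],

a sigmoid-gated, key-softmax-weighted value average with cost *linear* in the
context length (a standard multi-head attention aggregator is provided for
ablation). A token-wise max-pool on each side yields the fixed-length pair
representation; a dense head maps it to the affinity. Because each of the `d`
dimensions max-pools over residues, counting per-residue "votes" gives a
data-driven residue attribution.

**Multiview meta-prediction.** One encoder is trained per scenario; their
pooled representations are summed and concatenated with the six scalar
predictions, and a meta MLP (same layer plan as the member heads) learns a
correction on top of the mean member prediction.

**Metrics.** MSE/RMSE/MAE/R², Pearson, Spearman, concordance index (exact
O(n log n) and O(n²) paths), rm² = r²(1 − √|r² − r0²|), and AUPR after
binarizing the truth at a dataset threshold (7 for pKd-style panels).

## Worked example

```python
import numpy as np
from dataclasses import replace
from mixdta import SynthConfig, generate_dataset, make_folds, concordance_index, rm2
from mixdta.experiments import DESK_ENCODER, desk_train_config
from mixdta.training import train_scenario, predict_member
from mixdta.gba import Scenario

ds, _ = generate_dataset(SynthConfig(seed=0))
print(f"dataset: {ds.n_pairs} pairs, {len(ds.drugs)} drugs, {len(ds.proteins)} proteins")
fold = make_folds(ds, mode="warm", n_folds=1, seed=0).folds[0]
member = train_scenario(ds, fold,
                        replace(desk_train_config(0), scenario=Scenario.PROTEIN),
                        DESK_ENCODER)
y = ds.labels()[fold.test]
yhat = predict_member(member.model, ds, fold.test)
print(f"protein-scenario member: test MSE {np.mean((yhat-y)**2):.3f}  "
      f"CI {concordance_index(y, yhat):.3f}  rm2 {rm2(y, yhat):.3f}")
```

prints

```
dataset: 120 pairs, 20 drugs, 15 proteins
protein-scenario member: test MSE 0.778  CI 0.673  rm2 0.178
```

i.e. a single scenario member trained on 72 pairs of the synthetic panel
reaches test MSE 0.778 against a test-label variance of ≈ 0.92 and orders 67%
of test pairs correctly. The full six-scenario ensemble improves on this
(see below).

## Command line

```bash
mixdta simulate --config run.yaml     # synthetic dataset + ground truth
mixdta stats    --config run.yaml     # label concentration statistics
mixdta split    --config run.yaml     # warm / cold-drug / cold-target folds
mixdta train    --config run.yaml     # six scenario members (stage 1)
mixdta meta     --config run.yaml     # meta-predictor (stage 2)
mixdta evaluate --config run.yaml     # per-fold metrics + mean ± sd
mixdta attribute --config run.yaml    # top-k residue votes per test pair
```

One YAML config with a mandatory `seed` drives the whole pipeline; every
artifact embeds the resolved config, so runs reproduce byte for byte.

Real affinity tables are read in two dialects: `generic_csv`
(`drug_id,smiles,protein_id,sequence,label`) and the Therapeutics Data Commons
DTI layout (`Drug_ID,Drug,Target_ID,Target,Y`), with optional FASTA sequence
files and HDF5 archives of precomputed token embeddings (e.g. from molecule or
protein language models). Kd values in nM are harmonized to pKd with a 10 µM
cap (`pkd_transform`), reproducing the 5.00 label floor of Kd-type kinase
panels.

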