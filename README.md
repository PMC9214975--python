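# pankinet

Identification of **pan-kinase-family inhibitors (PKFIs)** — compounds
active against an entire kinase family rather than a single kinase — with
an explainable graph convolutional network (GCN), plus the statistics
needed to connect the model's atom-level attention to classical
functional-group descriptors.

Single-kinase inhibitors often lose efficacy to resistance because the
kinases of one family share catalytic sites and signaling pathways;
compounds that inhibit a whole family are therefore attractive starting
points for drug design. `pankinet` implements the full computational
route from raw bioactivity tables to ranked, atom-annotated chemistry:

1. **PKFI set curation** (`pankinet.pkfi`). Raw compound–kinase
   measurements (IC50 in nM, pKi) are filtered (censored relations `~`,
   `>>` dropped), binarized with strict cutoffs (IC50 < 500 nM active,
   pKi > 6 active), and duplicates merged by an 80%-consistency vote.
   A compound enters family *F*'s set only if it has consensus calls on
   at least max(⌈|F|/2⌉, 2) member kinases; unanimously active compounds
   are positives, unanimously inactive ones negatives.
2. **Graph featurization** (`pankinet.featurize`). Each compound becomes
   an attributed graph (AF, L̃): a 50×28 atom-descriptor matrix (atom-type
   one-hot, bonded hydrogens, hybridization, charges, ring membership,
   chirality, aromaticity, H-bonding; zero-padded to 50 heavy atoms) and
   the modified normalized Laplacian
   L̃ = D̃^(−1/2)(A + I)D̃^(−1/2), with D̃ the degree matrix of A + I.
3. **GCN classifier** (`pankinet.gcn`). Three graph convolutions
   F^l = ReLU(L̃ · F^(l−1) · W^l) with 64, 32 and 16 kernels, global
   average pooling after each layer, and a softmax classifier on the
   concatenated 112-dimensional embedding; trained with ADAM
   (lr 0.001, β₁ 0.9, β₂ 0.999) on cross-entropy for 100 epochs.
4. **Grad-CAM attribution** (`pankinet.gradcam`). Per-kernel weights
   α_k = (1/N) Σ_n ReLU(∂y^c/∂F^l[n,k]) combine with the feature map as
   M^c[n] = Σ_k α_k F^l[n,k] to score every atom's contribution to either
   class; rendered as green (positive) / orange (negative) circles on 2D
   depictions.
5. **Moiety enrichment** (`pankinet.moieties`). Functional-group SMARTS
   fingerprints scored by the continuity-corrected odds ratio
   OR = ((a+ε)(d+ε))/((b+ε)(c+ε)), ε = 0.5, over the positive/negative
   2×2 presence table.
6. **Synthetic benchmark** (`pankinet.synthetic`). A planted-motif
   generator that emulates the real corpus structure (duplicate and
   inconsistent records, variable family coverage, motif-enriched
   positives) with exact, generator-side ground truth.

## Worked example

Train and explain a model on a 200-compound planted-motif benchmark
(100 nitrile-bearing positives, 100 negatives):

```python
from pankinet import (SyntheticConfig, TrainConfig, evaluate,
                      gen_classification_benchmark, split_set, train)
from pankinet.io import PipelineConfig, featurize_set
from pankinet.gradcam import explain
from pankinet.moieties import load_dictionary, rank_descriptors

bench  = gen_classification_benchmark(SyntheticConfig(n_compounds=200, seed=7))
graphs = featurize_set(bench.structures, PipelineConfig())
split  = split_set(bench.pkfi_set, 0.8, seed=7)
params = train(split, graphs, TrainConfig(epochs=100, seed=7))
m = evaluate(params, split.test, graphs)
print(f"ACC {m.acc:.3f}  MCC {m.mcc:.3f}  AUROC {m.auroc:.3f}")
```

prints

```
ACC 1.000  MCC 1.000  AUROC 1.000
```

— the held-out 40 compounds are classified perfectly because the planted
nitrile is a sufficient class signal. Grad-CAM confirms the model uses
it: for test positive `CPD000009` (`N#COc1ccsc1`, motif atoms 0–1) the
positive-class attention ranks atoms 1 and 0 (the nitrile N and C)
highest, with normalized scores 1.000 and 0.905 against ≤ 0.454 for the
rest of the molecule. The enrichment ranking agrees with the construction:

```
rank 1: #1 nitrile (triple-bonded nitrogen)  a=100 c=0  OR=40401.0
rank 2: #29 any aromatic atom               a=81  c=72  OR=1.6
```

The same flow is available from the shell (`pankinet simulate`,
`build-sets`, `featurize`, `train`, `evaluate`, `explain`,
`moiety-stats`, `run-all`), all subcommands accepting `--seed`,
`--config` and `--out`.

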