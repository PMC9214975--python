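# Methods

This note documents the models and procedures implemented in `pankinet`,
the defaults chosen where the underlying method leaves them open, and
what the synthetic benchmark does and does not demonstrate.

## PKFI curation

A pan-kinase-family inhibitor (PKFI) set is built per family from
heterogeneous compound–kinase measurements in four steps.

**Filtering.** Records with relation `~` or `>>` are unusable
(approximate or strongly censored) and are dropped. ChEMBL-style
provenance attributes (assay type, target type, confidence score), when
present on a record, must read `Binding` / `SINGLE PROTEIN` / `9`;
records without these attributes pass, so minimal tables (and the
synthetic generator's output) need not carry them. A separate
profiling-style cleaning pass (`clean_records`) drops records with
missing identifiers or structures and removes compounds whose canonical
structure key collides across different compound ids.

**Binarization.** IC50 < 500 nM or pKi > 6 is active. Both cutoffs are
strict: a measurement at exactly 500 nM or pKi 6.0 is inactive.

**Duplicate voting.** All calls for one (compound, kinase) pair are
merged when the majority label reaches at least 80% of the calls; the
comparison is done in integer arithmetic (`5·n ≥ 4·total`) so a group at
exactly 0.80 is kept. Pairs below the threshold are excluded entirely.
The inclusive reading of the threshold is a documented choice; the
exclusive alternative changes only groups whose majority fraction is
exactly 4/5.

**Family labeling.** A compound is eligible for family *F* when its
consensus calls cover at least `max(ceil(|F|/2), 2)` member kinases —
"half the family" rounds up for odd sizes, since a compound tested on
fewer than half cannot satisfy "no less than half", and two kinases is
an absolute floor. Eligible compounds are labeled by unanimity: all
active → positive, all inactive → negative, otherwise *mixed* and
excluded. Positives, negatives, mixed and ineligible compounds partition
the input compound set. The positive class everywhere in the package is
the pan-family **active** class; internally the classifier indexes
active as class 0.

Compounds exceeding the featurizer's 50-heavy-atom cap are dropped from
the set at build time with a logged warning, so every emitted set is
featurizable downstream.

Train/test splits are stratified by class (80:20 by default) and
deterministic in the seed.

## Graph featurization

Each compound is an attributed graph `(AF, L̃)` over its heavy atoms
(hydrogens implicit), in RDKit canonical atom order (fixed by a
canonical-SMILES round trip) so atom indices are reproducible and align
with SMARTS match indices.

`AF` is 50×28. Per atom, in order: atom-type one-hot over
C, N, O, S, F, P, Cl, Br, I, other (10); bonded-hydrogen count (1);
hybridization one-hot over sp, sp², sp³, other (4; sp³d, sp³d² and
unhybridized fall in "other"); formal charge (1); Gasteiger partial
charge (1; non-finite values are replaced by 0 with a warning); radical
electrons (1); ring-membership bits for ring sizes 3–8 (6); chirality
(assigned or potential tetrahedral stereocenter), aromaticity (RDKit
default aromaticity model), H-bond donor and H-bond acceptor (4). The
donor/acceptor SMARTS definitions ship in
`pankinet/data/hbond_smarts.tsv` and are the conventional
Lipinski-style patterns; the partial-charge scheme and aromaticity model
are implementation choices documented here, as no single standard is
mandated by the descriptor list itself.

`L̃ = D̃^(−1/2)(A + I)D̃^(−1/2)` where `A` is the adjacency matrix and
`D̃` the diagonal degree matrix of `A + I`. By default `A` carries bond
orders (single 1, double 2, triple 3, aromatic 1.5), reflecting a
topology encoding of "connections and bond order"; a binary mode is a
config switch (`adjacency_mode`), since the Laplacian construction
itself is indifferent to the weighting. An isolated atom has degree 1
and L̃ entry exactly 1. Both `AF` and `L̃` are zero-padded to the fixed
50-atom dimension; molecules above 50 heavy atoms are rejected. Salt
stripping keeps the largest covalent fragment.

## GCN classifier

Three graph convolutions `F^l = act(L̃ · F^(l−1) · W^l)` with kernel
widths 64, 32, 16 and `F⁰ = AF`. Because padded rows of `L̃` are zero,
padded feature-map rows remain zero through every layer. Choices where
the architecture description is silent:

* **Activation**: ReLU after each convolution (keeps feature maps
  nonnegative, which in turn keeps Grad-CAM maps nonnegative); a linear
  option is retained in the config.
* **Pooling divisor**: global average pooling divides by the fixed
  padded dimension N = 50, so a padded and an unpadded forward pass
  agree up to this constant; a masked mean (divide by the real atom
  count) is available.
* **Classifier**: one affine map 112 → 2 with bias and softmax — no
  hidden dense layer.
* **Initialization**: seeded Glorot (variance-scaling) uniform.
* **Batch size**: 32. No early stopping, weight decay or dropout.
* **Class imbalance** is *not* corrected by default (an optional
  class-weight flag exists); low MCC on imbalanced sets is an expected
  and informative outcome, not a bug.

Training is ADAM (lr 0.001, β₁ 0.9, β₂ 0.999) on cross-entropy for 100
epochs. Forward, backward and the optimizer are written directly in
NumPy: the model is ~7k parameters on 50×50 graphs, a regime where a
framework adds no capability, and the explicit backward pass is exactly
the machinery Grad-CAM needs. All randomness flows from one integer
seed; repeated runs are bit-identical.

Evaluation reports ACC, MCC, AUROC (scikit-learn implementations, tested
against closed-form oracles) and the 2×2 confusion table. A single-class
test set leaves AUROC NaN with an explanatory flag.

## Grad-CAM

For class *c* and layer *l*, per-kernel weights are the atom-averaged
ReLU-clipped exact gradients of the softmax class probability:
`α_k = (1/N) Σ_n ReLU(∂y^c/∂F^l[n,k])` with N = 50 (the padded
dimension — a constant that rescales but never reorders attention). The
attention map is `M^c[n] = Σ_k α_k F^l[n,k]`, left unclipped: the ReLU
is applied to the gradients only, not to the final map (this differs
from the common CNN Grad-CAM variant that clips the combined map). The
gradients are exact partial derivatives accounting for both the layer's
pooled contribution to the classifier and its influence on deeper
layers; they are validated against central finite differences.

The default explanation layer is the third (last) convolution, whose
receptive field spans three bonds. For display, scores are normalized
per compound and class to a maximum of 1 (raw scores are preserved in
the JSON output); atoms below 0.05 normalized are not drawn, circle
radius is linear in the normalized score, green marks the positive and
orange the negative class.

## Moiety enrichment

Compounds are fingerprinted against a SMARTS dictionary; bit *i* is set
when pattern *i* matches at least once. The shipped default dictionary
has 30 common functional-group patterns (nitrile, amines, sulfonamide,
halogens, aromatic heteroatoms, …) — a compact stand-in for the ~204
descriptors of full functional-group perception programs; a complete
external dictionary can be loaded from TSV (`id`, `name`, `smarts`),
validated at load time. Enrichment uses the ε-corrected odds ratio with
ε = 0.5 added to **all four** cells of the 2×2 table (the symmetric
Haldane–Anscombe convention; adding ε only to zero cells is the main
alternative and changes no ranking in the all-nonzero case). The
orientation is enrichment **in positives** (`a` = positives carrying the
moiety). Descriptors are ranked by descending odds ratio, ties broken by
id; no minimum-support filter is applied by default (a flag exists), so
high-variance ratios from rare descriptors are visible rather than
hidden.

`attention_overlap` reports the ratio of mean Grad-CAM attention on a
descriptor's matched atoms to the mean over all real atoms — the
numeric bridge between the model's attention and the descriptor table.

## Synthetic benchmark

The generator emulates the *statistical shape* of a curated kinase
bioactivity corpus, not its chemistry. Compounds are one of ~20
drug-like ring scaffolds with 0–2 small decorations; designated
positives carry a grafted family motif (nitrile by default — chosen as a
compact, chemically unambiguous environment of the kind highlighted in
pan-family inhibitors; sulfonamide and trifluoromethyl for further
families), negatives a decoy substituent, making the motif the only
systematic class difference. Activity values are drawn log-uniformly
inside/outside the cutoffs so binarization is exercised near and far
from the boundary; duplicates (20% of pairs by default) are injected
with a 10% chance of being made inconsistent enough to fail the 80%
vote; 5% of pairs gain an extra censored-relation record; per-compound
family coverage is uniform from one kinase to the whole family. The
generator computes the expected consensus for every pair by direct
fraction arithmetic as it emits records — an oracle independent of the
curation code, which makes zero-error recovery a meaningful end-to-end
test. The default classification benchmark is 400 positives + 400
negatives with motif prevalence 1.0 and no label noise.

**What passing these tests shows**: the curation rules are implemented
exactly; the network can learn a genuine substructure signal from graph
input alone and its Grad-CAM maps localize that signal; the enrichment
statistic ranks a truly class-separating moiety first. **What it does
not show**: performance on real kinase data, where the signal is a
diffuse combination of many interacting environments, classes overlap,
and structure diversity is far higher. The published per-family
accuracies are therefore *not* a target of the synthetic benchmark; the
package instead recomputes the published summary statistics (set
balances and metric means) directly from the reported per-family counts
in `pankinet.reference`.

Problem sizes used by the test suite and the acceptance script — the
400+400 benchmark over three seeds, 100 epochs, and 150–300-compound
curation tables — keep a full run in the one-minute range on a single
CPU while leaving every statistical check comfortably powered.

## Numerical details and edge cases

* Softmax is computed with max-subtraction; non-finite intermediates
  raise rather than propagate.
* Voting uses exact integer comparison, never floating-point fractions.
* `split_set` requires ≥ 2 compounds per class; empty test sets and
  single-class training sets raise.
* Model checkpoints (`.npz`) embed the architecture and a SHA-256
  content checksum, verified on load; architecture mismatches and
  tampering raise.
* Every pipeline artifact records the seed and a hash of the full
  configuration; rerunning with the same seed reproduces the manifest
  byte for byte.

## Known limitations

* Gasteiger charges fail on some exotic elements; affected atoms fall
  back to 0 with a warning.
* The bond-order-weighted adjacency treats aromatic bonds uniformly as
  1.5; Kekulé-structure alternation is deliberately not represented.
* The shipped moiety dictionary is deliberately small; enrichment
  results are only as expressive as the dictionary supplied.
* No 3D information: conformers, protonation states and tautomers are
  out of scope.
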