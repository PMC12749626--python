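# Methods

This note documents the models and procedures implemented in
`reactionfunnel`, the choices made where the design was genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Problem setting

Minisci-type C-H alkylation couples an electron-poor N-heteroarene with an
alkyl radical generated by silver/persulfate-mediated oxidative
decarboxylation of a carboxylic acid. In a hit-to-lead campaign this is an
attractive late-stage diversification: a single heteroaromatic hit crossed
with a shelf of cheap sp3-rich acids yields a large virtual library, and
the practical bottleneck becomes knowing *which* of those couplings will
actually work. The package implements the computational side of such a
campaign: learn a reaction-outcome model from plate-based screening data,
enumerate the virtual library, and pass it through a staged
potency / synthesizability / property funnel.

## Reaction records (SURF dialect)

Reactions are exchanged as tab-separated tables, one row per experiment:
reactant structures as SMILES, categorical conditions (catalyst, additive,
oxidant/reagent, solvent, atmosphere), process variables (temperature in
degC, time in h, concentration in mol/L, scale in mol), and mono-/di-
alkylation yields. Yields are percentages on disk and fractions in [0, 1]
in memory. The di-alkylation column is optional (default 0), and
`mono + di` is clipped at 1 rather than rejected because LC-MS area
percentages can slightly oversum. A reaction is *positive* when its total
yield is at least 5%, the typical LC-MS detection-and-usefulness threshold
for plate screens; the boundary is inclusive everywhere.

## Molecular graphs

Molecules are explicit-hydrogen graphs. Each atom carries a 20-bit one-hot
vector: 12 element types (H, C, N, O, F, P, S, Cl, Br, I, Si, Se), ring
membership, aromaticity, and hybridization (SP3, SP2, SP, S). Elements
outside the alphabet raise immediately rather than map to a catch-all.
Edges are covalent bonds in both 2D and 3D mode; 3D mode decorates the
*same* bond edges with inter-atomic distances rather than densifying the
graph, which is the most literal reading of a neighborhood-sum update.
A fully connected 3D edge set was considered and not implemented; on the
small azines and acids this model targets, bond-graph message passing with
three layers already propagates information across the whole molecule.

Conformers are embedded with ETKDGv3 at a caller-supplied seed and
UFF-minimized; ten conformers per molecule by default. Embedding failures
are retried with derived seeds up to 5 times before an error that names
the structure. Distances enter the network through a sine/cosine Fourier
basis with K=16 angular frequencies geometrically spaced so the
half-periods pi/f cover 0.5-12 Angstrom — bond lengths up to through-space
contacts. K and the range are configurable.

## Reaction conditions

Categorical conditions are concatenated per-category one-hots over a
vocabulary built from the training data in first-appearance order. With the
condition inventory of the emulated campaign (4 reagents, 4 solvents,
11 catalysts, 4 additives, 2 atmospheres) the vector has 25 slots, 5 of
them set. Unknown labels raise by default; a per-category UNK level can be
enabled explicitly. The default is strict because silently collapsing a
novel catalyst into a shared bucket corrupts extrapolation experiments.

## The reaction model (GTNN)

Two message-passing towers encode the arene and the acid; only the initial
atom-embedding MLP is shared, so the model can treat the same fragment
differently in the two roles. Each tower runs `n_layers` updates

    h_i <- phi( h_i, sum_{j in N(i)} psi(h_i, h_j [, r_ij]) )

with psi and phi two-layer MLPs (SiLU), the empty neighbor sum defined as
the zero vector, and r_ij the Fourier distance features in 3D mode. The
per-layer outputs are concatenated, mapped by an MLP, and pooled with a
graph multiset transformer: multi-head attention from learned seed vectors
over the atom set, self-attention among the seeds, then single-seed
pooling. Pooled vectors (one per tower) are concatenated with a learned
embedding of the condition one-hot and mapped through an output MLP; a
logistic map squashes the scalar into [0, 1].

Default architecture: hidden width 128, embedding width 64, first
post-pooling layer 256, three message-passing layers, 4 pooling seeds.
The pooling uses 2 attention heads by default with 4 supported — the two
published descriptions of this architecture family disagree on the head
count, so both are exposed and neither is asserted as canonical. With the
default widths and the 25-slot condition vocabulary the model has
1,648,257 trainable parameters (about two million).

Both prediction targets — continuous total yield and binarized outcome —
are treated as regression with MSE loss. Training uses Adam at 1e-4, batch
16, a step learning-rate decay of 0.5 every 100 epochs (a decay-once
variant is selectable), and an exponential moving average of the weights
with retention 0.9 that is used for validation and test evaluation. The
smoothing is applied to *weights* rather than to logged metrics; that is
the common meaning of an exponential smoothing factor in this training
idiom, and it is toggleable. Early stopping keeps the parameters of the
epoch with the lowest validation MAE over the full schedule (1000 epochs at
full scale). The validation set is a seeded random 10% of the training
partition, since cross-validation folds define only train/test membership.
In 3D mode one conformer per molecule is drawn uniformly at each training
step; test predictions average the forward passes over the full conformer
ensemble.

The network and its training loop run on a compact NumPy reverse-mode
autodiff engine (`reactionfunnel.nn`) written for this package: broadcast
elementwise ops, batched matmuls, row gather / segment scatter with
precomputed sparse incidence matrices, and dense/segment softmax. Engine
gradients are verified against central finite differences in the test
suite. Float64 is the default (exactness for the oracle tests); training
presets use float32 for speed.

### Reduced configuration

Full-scale training of the default model is a GPU-scale job. Experiments
in this repository use `GTNNConfig.reduced()`: hidden width 32, embedding
32, two message-passing layers, 2 pooling seeds, batch 128, learning rate
1e-3 (decay 0.5 at epoch 100), float32, 200 epochs. An optional patience
parameter stops training after a given number of epochs without a
validation improvement; the comparison runs across split regimes use
patience 30 so that six trainings fit in minutes on one CPU, while the
headline baseline-comparison run uses the full 200-epoch schedule.
Problem sizes in the shipped experiments: 2,000 reactions, 4-fold splits,
fold 0.

## Extrapolation splits

Four regimes control train/test component sharing: `0D` shuffles
reactions; `1DN`/`1DA` partition the arene/acid entity sets so every test
entity is unseen; `2D` partitions both independently (k aligned pairings,
not k^2 cells) and keeps a reaction only if both components are held-in
(train) or both held-out (test) — reactions with exactly one novel
component are dropped from that fold entirely, keeping the training set
free of held-out entities. Entity identity is the canonical SMILES, so a
duplicate structure under a second ID cannot leak. Uneven folds
distribute the remainder round-robin after a seeded shuffle. On a fully
crossed 6x6 grid with k=2 this yields exactly 1/4 test cells and 1/2
dropped cells per fold.

## Virtual enumeration

The in-silico Minisci product is the scaffold with one aromatic C-H
replaced by the acid's decarboxylated alkyl fragment (delete the carboxyl
carbon and both oxygens, bond the alpha carbon to the ring position).
Every product must sanitize and satisfy heavy-atom bookkeeping
(product = scaffold + acid - 3 heavy atoms); formic acid is rejected.
Site resolution prefers positions *ortho* to a ring nitrogen, then
*para*, with remaining ties broken by canonical atom rank and then atom
index — radical addition to azines favors the positions alpha and gamma to
nitrogen, and the ortho preference makes the single-site choice
chemically sensible and deterministic. Single-site mode (one product per
scaffold x acid pair) is the default so library counts are exactly
|scaffolds| x |acids|; a multi-site mode expands all candidate sites, and
canonical de-duplication is available but off by default. Acid eligibility
follows the campaign's sourcing filter: molecular weight strictly below
230 g/mol and sp3 carbon fraction at least 0.5 (the sp3 cut is this
package's default where only "high" was specified).

## The funnel

Score cards carry predicted potency (pIC50), predicted yield, and four
ADME endpoints: LogD, LYSA solubility (ug/mL), P-gp efflux ratio, PAMPA
permeability (1e-6 cm/s). Stages are inclusive thresholds: pIC50 >= 6,
then yield >= 5%, then pIC50 >= 8. ADME windows *annotate* stage-3
survivors rather than eliminate them by default — hard sequential property
cutoffs propagate model error, so the final property trade-off belongs to
ranking and human judgment; a strict mode adds a fourth elimination stage
for users who want it. Ranking is descending pIC50, then descending yield,
then id, so output order is deterministic. The manual selection step that
follows stage 3 in a real campaign (availability, chemist judgment) is
deliberately not automated.

External scoring models (structure-based potency scoring, proprietary
ADME models) are consumed only through a named scorer registry mapping a
product SMILES to an endpoint value. The shipped `potency:synthetic` and
`adme:toy-*` scorers are deterministic descriptor-plus-hash heuristics for
testing the machinery; they reproduce no published model. Yield scoring
wraps a trained model checkpoint; because it needs the two reactant
structures and plate conditions rather than the product, it enters the
pipeline as a dedicated scoring path (best predicted yield over the
catalyst x additive plate) rather than through the product-SMILES registry.

## Unit conversions

pIC50 = -log10(IC50 in mol/L) = 9 - log10(IC50 in nM); LipE =
pIC50 - cLogP. Both are exact arithmetic, tested against reference potency
pairs at their reported precision.

## Synthetic data generator

The generator emulates the structure of a plate-based alkylation campaign:
80 azine scaffolds x 59 sp3-rich acids by default, each screened pair
occupying a full 24-well condition plate (six silver salts x four additive
levels: TFA, H2SO4, HNO3, none; single persulfate oxidant, MeCN/H2O 3:2,
ambient atmosphere, 80 degC, 18 h, 0.016 M, 0.8 umol), with 12% of the
pair grid screened. Scaffolds come from a core-plus-substituent grammar
(pyridine, pyrimidine, pyrazine, quinoline, isoquinoline, imidazopyridine
cores); acids from alkyl/cycloalkyl skeletons with alpha decorations, all
below 230 g/mol.

The latent yield is additive with one interaction:

    y = clip01( base + a(arene) + b(acid) + c(catalyst, additive) + eps )

with a ~ N(0, 0.12), b ~ N(0, 0.10), c ~ N(0, 0.08), eps ~ N(0, 0.05) by
default. The base offset is set from the sampled rows so that the >=5%
positive fraction hits the target rate (0.30) exactly at the quantile;
a fixed base can be supplied instead (used by the noiseless
parameter-recovery test, which checks that least squares on entity
indicators recovers the planted effects). Entity effects attach to
molecular identity, which is what makes entity-held-out splits genuinely
harder: no model can know a(arene) for an unseen arene, so the 0D-vs-2D
error ordering is a structural property of the generator, not a tuned
outcome. Total yield is split into mono/di components with di <= mono and
di present in ~25% of reactions.

What passing on this generator shows: the model can extract
structure-identity and condition-interaction signal from realistic-shaped
plate data, and the split machinery measures extrapolation honestly. What
it does not show: chemical generalization. The planted effects are i.i.d.
per entity with no structure-activity relationship, so test error on novel
entities bottoms out at the entity-effect variance; real Minisci data has
transferable substituent electronics that a graph model can partially
learn. The generator also ignores regiochemistry, mechanism, and
condition-substrate interactions beyond the catalyst x additive term.

## Numerical and degenerate-input conventions

- Empty neighbor sums are zero vectors; pooling an empty graph raises.
- Pearson correlation raises on constant input instead of returning NaN.
- Precision with zero predicted positives is reported as undefined
  (`None`), never 0.
- Cross-fold spread is the sample (n-1) standard deviation.
- Thresholds are inclusive (>=) throughout; the acid weight cut is the one
  strict inequality (< 230 g/mol), matching its "lower than" definition.
- Seeded runs are bitwise reproducible; the pipeline derives per-stage
  substream seeds from the global seed by hashing stage names.

## Known limitations

- The NumPy engine trains small models in minutes but is not a route to
  the full-width model on the full 13,490-reaction dataset; that remains a
  GPU-scale job outside this repository's scope.
- The 3D mode is exercised for correctness (invariances, conformer
  averaging) but the shipped experiments train in 2D mode.
- Toy scorers stand in for external potency/ADME models; funnel *counts*
  on synthetic cards are meaningful only against their stated
  distributions.
- The deposited campaign dataset is consumable through `read_surf` with a
  column-mapping config, but no network access is assumed anywhere in the
  tests or scripts.
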