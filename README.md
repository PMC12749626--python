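# reactionfunnel

Reaction-outcome prediction and multi-dimensional candidate filtering for
Minisci-type C-H alkylation campaigns in early drug discovery.

Minisci chemistry couples an electron-poor N-heteroarene (pyridines,
pyrimidines, quinolines, ...) with an alkyl radical generated by
silver/persulfate decarboxylation of a carboxylic acid. Crossing a set of
heteroaromatic hit molecules with a shelf of cheap sp3-rich acids defines a
large virtual library in one step — but most of those couplings fail at the
bench. This package implements the computational machinery that turns such
a campaign into a ranked, synthetically grounded candidate list:

- **SURF-style reaction tables** (`surf`): tab-separated records carrying
  reactant SMILES, categorical plate conditions, and mono-/di-alkylation
  yields; a reaction is *positive* when total yield ≥ 5%.
- **Graph featurization** (`chemgraph`): explicit-hydrogen molecular graphs
  with 20-bit one-hot atom features, optional ETKDG/UFF conformer
  ensembles, Fourier sine/cosine distance encodings, and one-hot condition
  vectors.
- **A graph transformer reaction model** (`gtnn`): twin message-passing
  towers over the arene and acid graphs,

      h_i ← φ( h_i, Σ_{j∈N(i)} ψ(h_i, h_j [, r_ij]) ),

  graph-multiset-transformer attention pooling, a learned condition
  embedding, and a logistic output head predicting yield in [0, 1]
  (≈2 M parameters at full width). Implemented, with its Adam/EMA
  training loop, on a compact NumPy reverse-mode autodiff engine (`nn`).
- **Extrapolation splits** (`datasplit`): 0D (random), 1DN (unseen
  arenes), 1DA (unseen acids) and 2D (both unseen) k-fold regimes.
- **Virtual enumeration** (`enumerator`): scaffold + acid − CO₂ template
  products at ortho/para azine positions, with strict heavy-atom
  bookkeeping.
- **The funnel** (`funnel`): staged inclusive thresholds — pIC50 ≥ 6,
  predicted yield ≥ 5%, pIC50 ≥ 8 — with ADME endpoints (LogD, LYSA,
  P-gp, PAMPA) annotating rather than eliminating by default, plus
  pIC50 ↔ IC50 and LipE = pIC50 − cLogP arithmetic.
- **A synthetic campaign generator** (`synthdata`): azine × acid ×
  24-well-plate datasets with a planted, recoverable yield surface
  calibrated to a 30% positive rate, so everything above is testable
  offline.

## Worked example

Generate a synthetic screening campaign, summarize it, and build a
double-extrapolation split:

```bash
$ funnel synth --seed 7 --n-reactions 480 --out demo.surf
wrote demo.surf
$ funnel surf summarize demo.surf
records:               480
positive rate (>=5%):  30.0%
arenes x acids:        20 x 17
screened combinations: 20
$ funnel split --surf demo.surf --mode 2d --k 4 --seed 1 --out splits.json
wrote splits.json
```

The 480 records are 20 scaffold×acid combinations, each screened across
the full 24-well catalyst×additive plate; 30.0% of wells cleared the 5%
LC-MS yield threshold, matching the generator's calibrated positive rate.
The split file holds four folds in which every test reaction's arene *and*
acid are absent from that fold's training records.

Potency arithmetic used in candidate ranking:

```python
>>> from reactionfunnel import pic50_from_ic50, lipe
>>> pic50_from_ic50(0.025)   # 25 pM inhibitor
10.60
>>> lipe(10.60, 3.72)        # pIC50 - cLogP
6.88
```

`funnel run --seed 5 --out-dir runs/demo` executes the whole cascade on
synthetic data — generate, split, train a reduced model, evaluate,
enumerate a library, score it and apply the funnel — writing a manifest
with per-stage artifact hashes. `funnel train / predict / evaluate /
enumerate` expose the stages individually for real SURF files, and
`funnel apply --library library.tsv --out result.json` scores a
pre-enumerated library with the registered scorer plug-ins and reports
per-stage survivor counts plus a ranked TSV.

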