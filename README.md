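# lsfgdl — geometric deep learning for late-stage C–H borylation

`lsfgdl` predicts the outcome of iridium-catalysed C–H borylation
reactions — the workhorse of late-stage functionalization in medicinal
chemistry — directly from reaction records.  Given a substrate structure
(SMILES) and categorical reaction conditions (ligand, solvent, and for
literature data also reagent and catalyst), it predicts

* **binary reaction outcome** — will any mono-/di-borylated product form
  (success = conversion ≥ 1%),
* **reaction yield** — continuous conversion in [0, 100]%,
* **regioselectivity** — which C–H carbon carries the pinacol-boronate
  (Bpin) group, as per-atom classification over the non-quaternary
  carbons.

Reactions are read and written in SURF (simple user-friendly reaction
format), a flat tab-separated one-row-per-reaction text format.

## Models

All graph networks share a three-layer E(3)-invariant message-passing
trunk over explicit-hydrogen molecular graphs,

```
h_i^{l+1} = φ( h_i^l , Σ_{j∈N(i)} ψ(h_i^l, h_j^l [, r_ij]) )
```

where the distance features `r_ij` (sine/cosine Fourier encodings of
interatomic distances) enter only for 3D graphs, whose edges connect all
atom pairs within 4 Å of a conformer.  Four graph variants — 2D, 3D and
their partial-charge-augmented twins 2DQM, 3DQM — quantify how much
steric (3D) and electronic (QM) information helps.  On top of the trunk:

* **GNN** — sum pooling + condition embedding → reaction output;
* **GTNN** — graph-multiset-transformer pooling (four attention heads,
  `Attn(Q,K,V) = QKᵀV` with learned per-head queries and per-head
  key/value message-passing blocks);
* **aGNN** — no pooling; per-atom sigmoid scores for regioselectivity;
* **ECFP4NN** — baseline from a 256-bit ECFP4 fingerprint and embedded
  ligand/solvent conditions.

Predictions on 3D variants average a ten-conformer ensemble
(distance-geometry embedding + UFF minimization, seeded) and report
mean ± standard deviation.  The networks and their training loop (Adam,
MSE loss, step learning-rate decay, early stopping on smoothed validation
MAE) run on a small NumPy reverse-mode autodiff engine contained in the
package — no deep-learning framework required.

A seeded synthetic-data module generates complete borylation campaigns
(substituted heteroaromatic substrates, 6 ligands × 4 solvents plate
conditions, steric/electronic ground-truth regiochemistry, noisy yields)
so the entire pipeline is testable end to end; see `docs/methods.md`.

## Worked example

```python
from lsfgdl import BorylationModel, ModelConfig, TrainConfig
from lsfgdl.synthetic import SyntheticSpec, make_dataset

records, truth = make_dataset(SyntheticSpec(n_substrates=12, seed=7))
model = BorylationModel(records, config=ModelConfig(
    architecture="GNN", graph_variant="2D", task="yield",
    hidden_dim=32, embed_dim=16, post_pool_dim=32, mlp_hidden=32))
res = model.fit(TrainConfig(learning_rate=1e-3, max_epochs=15, seed=0))
print(res.summary())
```

prints

```
Borylation model results
==========================================================
architecture:      GNN2D
task:              yield
trainable params:  37,249
n train/val/test:  184/32/72
best epoch:        15 of 15
seed:              0
----------------------------------------------------------
pearson_r:            0.658
mae_percent:          7.463
n:                    72
==========================================================
```

The 12 synthetic substrates × 24 plate conditions give 288 reactions; one
random fold (72 reactions) is held out and the model reaches a test-set
mean absolute error of ~7.5 yield points (the data carry 5% Gaussian
yield noise) with a Pearson r of 0.66 after a deliberately short 15-epoch
fit at toy dimensions.  `res.predict(new_records)` returns ensemble mean
and std per reaction; `res.plot_history()` shows the training curves.

The same workflow is available from the shell:

```bash
lsfgdl synth --n-substrates 12 --seed 7 --out demo.surf
lsfgdl surf validate demo.surf
lsfgdl surf stats demo.surf             # condition cardinalities, success rates
lsfgdl train --surf demo.surf --task yield --architecture GNN --variant 2D \
             --seed 0 --out-dir run/
lsfgdl predict --model run/model.npz --surf demo.surf --out predictions.surf
```

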