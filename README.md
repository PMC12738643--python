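# hdti — hybrid graph-network regression of drug potency

`hdti` predicts the potency of small-molecule inhibitors (pIC50 =
−log10 IC50) directly from their SMILES strings. Each molecule is parsed
into a featurized graph — atoms as nodes with physicochemical
descriptors, bonds as symmetric directed edge pairs with bond-order
codes — and fed to a hybrid graph neural network that stacks graph
convolutions (GCN) and graph attention layers (GATv2):

- an initial graph convolution mapping the raw atom features to a
  64-dimensional embedding,
- five hidden layers (two GCN, then three GATv2) with ReLU,
- a dual global readout `Concat(GMP(H), GAP(H))` — per-graph feature-wise
  max and mean pooling, giving a 128-wide graph vector,
- a single linear output head.

The GCN propagation is the mean-aggregation form with a learnable
self-loop weight, `h_v' = f(Wᵀ · mean_{u∈N(v)} h_u + Bᵀ h_v)`; the
attention layers use GATv2 scoring,
`e_{u→v} = aᵀ LeakyReLU(W h_u + W h_v)` with a per-destination softmax
(self-loops included). Layers, backpropagation and the Adam optimizer
are implemented from first principles in NumPy and verified against
dense/loop brute-force oracles and numerical gradients.

The package is aimed at cheminformatics practitioners who want a small,
fully inspectable graph-regression stack: every message-passing step,
attention coefficient and gradient is plain NumPy, and the learned
attention weights can be exported per bond for interpretation.

## Worked example

```python
import numpy as np
import hdti

# synthetic activity table with a known structure-activity function
cfg = hdti.SyntheticSARConfig(n_molecules=300, noise_sd=0.0, seed=7)
smiles = hdti.generate_molecules(300, seed=7)
graphs = [hdti.smiles_to_graph(s) for s in smiles]
y = np.array([hdti.ground_truth_pic50(g, cfg) for g in graphs])

folds = hdti.kfold_split(300, k=5, seed=42)
train_idx, val_idx = folds.fold_indices(0)

est = hdti.HybridGraphRegressor(epochs=300, learning_rate=0.005,
                                batch_size=64, random_state=0)
est.fit([graphs[i] for i in train_idx], y[train_idx])
pred = est.predict([graphs[i] for i in val_idx])
print(hdti.compute_metrics(y[val_idx], pred).as_dict())
```

Output (held-out fold, 60 molecules):

```
{'mae': 0.1563..., 'rmse': 0.1873..., 'r2': 0.9850..., 'ci': 0.9656..., 'n': 60}
```

R² ≈ 0.99 means the network recovered almost all of the planted
structure–activity signal from the molecular graphs alone; the
concordance index ≈ 0.97 says it ranks unseen molecules by potency
almost perfectly.

The same flow is available from the shell:

```bash
hdti simulate --n 300 --noise 0.1 --seed 7 --out synth.csv
hdti featurize --input synth.csv --out graphs.npz
hdti crossval --data graphs.npz --k 5 --epochs 300 --report cv.json
hdti explain --model model.npz --smiles "CCOc1ccccc1" --out mol.graphml
```

`hdti explain` writes a GraphML/DOT graph whose per-bond `weight`
attributes are the min–max-normalized attention coefficients of the last
GATv2 layer — ready for edge-colored rendering in any graph tool.

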