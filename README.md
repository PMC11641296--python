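# hydrobind

Water-network-aware graph transformer for protein–ligand binding-affinity
regression.

`hydrobind` converts a protein–ligand complex plus a set of interfacial water
sites into attributed graphs and regresses binding affinity (pKd) with a
graph transformer whose attention is biased by three structural encodings:
node degree (centrality), shortest-path hop distance (spatial), and edge
features along shortest paths (edge encoding). Two graph views of the same
complex — built from two different water-site sources — pass through the
encoder and are pooled into a single affinity prediction.

## Components

| module                  | purpose                                                                 |
|-------------------------|-------------------------------------------------------------------------|
| `structures_io`         | PDB/Mol2/SDF reading, residue-template chemistry, pocket extraction     |
| `hydration`             | water-site pipelines: probe-grid + weighted mean-shift clustering, density-peak extraction from volumetric grids, contact filtering, site matching |
| `volumetric`            | minimal OpenDX grid reader/writer                                       |
| `featurize`             | 58-dim node features (residue / protein-atom-type / element one-hots + invariant scalars), typed distance edges |
| `graph`                 | graph assembly (`G_A` waterless, `G_B`/`G_C` with waters), edge rules with a 6 Å base cutoff and a configurable water threshold `T` |
| `model`                 | graph transformer (numpy + built-in reverse-mode autodiff), dual-branch forward, virtual-node readout, checkpointing |
| `train_eval`            | Adam/MSE training loop, Pearson/RMSE metrics, ΔG↔Kd conversion, splits, ablation harness |
| `fixtures`              | synthetic complex generator with a planted water-bridge affinity law    |

The node feature layout (58 slots) and all structural conventions are
documented in `src/hydrobind/featurize.py`.

## CLI

```bash
hydrobind simulate --n 50 --seed 0 --out data/            # synthetic dataset
hydrobind hydrate --protein p.pdb --ligand l.mol2 \
                  --mode hydramap --out waters.pdb        # water prediction
hydrobind featurize --protein p.pdb --ligand l.mol2 \
                    --variant B --edge-threshold 6 --out graph.json
hydrobind train --dataset data/ --epochs 30 --checkpoint model.npz
hydrobind predict --checkpoint model.npz --protein p.pdb --ligand l.mol2
hydrobind evaluate --pred pred.txt --truth data/INDEX_synthetic.data
```

## Notes on design readings

* The probe scorer of the grid-clustering water pipeline is pluggable; the
  default is a documented surrogate (Gaussian attractions on polar protein
  atoms), not a knowledge-based statistical potential.
* The single "coordinates" slot of the node features holds the
  rigid-motion-invariant distance to the pocket centroid; raw coordinates
  enter the model only through pairwise distances.
* The edge-path attention bias averages over *all* shortest paths between a
  node pair, which makes predictions exactly permutation invariant; the
  alternative normalisation by the global edge count is available via
  `ModelConfig(edge_bias_mode="global_n")`.
* "Softmax regression" is implemented as softmax-weighted channel pooling
  over the concatenated graph embeddings followed by a linear head.
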