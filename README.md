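# trajnet

Trajectory-analysis toolkit for coarse molecular ensembles: least-squares
superposition and fluctuation statistics (RMSD/RMSF/B-factor conversion),
dynamic cross-correlation maps (DCCM), Cartesian-covariance PCA with
PC-space clustering, and correlation-weighted dynamical networks with
Girvan–Newman communities, critical nodes and optimal/suboptimal
communication paths.

Because no reference trajectory ships with the package, every analysis
stage is validated against synthetic generators with planted, analytically
known structure:

- **Gaussian ensembles** realise an exact 3N×3N displacement covariance
  (block correlations, planted eigen-spectra), so DCCM entries and PCA
  variance fractions have closed-form expected values.
- **Two-lobe mechanism** trajectories move two dense lattice lobes by
  rigid-body clamshell and twist rotations around a hinge, joined by a
  narrow bridge that is the only inter-lobe contact route — giving known
  anti-correlated inter-lobe motion, community structure and path
  topology.
- **Planted community graphs** provide ground truth for the network
  algorithms, which are additionally checked against brute-force
  enumeration and exhaustive max-modularity oracles.

## Layout

| module                | contents                                                         |
|-----------------------|------------------------------------------------------------------|
| `trajnet.model`       | `AtomRecord`, `Structure`, `Trajectory`, `Selection`, `NodeMap`  |
| `trajnet.io`          | multi-model PDB read/write, node-map construction                |
| `trajnet.synthetic`   | Gaussian-ensemble / two-lobe / planted-graph generators          |
| `trajnet.fluctuation` | Kabsch superposition, RMSD/RMSF, B-factor conversion, distance maps |
| `trajnet.corrpca`     | DCCM, covariance PCA, k-means / complete-link clustering, elbow scan |
| `trajnet.network`     | contact persistence, −ln\|C\| networks, communities, betweenness, paths |
| `trajnet.pipeline`    | JSON-config end-to-end pipeline and fixture factory              |
| `trajnet.cli`         | `trajnet` command-line interface                                 |

Trajectories travel as multi-model PDB (one `MODEL` per frame); tables are
TSV; networks are GraphML + edge lists; the pipeline summary is JSON and is
byte-identical for a fixed config + seed.

## CLI

```sh
# write a synthetic two-lobe fixture (trajectory + ground-truth JSON)
trajnet simulate two-lobe-default --seed 7 --out-dir scratch/fix

# single stages
trajnet rmsf scratch/fix/two-lobe-default.pdb rmsf.tsv
trajnet dccm scratch/fix/two-lobe-default.pdb dccm.tsv
trajnet pca  scratch/fix/two-lobe-default.pdb scree.tsv --projections proj.tsv
trajnet paths scratch/fix/two-lobe-default.pdb A:GLY2 A:GLY21 --exclude-neighbors 0

# full pipeline from a JSON config (see trajnet.pipeline.PipelineConfig)
trajnet run-all config.json
```

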