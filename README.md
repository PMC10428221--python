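# allopath

Allosteric path analysis for ion-channel MD trajectories: weighted
residue-interaction networks built from contacts and side-chain
mutual information, minimal-communication-path and centrality analytics,
symmetry-aware clustering of receptor conformations, and population-based
rescoring of ensemble-docking poses (MaxP / MaxP′).

The package is aimed at computational biophysicists studying how a
perturbation — typically a bound drug — rewires the communication between a
channel's voltage-sensor domain and its pore, the question at the heart of
activator pharmacology in Kv channels such as hERG.

## The model

The protein (plus an optionally bound ligand, split into user-defined
fragments) is a graph whose nodes are residues and fragments. Each edge
carries the weight

```
w_ij = -ln( C_ij · M̂_ij )
```

with two ingredients estimated from the trajectory:

* **Semi-binary contact map** `C_ij`: the frame average of a truncated
  Gaussian kernel of the Cα–Cα (or fragment-COM) distance — exactly 1 up to
  a cutoff `c = 7 Å`, a Gaussian tail beyond it, zero past a truncation
  distance `d_cut = 10 Å`. The tail width σ is calibrated so that
  `K(d_cut) = 10⁻⁵`, giving σ = 0.6252 Å (any value, e.g. 1.48 Å, can be
  set explicitly).
* **Normalized mutual information** `M̂_ij = M_ij / H_ij` of the two
  nodes' side-chain center-of-mass displacement series, where `H_ij` is the
  joint Shannon entropy, so `M̂ ∈ [0, 1]`. The default estimator is a
  fixed-width histogram; a parametric Gaussian estimator is available for
  closed-form checks.

Source and sink regions are detected by a moving-sphere occupancy rule
(7 Å radius, 70 % of frames). Minimal paths come from Dijkstra's algorithm;
the minimal length `d_min` measures coupling: since weights are natural
logarithms, `exp(-d_min)` is a multiplicative coupling efficiency and a
difference of 9 units in `d_min` is ~4 orders of magnitude. Per-node
importance is Brandes betweenness centrality.

Around the network core:

* **Receptor clustering** (`allopath.receptor_clustering`) — k-means with an
  RMSD-equivalent metric on superposed coordinates, after *symmetry
  expansion*: each frame contributes one copy per cyclic subunit relabeling,
  so the four equivalent binding sites of a homotetramer are pooled and
  cluster populations `P_J` are invariant under relabeling of the input.
* **Ensemble rescoring** (`allopath.rescoring`) — energy-ordered leader
  clustering of docking poses at a 2 Å RMSD threshold (cluster energy `E_I`
  = lowest member energy, population `P_I`), then
  `MaxP_I = P_I · exp(-E_I/kT)` and
  `MaxP′_{I,J} = P_J · P_I · exp(-E_I/kT)` with `kT = 0.593 kcal/mol`.
  Ligand protonation/ring-state bookkeeping (8 states, 4 retained) is
  included.
* **Synthetic data** (`allopath.synthetic`) — a C₄-symmetric pseudo-channel
  whose side-chain displacements follow a planted correlation structure, and
  pose ensembles drawn from planted modes, so every stage can be validated
  against known ground truth.
* **Structural reports** (`allopath.reports`) — ligand–residue contact
  fractions (4.5 Å cutoff), pore-integrity distance series, and a
  YAML-configured pipeline runner with a reproducible run manifest.

## Worked example

Build a 40-node pseudo-channel whose first subunit carries a planted chain
of correlated side chains (ρ = 0.9 between consecutive residues), then ask
for the minimal path between the chain's ends:

```python
from allopath import (AllostericNetworkModel, PlantedCovariance,
                      ToyChannelSpec, generate_toy_channel,
                      generate_trajectory)
from allopath.trajectory import extract_node_series, load_system

spec = ToyChannelSpec()                      # 4 subunits x 10 residues
channel = generate_toy_channel(spec)
cov = PlantedCovariance(path_nodes=tuple(range(10)), rho_path=0.9)
traj = generate_trajectory(channel, cov, n_frames=500, seed=1)

system = load_system(None, universe=traj.to_universe())
results = AllostericNetworkModel(extract_node_series(system)).fit()
print(results.summary())

r = results.min_path({0}, {9})
print("d_min =", round(r.d_min, 2))
print("best path:", " -> ".join(results.label_of(i) for i in r.best_path))
```

prints

```
Allosteric network summary
==========================================
nodes                 40
edges                 104
frames used           500
kernel cutoff c       7.00 A
kernel truncation     10.00 A
kernel sigma          0.6252 A
MI estimator          histogram/factorized (B=14)
edge weight           w_ij = -ln(C_ij * M_hat_ij)
weight min/median/max 1.379 / 5.097 / 8.510
top betweenness nodes:
  A:ALA5             0.2942
  A:ALA6             0.2874
  A:ALA3             0.2389
  A:ALA8             0.2308
  A:ALA4             0.2227
d_min = 12.74
best path: A:ALA1 -> A:ALA2 -> ... -> A:ALA10
```

The recovered minimal path is exactly the planted chain: its edges combine
full contact (`C = 1`) with high normalized MI, so each step costs ~1.4
units versus ~4–5 for uncorrelated neighbours, and the interior chain
residues dominate the betweenness ranking. `exp(-12.74) ≈ 3e-06` is the
end-to-end coupling efficiency; weakening the planted correlation raises
`d_min`.

A shell workflow is available through the `allopath` CLI
(`simulate`, `paths`, `cluster`, `rescore`, `contacts`, `report`), each
subcommand a thin wrapper over the pipeline runner.

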