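# Methods notes

This note records the scientific and numerical choices behind the package:
what each stage computes, which defaults matter, what the synthetic test bed
does and does not emulate, and where the design was genuinely open.

## Network model

**Nodes.** One node per protein residue plus one per user-defined ligand
fragment. Residue nodes are anchored at their Cα for the contact map; the
random variable entering the mutual information is the side-chain
center-of-mass displacement about its time mean (mass-weighted heavy atoms
beyond the backbone; glycine, with no heavy side-chain atom, falls back to
its Cα so every residue stays representable). Ligand fragments use the
fragment heavy-atom COM for both roles — fragments have no Cα, and using
one anchor for both keeps the ligand's treatment internally consistent.

**Contact map.** `C_ij` is the frame average of a semi-binary kernel: 1 for
`d ≤ c` (default 7 Å), `exp(-(d-c)²/2σ²)` beyond, and 0 past `d_cut`
(default 10 Å). σ defaults to the value solved from the calibration
condition `K(d_cut) = ε` with `ε = 10⁻⁵`:
`σ = (d_cut - c)/√(-2 ln ε) = 0.6252 Å`. Because the calibration is stated
at `d_cut`, the truncation is strict (`d > d_cut → 0`), so
`K(d_cut) = ε` holds exactly. Other parameterizations in circulation put the
Gaussian's center at zero rather than at the cutoff, which yields σ near
1.5–2 Å for the same floor condition; any explicit σ can therefore be
supplied through `KernelParams(sigma=...)` and is recorded in the network
provenance.

**Mutual information.** `M_ij = H_i + H_j - H_ij` with plug-in Shannon
entropies of discretized displacements; normalization by the joint entropy
gives `M̂ = M/H_ij ∈ [0, 1]`, which a discrete estimator guarantees
(differential entropies can be negative, which would break the
normalization — the main reason the histogram estimator is the default and
the Gaussian estimator is reserved for closed-form cross-checks).

Two histogram layouts are available:

* `factorized` (default): MI and joint entropy are estimated per spatial
  dimension (B bins each over mean ± 4 SD) and summed. For displacement
  components that are independent across x/y/z — exactly true of the
  synthetic generator, and a reasonable approximation for roughly isotropic
  side-chain motion — MI is additive over dimensions, and each per-dimension
  joint histogram (B² cells) stays well-sampled at a few hundred frames.
* `joint`: the literal 3-D joint histogram with B³ bins per node. Exact in
  principle, but its B⁶ joint cells are severely undersampled at desk-scale
  frame counts (at B = 10 and 500 frames the plug-in `M̂` saturates toward
  ~0.6 for *independent* pairs, destroying contrast), so it is provided for
  completeness rather than as the default.

The default bin count is B = 14. The choice balances two opposing plug-in
errors for a Gaussian pair at ~5000 samples: quantization loss (dominant at
small B; ~21 % of the true MI at B = 10 for ρ = 0.9) against sampling bias
(grows as ~(B-1)²/2N; dominant past B ≈ 20 at ρ = 0.5). B = 14 keeps the
worst-case relative error over both regimes near 12 %. Degenerate
(zero-variance) series get `M̂ = 0` with a warning — a frozen node carries
no information.

**Weights, paths, centrality.** `w_ij = -ln(C_ij · M̂_ij)`, edges only
where the product is positive, no self-edges. The natural logarithm is fixed
by the metric's interpretation: `exp(-d_min)` is a product of per-edge
coupling factors, and a 9-unit difference in `d_min` is
`log₁₀(e⁹) ≈ 3.9` — four orders of magnitude. Sequence-adjacent residues
are *not* excluded from the edge set by default (a configurable mask
exists). Source/sink regions are detected with a sphere that moves with the
center residue (radius 7 Å, occupancy ≥ 70 % of frames). `d_min` is the
minimum Dijkstra distance over all source–sink pairs; all co-minimal paths
within a 10⁻⁹ relative tolerance are collected and the lexicographically
smallest node sequence is the deterministic `best_path`. Betweenness is
Brandes's algorithm with NetworkX's pair normalization
(2/((n-1)(n-2)) for undirected graphs), recorded in the docstring and
summary. Displacements are centered per trajectory; no superposition is
applied by default (an optional least-squares fit to the mean structure is
available and logged, for inputs with global drift).

## Receptor clustering

Conformations are clustered on a residue selection (default: the
pore-lining S5 546–559 and S6 649–667 ranges of hERG, heavy atoms) with
k = 10 by default. Because the four subunits of a homotetramer are
chemically equivalent, each frame is first *symmetry-expanded* into its
cyclic subunit relabelings; the augmented set is rigid-body fitted to its
iteratively refined mean and clustered by seeded k-means++ on flattened
coordinates (Euclidean distance there equals RMSD × √n after alignment).
Expansion rather than a symmetry-corrected distance kernel was chosen
because it keeps the clustering a plain k-means problem and makes the
invariance property directly testable: relabeling the input permutes the
augmented multiset and leaves populations unchanged. Representatives are
exact medoids (the member minimizing mean distance to its cluster);
populations count augmented items, which pools the four equivalent binding
sites — the purpose of the exercise. All-identical inputs collapse to one
effective cluster with a warning; k-means' internal relocation handles
transiently empty clusters.

## Ensemble rescoring

Poses are clustered per docking run (receptor conformation × ligand state)
by energy-ordered leader clustering: the best-energy unassigned pose seeds a
cluster and every pose joins the first cluster whose seed is within the
RMSD threshold (default 2 Å), with plain coordinate RMSD — no
superposition, since docked poses share the receptor frame, and no symmetry
correction. Cluster energy is the lowest member energy; populations are
normalized within the run. Runs are pooled into one ranked table;
cross-state RMSD comparison is not attempted because different ligand
states have different atom identities.

Scores: `E_AD4` ranks by raw energy; `MaxP_I = P_I·exp(-E_I/kT)`;
`MaxP′_{I,J} = P_J·P_I·exp(-E_I/kT)` with receptor populations `P_J`
normalized over the whole conformational ensemble. The Boltzmann-weighted
population form is the natural reading of "maximum probability": it is the
product of how often a mode is found and how strongly it binds, and the
additive equivalent `E - kT ln P` (reported as `effective_energy`) gives
identical rankings, making the choice of multiplicative constant
immaterial — rankings, not absolute scores, are the contract. `kT`
defaults to 0.593 kcal/mol (298 K). Ties break toward lower energy, then
cluster identity, so rankings are total orders.

The ligand-state bookkeeping enumerates protonation {Z, N} ×
N-pyramidalization (position 1 equatorial/axial) × ring pseudorotation
(positions 3/4 swap e/a under the syn constraint) = 8 states, and retains
the four with the position-1 substituent equatorial — the axial orientation
of the bulky substituent is sterically penalized.

## Synthetic test bed

The toy channel is a bundle of n (default 4) identical helical rods related
by exact rotations about the pore axis; each residue is a CA/CB pair. The
rod geometry is chosen so that consecutive residues are ~5.1 Å apart
(always in contact), second neighbours ~8.6 Å (weak kernel tail) and third
neighbours beyond 10 Å (no contact): the residue chain is the natural
contact path along a subunit, with weak inter-subunit contacts at the
bundle radius (7 Å) providing background edges.

Displacements are multivariate Gaussian per frame, i.i.d. in time, with a
planted correlation matrix acting identically and independently on x, y, z:
along the designated path the correlation between nodes at chain distance m
is `ρ^m` (a Markov chain — consecutive correlation exactly ρ and positive
definite by construction), background nodes share a constant correlation
(default 0). User-specified matrices that are mildly non-PSD are repaired
by eigenvalue clipping with a warning; negative eigenvalues beyond 5 % of
the top eigenvalue are refused. Displacements are applied to side-chain
atoms only, so the toy contact map is deterministic while the MI structure
is planted. Default study conditions for recovery experiments: 40 nodes,
ρ_path = 0.9, unit noise SD, 500 frames, 20 seeded replicates — sizes at
which the sample correlation estimator pins the planted value to ±0.013
(3 SE) and a full pipeline run takes ~3 s.

What the generator does **not** emulate: temporal autocorrelation (the
estimators treat frames as independent samples, so planted correlations are
recovered faster than they would be from correlated MD frames — effective
sample sizes in real data are smaller than the frame count); anisotropic or
non-Gaussian side-chain motion; conformational transitions; force-field
physics of any kind. Passing tests therefore demonstrate estimator and
algorithm correctness under known statistics, not robustness to the
slow-relaxation pathologies of real trajectories.

Pose ensembles are drawn from explicit modes (center, energy, count,
isotropic spread); with modes ≳8 Å apart and sub-Å spread, 2 Å leader
clustering recovers the planted partition exactly, which is what the
rescoring recovery checks rely on.

## Numerical conventions and degenerate inputs

* All entropies and MI in nats; energies kcal/mol; distances Å.
* Histogram span mean ± 4 SD per dimension, clipped at the edge bins;
  frozen dimensions occupy a single bin.
* `M̂` clipped to [0, 1]; `M` floored at 0 before normalization.
* Shortest-path ties resolved lexicographically (stringified node ids);
  co-minimal paths all reported.
* Pose-cluster ties (equal score) broken by lower `E_I`, then cluster id.
* Empty frame selections, mismatched topology/trajectory atom counts,
  non-partitioning fragment maps, missing Cα atoms, missing receptor
  populations and k > n clustering requests all raise descriptive errors.
* Every generator and every clustering call is a pure function of its
  inputs and seed; pipeline runs write a manifest with SHA-256 checksums of
  all outputs, and rerunning a deterministic configuration reproduces the
  checksums byte for byte.

## Known limitations

* The factorized MI default underestimates cross-dimensional redundancy
  when displacement components are strongly coupled across axes; the
  `joint` mode exists for such data but needs far more frames than it is
  practical to require by default.
* Leader clustering is order-dependent by design (energy order); it matches
  the docking-tool convention it reproduces but is not a global optimum.
* Symmetry expansion multiplies clustering cost by the subunit count;
  for very long trajectories subsample frames first.
* The pipeline assumes whole (PBC-unwrapped) coordinates and does not
  align trajectories beyond the optional least-squares fit.
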