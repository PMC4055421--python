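# Methods

This note records the models implemented in psnflow, the parameters
that matter, the numerical conventions, and what the synthetic studies
do and do not demonstrate.

## Ensembles and residue representation

A conformational ensemble is a fixed topology plus ≥1 coordinate
frames. Multi-model PDB is the interchange format; a binary-trajectory
adapter (mdtraj) exists behind the same contract but nothing in the
core depends on it. Hydrogens, waters and (by default) heteroatoms are
dropped on read, because all analyses operate on amino-acid residue
graphs. Residues are keyed by (chain id, author residue number,
insertion code) and never renumbered; the two chains of a homodimer
therefore keep separate numbering.

Three representation modes exist: `calpha` (one CA per residue, used
for rigidity, correlation and PCA), `all` (all heavy atoms), and
`sidechain` (heavy side-chain atoms, used for contact counting).
Glycine has no heavy side chain and falls back to its CA in
`sidechain` mode — the alternative, dropping glycines, would puncture
residue-complete profiles and delete real network nodes. The synthetic
toy chains are built from glycines deliberately so that their single
CA serves both representations.

## Force-constant rigidity profiles

For each selected atom *a* of residue *i*, the per-frame mean distance
*d_a(t)* to all atoms of admissible residues is computed; residues
within `exclusion_width` (default 1) sequence positions on the same
chain are excluded, because those distances are nearly constant by
covalent geometry and would deflate the variance. Inter-chain pairs
are always admissible. Then

    k_a = c · k_B · T / Var(d_a),      k_i = mean over atoms of k_a.

Conventions and defaults:

* `c = 3` (one factor of k_B T per Cartesian degree of freedom of the
  distance fluctuation). The constant is a pure scale — profiles are
  used comparatively — so it is an explicit config scalar; setting
  `c = 1` reproduces the 1-k_B-T variant.
* `k_B = 1.987204259e-3 kcal/mol/K`, `T = 300 K`. Units of k_i:
  kcal mol⁻¹ Å⁻².
* Variance is the population variance over frames (two-pass, clamped
  at zero). Zero-variance residues are flagged `rigid` instead of
  receiving an infinite value; downstream consumers cap them at the
  profile maximum for display.
* Distances are Euclidean invariants, so the profile is exactly
  invariant under per-frame rigid-body transforms; no superposition is
  required before this stage.

On the two-domain hinge ensemble the hinge residues sit close to the
rotation axis, so their mean distance to both domains barely changes
while domain residues sweep large distance changes: the hinge is the
force-constant peak by construction, which is the oracle the tests
use.

## B-factors, depth, differential protection

Ensemble B-factors are B_i = (8π²/3)·⟨|Δr_i|²⟩ about the ensemble
mean (superposed frames assumed; per-residue over the representative
atoms). Residue depth below the solvent-accessible surface is computed
by sphere-point sampling: each atom's SAS sphere (vdW + probe, probe
1.4 Å, 96 points by default on a golden-spiral lattice) is pruned of
points buried in neighbouring spheres; an atom's depth is the distance
from its centre to the nearest surviving surface point, a residue
averages its heavy atoms, and the profile averages frames. This is a
deterministic, dependency-free approximation chosen because depth is
used only differentially (state A minus state B on the shared residue
set); absolute depths converge to ~0.1 Å by 128 points on compact
structures and the differential profile is antisymmetric by
construction.

## Superposition, correlation, modes

Frames are least-squares fitted (Kabsch, equal weights over the
selected atoms, reflection-safe) onto an iteratively refined mean
structure, converged when the mean moves < 1e-6 Å RMSD. The fitting
reference matters for mobility statements: with equal weights over an
asymmetric hinge system, the stationary hinge inherits the centroid
swing of the moving domain, so hinge-mobility comparisons are made
after fitting on the rigid core (one domain), where the construction
guarantees zero residual RMSF inside the fitted domain.

The dynamic cross-correlation matrix uses one representative point per
residue (centroid of the selection atoms; the CA in `calpha` mode):
C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), clipped to [−1, 1],
diagonal forced to 1; zero-fluctuation residues get zeroed rows and a
flag rather than NaNs. PCA diagonalizes the 3N covariance of the
representative coordinates; "low-frequency modes" are identified with
the largest-variance components by the quasi-harmonic correspondence,
and the mode-averaged mobility profile is
sqrt(Σ_m λ_m |v_m,i|²) over the top `n_use` (default 3) modes.

The Gaussian-network generator prescribes an isotropic per-node
covariance (scaled pseudo-inverse of the contact Kirchhoff matrix,
applied independently per axis), which gives closed forms for the
correlation matrix, B-factors and PCA spectrum; sampling accuracy of
the estimators is verified against those closed forms at 20,000 frames
(correlation RMS error well under 0.05, force constants within 10% of
an independent multivariate-normal sampling oracle).

## Contact networks and occupancy

n_ij counts distinct side-chain heavy-atom pairs within `cutoff`
(4.5 Å) between residues i and j; I_ij = 100·n_ij/√(N_i N_j) percent.
The per-type normalization values N_i ship as the classical values
used in PSN construction (packaged table, fully overridable); an
`empirical` mode instead sets N_i to the maximum total contact count
observed for that residue type in the input ensemble, which is the
right choice for synthetic structures whose contact regime is far from
the canonical 20 residue types. A `unit` mode (N_i = 1) exists for
raw-count networks.

Network rules, all strict inequalities ("greater than"): edge iff
I_ij > I_min (default 3.0%); stable iff occupancy > 0.75. Sequence
neighbours within a chain are never connected; inter-chain pairs are
always eligible. Occupancy is evaluated over evenly spaced snapshots
(default cap 500; deterministic subsampling, never random), and is
defined per edge — subgraph-level persistence is reported separately
(below). The I_min scan reports the largest connected cluster per grid
point and estimates the percolation transition as the grid point with
the largest drop from its predecessor; a flat scan leaves the
transition flagged undefined. Hubs are nodes with degree ≥ 4.

## Clique percolation

k-cliques are enumerated by expanding maximal cliques (Bron–Kerbosch
with pivoting via networkx) into their size-k subsets — exhaustive
because every k-clique lies in a maximal clique; correctness over
speed is the contract at the few-hundred-node scale of residue
networks. Communities are connected components of the clique-adjacency
relation under a configurable rule: strict (intersection ≥ k−1) or
relaxed (≥ k−2, the default, matching the "share k−1 or k−2 nodes"
definition). The relaxed rule can only coarsen the strict partition
(tested property). Defaults report k = 3 and k = 4 separately.

For ensembles, communities are computed on the occupancy-stable edge
network; because "a community is intact in a snapshot" admits two
readings (every member edge present vs. its cliques present), each
community additionally reports the fraction of snapshots in which all
its member-clique edges are simultaneously present, so the stricter
reading stays inspectable without changing the community set.

## Communication graphs, centrality, paths

Edge weights w_ij = −ln max(|C_ij|, floor) with floor 1e-6 (a |C| = 0
contact is capped, not infinite, and flagged). Edges exist only where
a stable contact exists — correlation alone never creates an edge.
Contacts with |C| below `c_min` (default 0.5) are kept for centrality
(they still carry flow, heavily penalized by weight) but excluded from
explicit source→target path ensembles, where the well-correlated-
intermediates restriction belongs. Hop-count shortest paths are
available as a first-stage cross-check; weighted paths are
authoritative for all reported quantities.

All-pairs distances and minimum-weight path counts use Floyd–Warshall
with a relative tie tolerance of 1e-9; at stage k a pair's count
accumulates products of sub-counts exactly when the detour through k
ties the incumbent, which counts each shortest path once at its
highest-index intermediate. Betweenness is
b_i = Σ_{j<k≠i} g_jk(i)/g_jk normalized by (N−1)(N−2)/2 (undirected
convention, stated in output metadata); endpoints never count as
pass-through. Degenerate exactly-zero-weight cycles (only possible at
|C| = 1 to machine precision) can make tie counting ambiguous; the
synthetic studies and tests use strictly positive weights. Closeness
(inverse mean distance) is exposed as a trivial derived quantity only.

Suboptimal paths are enumerated depth-first with branch-and-bound
(prune when current length plus the Dijkstra distance-to-target
exceeds L_opt + tolerance), default tolerance 0.69 — the weight of a
|C| = 0.5 edge — with a hard cap (default 1e5 paths) and a truncation
flag to guarantee termination.

## Synthetic studies: what they show and what they do not

The generators fix the study conditions: Gaussian ensembles (12-node
chain, GNM cutoff 8 Å, scale 0.5 Å², 20,000 frames for statistical
recovery, 2,000 in the bundled demo), the hinge ensemble (2×16
residues + 3 hinge residues, ±25° uniform bending, 200 frames), and
the bridge ensemble (two 6-residue octahedral clusters joined by one
bridge residue, an asymmetric stretch mode of amplitude 0.35 Å over
0.08 Å atomic noise, 200 frames). These sizes keep every oracle exact
or exhaustively checkable at desk scale.

Passing tests therefore demonstrate correctness of the estimators and
graph algorithms against known ground truth — they do not demonstrate
that a 50-ns all-atom trajectory of a real chaperone is converged, nor
that the biological interpretation of any particular peak is right.
Features of real data the generators do not emulate: anisotropic and
correlated noise across all residues, side-chain rotamer dynamics
(synthetic residues are single points, so contact counts are 0/1),
solvent effects, and the 20-residue contact-capacity spectrum (hence
the `empirical` normalization in the demo configs).

## Known limitations

* The packaged N_i table is the standard literature normalization but
  is overridable precisely because it is a convention, not ground
  truth; tests never depend on specific N_i values.
* FW path counting counts non-simple decompositions only in the
  presence of exact zero-weight cycles (see above); weights derived
  from |C| < 1 are strictly positive.
* Depth is a comparative quantity here; it is not a replacement for
  water-placement or ray-casting depth algorithms when absolute depths
  matter.
* Community identity across snapshots is by node-set equality; no
  fuzzy matching of drifting communities.
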