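# psnflow

Ensemble-based **protein structure network** (PSN) analysis: residue
rigidity profiling, side-chain interaction networks with dynamic
occupancy filtering, k-clique percolation communities, and
correlation-weighted centrality / communication-pathway analysis.

## Who this is for

Structural bioinformaticians studying allosteric communication in
multi-domain proteins (chaperones such as Hsp90 are the canonical
example). The input is a conformational ensemble — an MD trajectory
exported as a multi-model PDB, or any set of frames over a fixed
topology — and the output is a set of residue-level profiles and
network maps that together locate the structurally rigid scaffold and
the residues that mediate communication across it.

## The quantities computed

**Force-constant rigidity profile.** For residue *i*, let
*d<sub>i</sub>(t)* be its mean distance to all residues outside its
sequence neighbourhood in frame *t*. The effective force constant

&nbsp;&nbsp;&nbsp;&nbsp;*k<sub>i</sub>* = 3 *k*<sub>B</sub>*T* / ⟨(*d<sub>i</sub>* − ⟨*d<sub>i</sub>*⟩)²⟩

is the inverse of the distance-fluctuation variance scaled by thermal
energy (*T* = 300 K by default): rigid residues — inter-domain hinges
above all — show up as sharp peaks.

**Contact network.** Residues *i, j* are connected when their
normalized side-chain contact strength
*I<sub>ij</sub>* = 100 · *n<sub>ij</sub>* / √(*N<sub>i</sub>N<sub>j</sub>*)
exceeds *I*<sub>min</sub> (default 3%), where *n<sub>ij</sub>* counts
side-chain heavy-atom pairs within 4.5 Å and *N<sub>i</sub>* is a
residue-type normalization. Sequence neighbours are never connected.
Over an ensemble, an edge's **occupancy** is the fraction of snapshots
in which it exists; edges with occupancy > 0.75 form the *dynamically
stable* network.

**Communities.** k-clique percolation (k = 3, 4) on the stable
network, with the relaxed adjacency rule in which two cliques are
adjacent when they share k−1 *or* k−2 nodes (the strict k−1 rule is a
switch).

**Communication.** Stable edges are weighted by
*w<sub>ij</sub>* = −ln |*C<sub>ij</sub>*|, where *C<sub>ij</sub>* is the
dynamic cross-correlation of residue displacements. All-pairs shortest
paths (Floyd–Warshall with minimum-weight path counting) yield
normalized betweenness; for a chosen residue pair the package
enumerates the optimal path plus all suboptimal paths within a length
tolerance (default 0.69, the weight of a |C| = 0.5 edge), restricted to
well-correlated intermediates.

Because 50-ns MD of a real chaperone is not a test fixture, the package
ships a synthetic-data module that generates ensembles with *known*
ground truth (Gaussian-network ensembles with analytic covariance,
rigid two-domain hinge motion, a planted bridge topology, hand-counted
contact fixtures), and every stage is tested against those oracles.

## Worked example

```
python analysis/01_simulate.py --seed 1      # synthetic study
python analysis/02_rigidity_profile.py       # force constants
python analysis/06_communication_paths.py    # betweenness + paths
```

prints, among other things:

```
hinge residues [17, 18, 19]: median k = 529.9 kcal/mol/A^2
domain residues: median k = 96.4
top force-constant decile: residues [17, 18, 19, 25] (hinge coverage 3/3)
...
top betweenness residues:
chain residue res_name  degree  betweenness
    A       7      GLY       4     0.545455
    A      13      GLY       4     0.333333
    A       1      GLY       4     0.333333
40 paths within tolerance 0.69 of optimum L = 0.987; best route: A:4 -> A:1 -> A:7 -> A:13 -> A:10
```

Reading: the three hinge residues of the two-domain ensemble carry
force constants ~5× the domain median and occupy the top decile — they
are the rigid pivot the domains move about. In the bridge study, the
single residue connecting the two clusters (A:7) attains the maximum
normalized betweenness, and every optimal/suboptimal communication
pathway funnels through it. That rigidity/centrality correspondence is
exactly the signature used to nominate allosteric mediating residues in
real chaperone ensembles.

The same pipeline runs from the command line on any multi-model PDB:

```
psnflow simulate --seed 1 --outdir demo
psnflow run-all --config demo/demo_bridge.cfg
psnflow profile --input your_ensemble.pdb --output k.tsv
```

## Layout

```
src/psnflow/          library: ensemble_io, synthetic_data, stability,
                      correlation, psn_graph, communities,
                      communication, pipeline, cli
analysis/             numbered study drivers (simulate -> paths)
tests/                pytest suite incl. oracle-based acceptance tests
scripts/acceptance.py end-to-end reproduction script
docs/methods.md       model, parameters, numerical choices, limitations
```
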