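# mdnetkit

Dynamic residue network (DRN) and trajectory analysis for molecular
ensembles, aimed at studies of allosteric communication in multi-domain
proteins (the Hsp70 chaperone family — an N-terminal nucleotide-binding
domain coupled to a substrate-binding domain through a conserved flexible
linker — is the motivating case).

Given an ensemble of conformations (a multi-model PDB, one MODEL per frame),
the package builds a residue interaction network per frame — nodes are
residue representative atoms (C&beta;, with C&alpha; standing in for
glycine), edges join pairs within a 6.7 Å cutoff — and averages two
per-residue graph metrics over frames:

* **average shortest path** `L(i) = Σ_j d(i,j) / (N−1)` — the mean hop count
  from residue *i* to every other reachable residue; low `L` marks residues
  highly accessible for signal propagation;
* **betweenness centrality**
  `BC(i) = 2/((N−1)(N−2)) · Σ_{s<t} σ_st(i)/σ_st` — the fraction of all
  shortest paths passing through *i*; high `BC` marks communication
  bottlenecks.

Residues beyond `mean ± k·SD` of a profile are flagged as hubs
(conventionally `k = 1` below the mean for `L`, `k = 2` above it for `BC`).
Ligand-free and ligand-bound conditions are compared by per-residue deltas
(free − bound), by joint min–max normalisation of the pair onto [0, 1]
(`Z_A = (A − min(A,B)) / (max(A,B) − min(A,B))`, min/max over the union),
and by Pearson correlations between metrics (including inverse-transformed
comparisons such as `L⁻¹` vs `BC`).

Alongside the network layer the package provides the standard trajectory
statistics — Kabsch superposition, RMSD, RMSF, radius of gyration,
interdomain centre-of-mass distances, geometric hydrogen-bond counts,
gromos conformational clustering — and essential dynamics: the `3N × 3N`
C&alpha; covariance matrix, its eigendecomposition and trace, frame
projections onto the top eigenvectors, and Gibbs free-energy landscapes
`ΔG = −k_B T ln(P/P_max)` over (PC1, PC2).

A seeded synthetic-trajectory generator with exact ground truth (per-residue
noise amplitudes, an interdomain distance schedule, a planted high-centrality
bridge residue) makes every stage testable without external data.

## Worked example

```python
import numpy as np
import mdnetkit as mk

# a structure whose 6.7 Å contact graph is two 10-residue cliques joined
# through one bridge residue, plus thermal noise
frame, truth = mk.generate_planted_bridge_structure(m=10, seed=42)
traj = mk.add_positional_noise(frame, sigma_profile=0.2, n_frames=25, seed=43)
sel = mk.select_representatives(traj)

profile = mk.average_profiles(traj, sel, cutoff=6.7)
hubs = mk.detect_hubs(profile.profile("BC"), k_sd=2.0, direction="high")
bridge = sel.residue_labels.index(truth.bridge_residue)
print(profile.avg_BC[bridge], hubs.threshold)
```

prints (see `examples/02_residue_network_hubs.py` for the full script):

```
avg BC at bridge: 0.5263 (fraction of all shortest paths crossing it)
avg BC elsewhere: max 0.5211
BC hubs (mean+2SD, threshold 0.4496): ['A1', 'L11', 'B12']
```

The planted bridge (`L11`) carries 52.6% of all shortest residue–residue
paths and is flagged by the 2-SD rule together with its two gateway
contacts — the synthetic analogue of an interdomain-linker communication
hub.  The other examples cover RMSF/COM-schedule parameter recovery
(`examples/01...`), essential dynamics and free-energy landscapes
(`examples/03...`) and the full free-vs-bound pipeline (`examples/04...`).

## Command line

A thin CLI wraps the library:

```sh
mdnetkit simulate --n-a 20 --n-b 20 --n-linker 10 --sigma 0.5 \
    --schedule const:25 --frames 2000 --seed 1 --out traj.pdb
mdnetkit drn compute traj.pdb --cutoff 6.7 --window last:15% --out profile.csv
mdnetkit drn hubs profile.csv --metric BC
mdnetkit metrics rmsf traj.pdb --units nm
mdnetkit ed eig traj.pdb --selection CA
mdnetkit run --config config.yaml     # full free-vs-bound pipeline
```

## Scope

The package analyses ensembles; it does not generate them (no force fields
or integrators), build homology models, dock ligands, or compute binding
free energies.
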