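# Methods

## Residue interaction networks and their frame averages

A residue interaction network (RIN) for one conformation is an undirected,
unweighted graph whose nodes are one representative atom per residue — the
C&beta;, with the C&alpha; standing in for glycine — and whose edges join
every pair of representatives within a distance cutoff.  The default cutoff
is 6.7 Å and the comparison is inclusive (a pair at exactly 6.7 Å is an
edge), reading the threshold as a minimum interaction distance.  Covalently
adjacent residues (i, i±1 on one chain) are kept as contacts by default; a
flag removes them for users who want purely tertiary contacts.

The dynamic residue network (DRN) view recomputes the RIN on every frame of
an analysis window and averages two per-residue metrics across frames:

* **L**, average shortest path: the mean hop count of breadth-first shortest
  paths from the residue to every other reachable residue.  On a
  disconnected graph the average runs over the reachable set only and the
  reachable fraction is recorded per residue; a fully isolated residue has
  undefined (NaN) L.  Nothing is imputed: substituting a large constant for
  unreachable pairs would shift frame averages invisibly.
* **BC**, betweenness centrality with fractional credit over equal shortest
  paths (Brandes pair-dependency accumulation, delegated to networkx, which
  is also the engine of the field's standard DRN tooling), normalised by
  2/((N−1)(N−2)) so values lie in [0, 1].  The star-graph centre attains
  exactly 1.  For N < 3 all values are defined as 0.

Profile statistics use per-residue means and sample standard deviations
(n−1 divisor) over frames; per-frame NaN values are excluded per residue.
Duplicate simulation runs are combined by an explicit `combine_runs` step
(per-residue mean of run means, root-mean-square of run SDs), never
implicitly.

## Hub detection, deltas, normalisation, correlations

Hubs are residues beyond `mean ± k·SD` of a profile, computed over defined
values only, with inclusive comparisons (deterministic under exact ties).
The conventional settings are `k = 1` below the mean for L (accessibility
dips) and `k = 2` above the mean for BC (centrality peaks); both the
multiplier and the direction are parameters, since an L cut can also be
meaningfully read as an upper threshold.  A constant profile yields an empty
hub set with a warning rather than an error.

Condition comparisons are per-residue differences, ligand-free minus
ligand-bound, on the explicit intersection of residue label sets (dropped
labels are reported; an undefined value on either side gives an undefined
delta).  A free/bound pair of profiles can be jointly rescaled onto [0, 1]
with min and max taken over the union of both vectors, so the two conditions
remain on one scale; equal-everything input is a zero-denominator error.
Pearson comparisons between per-residue metrics (optionally on inverses,
e.g. L⁻¹ vs BC) run over the residues where both transformed values are
finite; inverse transforms exclude exact zeros and the exclusion count is
reported.

## Geometry metrics

Superposition is the Kabsch solution (SVD of the weighted cross-covariance
with a determinant sign correction, so only proper rotations occur).  RMSF
uses a two-pass fit: frames are first fitted to frame 0, the mean structure
is computed, and frames are refitted to that mean; the same fitted
coordinates feed the covariance builder, which makes
`Σ_i RMSF_i² = trace(C)` an exact identity rather than an approximation.
The radius of gyration is equal-weighted by default when the selection holds
one atom per residue (masses are then nearly constant); centre-of-mass
distances are mass-weighted by default.  Both flags are exposed.

Hydrogen bonds use the geometric criterion |D−A| ≤ 3.5 Å and
angle(H–D–A) ≤ 30°, with explicit hydrogen positions required.  These
defaults mirror the common convention of standard MD analysis tooling and
are configurable; they are a documented assumption, not a measured choice.

gromos conformational clustering takes a precomputed symmetric frame-pair
RMSD matrix (staying agnostic about what was superposed), repeatedly
extracts the frame with the most neighbours within the cutoff as a centroid
(ties to the lowest frame index, which the original method description
leaves open), and removes the cluster.  Output clusters are ordered by
decreasing size, ties by lower centroid index, and always partition the
frame set.

## Essential dynamics and free-energy landscapes

The covariance of the flattened 3N selected coordinates uses the population
(1/M) divisor, matching the convention of the standard trajectory tools, and
is unweighted (one atom per residue).  Eigendecomposition returns descending
eigenvalues whose sum equals the trace; eigenvector signs are fixed by
making each column's largest-magnitude component positive so projections
are reproducible.  Lengths are Å internally; traces are also reportable in
nm² (1 nm² = 100 Å²) at the output layer only.

The free-energy landscape is the Boltzmann inversion
`ΔG(bin) = −k_B T ln(P(bin)/P_max)` with
k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹ and default T = 300 K, over a 2-D histogram
of (PC1, PC2) projections on a 32×32 grid spanning the data range padded by
1%.  Empty bins are masked rather than given a pseudo-count, so unsampled
regions stay blank; the most populated bin sits at exactly ΔG = 0.  Local
minima (occupied bins with no lower occupied 8-neighbour) are reported with
the frame nearest the bin centre as the representative conformer.

## Synthetic data: what it emulates, what it does not

Real inputs for this kind of analysis are hundred-nanosecond all-atom MD
trajectories of ~600-residue proteins, which cannot be regenerated at desk
scale; the generator instead produces small ensembles whose generating
parameters are known exactly, so estimators can be checked against closed
forms.

The two-domain generator builds beads on jittered cubic lattices (3.8 Å
spacing, the C&alpha; virtual bond length) for two compact domains joined by
an interpolated linker; frame *t* rigidly translates domain B so the B−A
centre-of-mass separation equals a prescribed schedule exactly, then every
bead receives independent isotropic Gaussian noise with a per-residue SD.
Consequences used by the tests: with zero noise the COM-distance series
reproduces the schedule to machine precision, and with noise σ the RMSF
converges to σ√3.  Defaults describe the reference study system: 50
residues (20/10/20), σ = 0.5 Å, constant 25 Å separation, 2000 frames
stored every 2 ps.  One bead serves as the whole residue and is emitted as
a glycine C&alpha;, so both the C&alpha; and C&beta; selection schemes
resolve to it.  Randomness flows through numpy's PCG64 generator, making
output bit-reproducible for a given spec and seed.

The planted-bridge generator places two m-residue cliques whose only
inter-community connection passes through one bridge residue.  Geometry:
bridge at the origin, one gateway bead per clique at ±4.5 Å (2.2 Å inside
the cutoff — the two bridge edges are the only contacts whose loss could
sever the communities, so they get the widest margin), and the remaining
beads in a 1.5 Å ball at ±9.0 Å.  Under the 0.2 Å thermal jitter used in
the hub-recovery study, occasional loss of a member–gateway contact or gain
of a member–bridge contact cannot create a path that bypasses the bridge,
so the bridge remains the unique inter-clique cut vertex.  The default
community size for hub-recovery studies is m = 10: with two m-cliques plus
a bridge the gateways' BC, (m²−1)/(m(2m−1)), is nearly the bridge's
m/(2m−1), and for m ≤ 7 the mean + 2·SD threshold over the 2m+1 values sits
above the bridge's BC even in the noise-free graph — the detection rule is
only satisfiable for m ≥ 8.

What the generator does *not* emulate: bonded/non-bonded potentials,
secondary structure, anisotropic or correlated fluctuations, solvent, and
realistic contact-density heterogeneity.  Passing tests therefore
demonstrate correctness of the estimators and the analysis logic under
known ground truth, not performance on real chaperone trajectories.

## Numerical and I/O choices

* Internal length unit is Å (native to PDB); nm is an output-layer
  conversion only.
* Multi-model PDB frames get synthesized times, model ordinal × dt (default
  dt = 2 ps); PDB has no standard time field.  Alternate locations other
  than '' / 'A' are dropped with a warning.  Atomic masses come from a fixed
  internal element table; unknown elements get carbon's mass with a warning.
* Frame windows keep frames in the closed interval and thin greedily: each
  kept frame is at least the stride after the previous kept one.  The
  analysis default mirrors the field convention of sampling the final
  segment of a production run (last 15% at 10 ps stride).
* The frame-pair RMSD matrix for clustering must be symmetric within 1e−10;
  covariance matrices are symmetrised against round-off before
  eigendecomposition.
* Pipeline outputs render floats with 6 significant digits and contain no
  timestamps, so a rerun of the same configuration is byte-identical.

## Problem sizes in the verification suite

The test and acceptance runs use sizes chosen to make every check exact or
statistically sharp while staying desk-scale: 100 random geometric graphs of
up to 40 nodes for oracle equivalence (exhaustive path enumeration up to 12
nodes), 50-residue ensembles of 500–2000 frames for identities and parameter
recovery, 100 seeds for planted-hub recovery, and 20-residue ensembles for
the end-to-end pipeline determinism check.

## Known limitations

* Binary trajectory formats (XTC/TRR/DCD) are not read; inputs are
  multi-model PDB or the plain-text XYZT dialect.
* Insertion codes are not treated as distinct residues unless they differ in
  residue number.
* The hydrogen-bond module requires explicit hydrogens; no donor inference.
* FEL landscapes of noisy data contain many shallow local minima; the
  minima report is deliberately unsmoothed.
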