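# Methods

## Model

A single-cell chromosome structure is an ordered sequence of loci
(genomic bins) with 3D coordinates x_i (nm) and a distance SpD_i from each
locus to its nearest nuclear speckle. The working hypotheses are the two
classic regularities of nuclear organisation: loci of the same compartment
are spatially closer to each other than cross-compartment loci at the same
genomic separation, and A (active) loci sit closer to nuclear speckles.

The structure is embedded as an undirected weighted graph. With z_i the
within-cell z-score of SpD_i (population sd; all-zero when the sd is 0) and
g_i the sequence position, the edge weight is

    w_ij = |z_i − z_j| · ‖x_i − x_j‖₂ / √|g_i − g_j| ,

the √gap denominator being the expected polymer scaling of spatial distance
with genomic separation at short range. Edges with ‖x_i − x_j‖₂ > 16·R_bead
are removed (compartments are decided by local structure), and weights are
divided by their maximum so W ∈ [0,1]. Cutting high-weight edges separates
pairs that are unusually far apart *and* differ in speckle association, so
the A/B partition is recovered as the graph's maximum cut. The cut side
with smaller mean speckle distance is A; an exact tie goes to the side
containing node 0 (deterministic, logged).

For intensity-only speckle data, 1/√s converts marker intensity to a
pseudo-distance (quadratic decay assumption); the z-scoring then removes
the overall scale, so the conversion is calibration-free. Non-positive
intensities are floored to the smallest positive reading of the trace.

## Max-cut solver

The relaxation max ¼⟨L, A⟩ s.t. diag(A)=1, A ⪰ 0 is solved by low-rank
coordinate ascent on the factor V (A = VVᵀ, unit-norm rows, rank
⌈√(2n)⌉+1): each row update v_i ← −(WV)_i/‖(WV)_i‖ is the exact block
optimum, and at this rank the non-convex surrogate has no spurious local
optima for generic instances. Convergence is certified, not assumed: from
the stationary point, y_i = (LA)_ii/4 and S = Diag(y) − L/4 give a dual
point after shifting y by the most negative eigenvalue of S, so

    bound = Σy_i − n·min(0, λ_min(S))

is a rigorous upper bound on the SDP optimum (hence on the max cut)
regardless of ascent quality. The solver converges when the primal–dual gap
is below the tolerance (default 1e-6, one automatic retry at 1e-4 from a
fresh start). All reported bounds (weak-duality checks, rounding
thresholds) use this certified bound rather than the primal value.

A is factorized by LDL decomposition with negative diagonal entries clamped
to zero (2×2 pivot blocks are diagonalized before clamping), so a solver
tolerance that leaves A marginally indefinite cannot break the
factorization; the factorization error equals the clamped mass. Rounding
draws standard-normal hyperplanes, labels s_i = sign(v_i·r) (ties to +1),
keeps the best cut, and stops at 0.878× the certified bound — a stricter
threshold than 0.878×OPT, since the bound dominates OPT — or after
max_rounds (default 1000), returning the best cut found with a warning. A
brute-force enumerator (n ≤ 22) serves as the exact oracle in tests and in
the acceptance script, never as the production path.

## Parameters

| parameter | default | meaning |
|---|---|---|
| R_bead | 100 nm (imaging) | bead radius; prune radius is 16·R_bead. For modeled/synthetic structures it must be chosen by the user to match the model's bead size. |
| prune_factor | 16 | edge removal threshold in bead radii |
| tolerance | 1e-6 | SDP primal–dual gap |
| threshold_ratio | 0.878 | rounding stop, relative to the certified bound |
| max_rounds | 1000 | hyperplane draws before giving up on the threshold |
| cutoff_factor (CCS) | 3 | contact radius in bead radii (4 for 3-Mb-resolution imaging loci) |
| R_nuc | 5 µm | nucleus radius for radial positions of modeled structures |
| R_soft | 1000 nm | interchromosomal contact range |
| CG neighborhood | 250 nm | smoothing radius of the CG-phasing baseline |

Genomic gap uses the panel bin index by default; the weight formula is
invariant to uniform rescaling of g (a common factor divides all weights
and the max-normalization removes it), so base-pair units are unnecessary.
A `bp_over_resolution` mode exists for unevenly spaced panels.

## Population statistics

With c_k ∈ {0,1}^N the per-cell calls (1 = A) over K cells:
c_ens = K⁻¹Σc_k; f = c_ens − 1[c_ens < 0.5] (so |f| ≥ 0.5 always — every
bin has a majority compartment); f_norm = c_ens − 0.5; δc is the
population (divide-by-K) sd of the binary calls, identically
√(c_ens(1−c_ens)). Population-sd conventions are used throughout
(δc, z-scores, δSpD, radial variability).

CCS is the fraction of contacts (d ≤ cutoff_factor·R_bead,
sequence-adjacent pairs included by default, excludable by flag) joining
same-compartment loci. DCS is d_intra/(d_intra+d_inter) on *summed*
pairwise distances; a mean-based variant is available behind a flag. Both
are reported missing (NaN), never imputed, for degenerate structures (no
contacts, an empty compartment, all-coincident points).

The transcription ratio drops, per gene, the ⌊5%⌋ of cells with the
smallest transcript count, groups cells by biallelic call at the gene's
bin (both homologs A vs both B; mixed cells are excluded), and reports
log2(t_A/t_B) of the group means — undefined when a group is empty or a
mean is zero.

## Baselines

Distance PCA: population-mean distance matrix, normalized by a log–log OLS
power-law fit of mean distance vs genomic gap, converted to a Pearson
correlation matrix; the leading eigenvector's signs split the bins, and a
single annotation applies to every cell. CG phasing: per cell, each locus's
CG content is averaged over loci within 250 nm in 3D (self included) and
compared to the cell's chromosome mean; positive log fold change calls A
(uniform CG ⇒ all-B, by the strict inequality). Hi-C PCA: leading principal
component of the (by default correlation-transformed) dense matrix's
covariance. Eigenvector sign is arbitrary, so all eigenvector-based callers
are oriented by speckle proximity (A = proximal), falling back to CG
content (A = rich); this is the field's biological reading of A, which the
source of the annotation does not itself provide. Profile comparisons use
Pearson r over bins where both vectors are defined and the prediction is
non-zero.

## Synthetic generator

The generator is a phenomenological two-center model, deliberately not a
polymer simulation: it reproduces exactly the regularities the caller
exploits and nothing else, so recovery demonstrates the method rather than
a shared polymer model. Planted labels follow a two-state Markov chain
(switch probability 0.1 ⇒ ~10-bin blocks). Each cell's trace is an AR(1)
walk: starting from a uniformly random point in the nucleus (territories
sit anywhere; this also guarantees that with pull = 0 the bin index carries
no systematic geometric signal), each bead moves fraction `pull` toward its
compartment's center plus N(0, step_sd²) noise, clipped to the nuclear
sphere. The A and B centers are `separation` apart; speckles are Gaussian
jitter around the A center; measured SpD adds N(0, speckle_noise_sd²).
Per-bead labels flip with probability `label_noise` per cell, which both
creates realistic cell-to-cell variability and caps attainable per-cell
accuracy at ≈ 1 − label_noise.

Defaults (the package's reference study conditions): 60 loci at 200 kb,
100 cells, separation 2000 nm, step_sd 200 nm (typical neighbor-locus
distance at this resolution), pull 0.8, nucleus radius 3000 nm, 3 speckles
with 200 nm jitter, 100 nm SpD noise, label noise 0.05, Poisson transcript
rates 10 (A) / 2 (B). The generated beads are modeled structures, so the
config carries its own bead radius (r_bead = 200 nm) to be passed to graph
construction and contact scoring. What the generator does *not* emulate:
TADs/loops, polymer connectivity constraints, interleaved multi-blob
compartments, imaging detection dropout beyond what the interpolation tests
construct, and realistic Hi-C maps — so passing tests shows the algorithm
recovers planted structure under its own assumptions, not that those
assumptions hold in any particular real dataset.

All randomness derives from a single seed via spawned substreams (per cell,
labels, speckles, counts), making populations bit-reproducible; the
analysis pipeline separately derives one rounding seed per trace from its
base seed.

## Numerical choices and degenerate inputs

Missing coordinates/tracks are linearly interpolated along the bin index;
leading/trailing gaps copy the nearest observed value (no extrapolation);
traces with <2 observed loci are rejected; one failing trace never aborts a
population run. Constant speckle distances zero every edge weight and raise
a degenerate-graph error naming the cause (the formula is kept verbatim;
an epsilon_z guard exists for pathological inputs but defaults to 0).
Pruned edges do not participate in the max-normalization. Distances are nm
internally; readers convert µm inputs (FOF-CT convention, or a units header).

## Known limitations

The per-trace z-scoring of speckle distances (rather than population-wide)
is a choice the underlying procedure leaves open; it is robust to per-cell
imaging batch effects but makes cells with genuinely shifted speckle
geometry indistinguishable from batch variation (a config switch selects
population-wide scoring). The SDP ascent certificate makes silent
convergence failure impossible, but on adversarial graphs the ascent may
need its restart to close the gap. The Hi-C utility performs no matrix
balancing; supply a normalized matrix. Problem sizes: everything here is
exercised at ≤ 60-node graphs and ≤ 400 traces, where a full population run
takes seconds; the solver scales as O(n²·√n) per sweep and handles
hundreds of nodes comfortably, but has not been profiled beyond that.
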