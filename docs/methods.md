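# Methods

## Scope and units

The package analyses (biased + unbiased) sampling of a conformational
transition into three artifacts: a minimum-energy path between two endpoint
configurations, a multi-ensemble Markov model (MEMM) with microstate free
energies and macrostate switching kinetics, and a ranked critical-residue
table from dynamic-network analysis.  Internally kT = 1 and time is counted
in integration steps / lag frames; physical units (kcal/mol, ns, Å) exist
only as metadata the caller attaches (`KT_TO_KCAL_PER_MOL = 0.5924847`
kcal/mol per kT at 298.15 K is provided for display).

## Synthetic dynamics (`toysim`)

The generators emulate the statistical structure of an MD study without
atomistic force fields:

* **Potentials**: quartic double wells (1-D, tilted, 2-D with harmonic
  confinement), a 2-D triple well, and a four-Gaussian surface with two
  saddle points scaled so barriers are a few kT.  Declared minima of the
  2-D families are polished to stationarity at construction.
* **Dynamics**: overdamped (Brownian) Euler–Maruyama,
  `x ← x − D∇(U+b)Δt/kT + √(2DΔt) ξ`.  An underdamped integrator is not
  needed because every downstream estimator consumes only stationary and
  lag-τ statistics.  The scheme's stationary density carries an O(Δt)
  bias; the defaults (Δt = 0.005 at barrier curvature ~10 kT/unit²) keep
  that bias well below the statistical resolution of the tests, and the
  χ²-stationarity check runs at Δt = 0.0025 where it is undetectable at
  the sample sizes used.
* **Umbrella windows**: one harmonic bias per center, each walker seeded
  at its own center (the reproducible choice; per-window re-equilibration
  is not modelled).  A warning fires when neighbor spacing exceeds
  4·√(kT/k), the practical overlap limit.
* **Random streams**: every trajectory draws from its own
  `SeedSequence(seed).spawn` substream keyed by trajectory index, so adding
  trajectories never reshuffles existing ones; identical inputs give
  bit-identical output.
* **Network fixtures**: pseudo-residues move as a community-shared latent
  displacement plus node noise (same-community correlation is
  latent²/(latent²+noise²) by construction), communities are placed far
  apart, and a backbone chain from source to sink is laid out at 0.6× the
  contact cutoff with its own shared latent, making it both persistently
  connected and strongly correlated — the planted communication route.
  Conservation is planted at 1.0 on backbone nodes, U(0, 0.4) elsewhere.
* **Saddle oracle**: lowest saddle between two minima by threshold
  union-find over a dense energy grid (minimax level), refined by local
  minimization of |∇U|².  This is deliberately a different algorithm from
  the band optimizer it validates.

What the fixtures do **not** emulate: anharmonic cross-correlations between
collective coordinates, solvent memory/friction anisotropy, force-field
error, and conformational states not reachable from the seeded path.
Passing tests therefore demonstrate the correctness of the estimators, not
the adequacy of any particular MD sampling design.

## TICA (`featspace`)

Features are contact-selected inter-point distances (one representative
point per residue; pairs within the cutoff in at least one sampled frame;
annotated base-pair opening distances may be appended).  The TICA estimator
is symmetrized: with mean-free pooled data (pooled mean over all frames of
all trajectories, lagged pairs formed only within trajectories),
`C(0) = (X₀ᵀX₀ + XτᵀXτ)/2N` and `C(τ) = (X₀ᵀXτ + XτᵀX₀)/2N`, so
`C(0) ± C(τ)` are Gram matrices and all generalized eigenvalues are real in
[−1, 1] by construction.  `reg` is added to the diagonal of C(0); a
singular C(0) raises with the instruction to raise `reg`.  Component signs
are fixed by making the largest-magnitude loading positive.  Lag selection
stays manual; `implied_timescales` is the supporting diagnostic.

## Microstates (`microstates`)

k-means with k-means++ seeding and a fixed seed (Lloyd iterations via
scikit-learn); stored state sequences are produced by the package's own
nearest-center assignment so the documented tie rule (lowest index) holds
exactly.  Transition counting is sliding-window by default (all (t, t+τ)
pairs within a trajectory, never across trajectories or ensembles);
strided counting is available for independence checks.

## TRAM (`memm`)

The discrete TRAM estimator: per-ensemble reversible transition matrices
coupled to per-frame reduced bias energies `b^k(x)` through local free
energies `f_i^k`, Lagrange multipliers `v_i^k`, and unbiased per-frame
weights `μ(x)`.  The self-consistent updates (log-space throughout) are

    v_i^k ← Σ_j CS_ij^k v_i^k e^{−f_j^k} / (v_i^k e^{−f_j^k} + v_j^k e^{−f_i^k}),
    R_i^k = Σ_j CS_ij^k v_j^k e^{−f_i^k} / (v_i^k e^{−f_j^k} + v_j^k e^{−f_i^k})
            + N_i^k − Σ_j c_ji^k,
    μ(x)  = 1 / Σ_k R_{i(x)}^k exp(f_{i(x)}^k − b^k(x)),
    e^{−f_i^k} ← Σ_{x∈i} e^{−b^k(x)} μ(x),

with `CS = c + cᵀ` the symmetrized counts and `N_i^k` the number of frames
of ensemble k in state i (so `N − Σ_j c_ji ≥ 0` counts frames that are not
lagged-pair endpoints).  These are the stationarity conditions of the
joint likelihood; the leftover term must use *incoming* pairs — using
outgoing pairs instead produces a fixed point that deviates from the
single-ensemble reversible-MSM limit whenever per-state in/out pair counts
are imbalanced by trajectory boundaries, an error mode the reduction test
pins down.

Numerical choices:

* **Connectivity**: (state, ensemble) pairs are nodes; edges join pairs
  with reversible counts within an ensemble and the same state sampled in
  two ensembles.  The component with the most samples is kept; samples
  whose generating (state, ensemble) pair falls outside it are dropped.
* **Convergence** is declared on the maximum change of all `f_i^k`, of
  `log R_i^k`, and of the per-ensemble transition matrices (default tol
  1e-8, max_iter 100 000).  The raw multipliers are excluded on purpose:
  at boundary solutions (states whose counts cannot support their weight
  in some ensemble) individual `v` drift toward zero geometrically
  forever, while every quantity entering the model converges.
* **Gauge**: the equations fix f only up to a constant; after convergence
  all free energies are shifted so that Σ_x μ(x) = 1, making the unbiased
  stationary vector `π_i ∝ e^{−f_i}` sum to 1 exactly.
* **Transition matrices** are built from the symmetric flow matrix
  `X_ij = CS_ij e^{−f_i−f_j}/(v_i e^{−f_j} + v_j e^{−f_i})` row-normalized,
  so row-stochasticity and detailed balance hold to machine precision by
  construction.
* The per-sample update runs in linear space with one scalar scale
  (bias energies are ≥ 0, so the sample weights are bounded), grouping
  samples by state with segmented reductions; cost per sweep is
  O(N_samples·K + K·n²).

`estimate_reversible_msm` is the single-ensemble special case (fixed-point
iteration on symmetric flows, largest strongly connected component) and
doubles as the internal reduction oracle.  The free-energy surface is
`ΔG(bin) = −kT ln Σ μ(x)` over IC-space bins, empty bins masked, reference
region shifted to 0.

## PCCA+ (`macro`)

Dominant right eigenvectors are obtained from the π-symmetrized matrix (so
they are real for reversible input); the inner-simplex vertex search gives
the initial transformation A, which is made feasible (non-negative
memberships, rows summing to 1) and then refined by maximizing the
Roeblitz–Weber crispness `trace(diag(1/A[0,:]) AᵀA)` (Nelder–Mead over the
free block, feasibility re-imposed each evaluation, candidates accepted
only when crispness improves and memberships stay non-negative).
Macrostates are ordered by descending crisp population, ties by first
member index, giving a stable S1…Sm naming; every macrostate is guaranteed
non-empty under crisp (argmax, lowest-index-tie) assignment.  m is a config
choice; the eigenvalue spectrum is the user's guide.

## Kinetics and bootstrap (`kinetics`)

Committors solve `q = Tq` with q = 0 on A, 1 on B; MFPTs solve
`m = τ + Tm` with m = 0 on B.  Macrostate MFPT(A→B) weights source states
by the stationary distribution restricted to A (the transition-path-theory
convention).  All linear solves are dense; systems here are small.

Statistical inefficiency: `g = 1 + 2 Σ_t (1 − t/n) ρ(t)` with the
autocorrelation sum truncated at the first non-positive value
(initial-positive-sequence convention), clipped to ≥ 1; a constant series
is reported as g = n (fully correlated).

Bootstrap: each sample redraws whole unbiased trajectories with
replacement and rebuilds each biased trajectory from stationary-bootstrap
blocks (geometric lengths, mean = `min_block_length`, wrap-around within
the source trajectory; bias-energy rows are resampled in sync).  One full
estimation runs per sample — TRAM when several ensembles are present,
reversible MSM otherwise, then optional PCCA+ whose macrostates are
aligned to the point-estimate model by Hungarian matching on membership
overlap (without alignment, percentile intervals over samples would mix
labels and be meaningless).  Intervals are percentile (5th/95th default);
failed samples are dropped and counted.  `min_block_length` is set from
the mean statistical inefficiency of the biased discrete trajectories.

## Band optimization (`pathopt`)

Improved-tangent (energy-weighted) NEB forces: the physical force with its
tangent-parallel component removed plus a spring force
`k(|R_{i+1}−R_i| − |R_i−R_{i−1}|)` along the tangent, applied on a
configurable active coordinate subset (the "partial" variant — inactive
coordinates feel only the physical force); fixed endpoints receive zero
force and never move (bit-exact).  Optimization follows annealing cycles
of (heat k=20, hold k=10, cool k=20) stages; finite-temperature stages are
overdamped Langevin on the band forces, 0 K stages steepest descent with a
per-step displacement cap (default 0.05).  At toy scale the cool stage is
stretched (5× the heat stage by default) so each cycle ends fully relaxed.
Convergence is the maximum per-replica RMSD between successive cycles over
active coordinates, with coordinates grouped into points (≤ 3 active
coordinates = one point, else triples); the default threshold is 0.3
length units.  Climbing-image NEB is out of scope, so the saddle is
resolved only to the replica spacing — the long cool stages and 32
replicas put the maximum-energy replica within ~0.01 energy units of the
grid-search saddle on the bundled surfaces.

## Network scoring (`netscore`)

Correlations are Pearson coefficients of displacement vectors after
two-pass Kabsch superposition onto the mean structure (linear mutual
information is a known alternative; Pearson is used for testability).
Edges require contact persistence ≥ threshold (default 0.75) at cutoff
(default 5 length units) and carry weight `−ln|c_ij|` with |c| floored at
1e-12 and capped at 1.  All-pairs shortest paths use Floyd–Warshall
(SciPy's csgraph implementation behind the module surface; an independent
Dijkstra is the test oracle).  Suboptimal paths are enumerated best-first
with an admissible distance-to-sink bound, so output order is (length,
lexicographic) and a `max_paths` cap (default 150 000) keeps the shortest
paths.  Usage scores are per-macrostate path fractions averaged over
macrostates then min–max normalized; contact persistence to the partner
group is summed over macrostates then min–max normalized; the combined
score is the unweighted sum of the three [0, 1] components (weights
exposed), ranked with ties broken by usage then node id, top-k (default
16) flagged.  An ambiguity is preserved deliberately: a single geometric
"distance cutoff" in path analysis can mean an edge-formation limit or a
path-length dilation — both are separate parameters here and no claim is
made about reproducing any particular published setting.

## Pipeline (`app`)

A strict-validation (unknown keys rejected, global seed mandatory) JSON
config with one block per stage; stages communicate only through
serialized artifacts in the run directory (.npz array containers with JSON
metadata blocks, CSV/TSV reports), so each CLI subcommand can run alone.
The manifest records the config hash and per-stage output checksums;
deterministic stages reproduce identical checksums for identical
config + seed.  MD-format trajectories enter through mdtraj and are
reduced to one representative point per residue (backbone phosphorus for
nucleotides, C-α for amino acids).

## Problem sizes

Default study conditions for the synthetic end-to-end analyses: double-well
TRAM uses 2 unbiased + 8 umbrella trajectories of 10⁵ dynamics steps each
(frames saved every 10 steps), 30 microstates, lag 10 frames; planted-block
chains use 10⁶ total steps; TICA recovery uses 10⁵ frames; network
fixtures use 60 nodes × 5000 frames; bands use 32 replicas.  The nested
bootstrap-coverage experiment uses 200 replications × 200 bootstrap
samples of 50 short trajectories.

## Known limitations

* Continuous-bias/binless multi-ensemble estimators (MBAR-style hybrids)
  are not implemented; bias energies must be evaluable per frame per
  ensemble.
* Kinetic quantities come from the unbiased ensemble's transition matrix
  only; TRAM transfers thermodynamic, not kinetic, information across
  ensembles.
* PCCA+ optimization is local (inner-simplex start); for strongly
  overlapping macrostates the crisp labels can depend on the spectrum's
  conditioning.
* The band optimizer has no climbing image, so saddle energies are
  resolved to the replica spacing.
* Bootstrap intervals are percentile intervals; no BCa or normal-theory
  correction.
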