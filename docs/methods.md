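# Methods

This note records the model, the algorithms, the numerical choices, and
the limitations of `motiflattice`, at the level of detail a user needs
to judge what a passing test suite does and does not demonstrate.

## Model and conventions

Polymers of `L` motifs over {A, B} occupy a periodic FCC lattice in
primitive-vector indexing: every integer triple is a site, the twelve
neighbors are the fixed offsets ±(1,0,0), ±(0,1,0), ±(0,0,1),
±(1,−1,0), ±(0,1,−1), ±(1,0,−1), and a 30×30×30 box has exactly 27000
sites.  Cartesian geometry (for radii of gyration) uses primitive
vectors (1,1,0)/√2, (0,1,1)/√2, (1,0,1)/√2, so the nearest-neighbor
distance is one monomer length.

A site holds at most two monomers and never two of the same type; a
site holding one A and one B carries a specific bond (q = 1).
Consecutive monomers of a chain are either adjacent or co-resident
(a "contiguous" bond).  The Hamiltonian is

    H = −ε Σ_i q_i − J Σ_⟨ij⟩ r_i r_j ,

with all adjacent site pairs contributing to the nonspecific term,
*including* pairs formed by consecutive monomers of one chain: the
model text gives no exclusion, the intra-chain contribution is nearly
constant, and it is absorbed into the working μ scale.  Energies are
reported in units of ε, temperatures as βε, chemical potentials as μ/ε;
μ is the shifted value in which the ideal-chain entropy ln(z+1)^{L−1}
is carried by the (z+1)^{L−1} factors of the insertion/deletion
acceptance probabilities.  The volume fraction is φ = N·L/V ∈ [0, 2].

Defaults that define the study conditions: J = 0.05 ε; 30³ production
lattice for the published-scale anchor; initialization with randomly
placed straight chains (N₀ = 100 by default); simulated-annealing ramp
(10 geometric stages from β/2, 10% of the steps) followed by
production of which the first 20% is discarded.

## Monte Carlo engine

The kernel (numba-compiled) holds the microstate in flat arrays and
tracks the energy as two integers — the bonded-site count Q and the
adjacency pair sum W = Σ_⟨ij⟩ r_i r_j — so the cached energy −Q − J·W
is exact, with no floating-point drift; a from-scratch validator
(`LatticeConfig.validate`) recomputes both after runs.

Move set and detailed balance:

* **end / corner / reptation** — standard local chain moves with
  symmetric proposals (corner candidates are the common neighbors of
  the two flanking sites; reptation draws one of 13 extensions of the
  leading end, including the stay-and-bond option).
* **contraction / expansion** — a consecutive A-B pair collapses onto
  one site or separates into one of the 12 directions.  Twelve expanded
  states feed any one contracted state, so expansions are proposed at
  exactly 12× the contraction rate (enforced by the `MoveMixture`
  invariant); the specific-state proposal probabilities then match and
  the acceptance is plain Metropolis.
* **cluster translation** — a bond-connected cluster moves by one
  lattice vector, rejected outright if any bond would form or break
  (breaking is impossible by construction; forming means an external
  occupant sits on a target site).  Clusters larger than a cap
  (default 64 polymers) are rejected outright; the rejection is
  symmetric in both directions, so detailed balance is untouched —
  this is purely an efficiency device for the dense phase.
* **insertion / deletion** — configurational-bias growth: each
  continuation is drawn uniformly from the allowed set (12 neighbors
  plus the same-site bond option), the Rosenbluth weight R = Π W_k
  enters the acceptance together with V/(N+1) and (z+1)^{L−1}, and
  deletions retrace the stored conformation with the not-yet-placed
  tail removed, so delete-after-insert reproduces R exactly.

One Monte Carlo "step" is one elementary proposal.  Default mixture:
equal weight to the end/corner/reptation/cluster/(contraction+expansion)
blocks within 90%, insertions and deletions 5% each; phase-boundary
drivers raise the insertion/deletion fraction to 30% because the
polymer-number random walk is the slow direction there.

Histograms P(N, E) are accumulated on an (N, energy-bin) grid (bin
width automatic, ≥0.25 ε) with all collection metadata (β, μ, h) stored
for reweighting; trajectories record per-snapshot aggregates of
per-polymer self-bonds, trans-bonds and radii of gyration.

The engine is validated end-to-end against exact grand-canonical
enumeration on tiny systems: the hard-core monomer gas on 3³ (P(N)
χ² p ≈ 0.5) and AB dimers on 4³ (joint P(N, E), including the
unordered-configuration bookkeeping).

## Phase analysis

Reweighting is the exact identity
P̃(N,E) ∝ P(N,E)·exp(−Δβ·E + Δ(βμ)·N + β₀h₀(N) − β₁h₁(N)), with an
effective-sample-size diagnostic.  The phase boundary μ* at a given β
is the root of equal mixture weights of a two-component Gaussian fit to
P(N) (weighted EM; candidate crossings are filtered by Ashman's
separation and a minimum density gap between components, because EM on
a single-phase histogram happily fits two overlapping components).

The critical point is located by minimizing the L2 distance between
the standardized distribution of the mixed order parameter M = N − xE
and the universal 3D-Ising order-parameter distribution over
(β, μ, x), inside an explicit reweighting trust region.  The reference
is shipped as a tabulated text asset
(`data/ising3d_orderparam.tsv`), generated from the closed-form fit
p(y) ∝ exp[−(y²/y₀² − 1)² (a y²/y₀² + c)] with a = 0.158, c = 0.776
(Tsypin & Blöte, Phys. Rev. E 62, 73 (2000)), standardized to unit
variance; a symmetric double-Gaussian surrogate is available for smoke
tests, and the asset can be replaced by any other tabulation.

**Search drivers.**  Finding where to simulate is the hard part at
desk scale, and the package provides three tools with different
cost/rigor trade-offs:

1. `condensation_onset` — cloud-point cooling: the system is cooled
   stepwise (warm starts) with μ pinned to the sequence's ideal-dilute
   line at a reference density (default φ_ref = 0.03, chosen dilute
   enough that the reference is unambiguous but dense enough that
   condensation occurs within the window); the onset is where the
   relaxed density jumps through 0.4.  At a fixed per-step budget this
   pseudo-critical temperature is slightly cold-biased (nucleation
   delay) but extremely reproducible (replicate sd ~0.3% at the
   default budget), which makes it the right instrument for *comparing*
   sequences: for L=12 blocks on 16³ it strictly orders
   T(ℓ=2) < T(ℓ=3) < T(ℓ=6) in every replicate.
2. `locate_critical_point` — cloud-point bracketing followed by
   iterative multicanonical flattening at the onset point (where the
   inter-phase barrier is still small), then equal-weight analysis and
   the universal-distribution match.  Replicates for the ℓ=3, L=12
   sequence on 16³ give β_c = 1.005/0.990 (≈1.5% scatter).
3. `mu_star_by_integration` — thermodynamic integration of the grand
   potential around the critical point, for temperatures where the
   transition is strongly first order and direct two-phase sampling is
   hopeless at desk budgets.  d lnΞ/dμ = β⟨N⟩ along isotherms and
   d lnΞ/dβ = ⟨−H + μN⟩ along iso-μ paths; the dilute branch is
   integrated directly from a near-ideal anchor, the dense branch is
   anchored through a supercritical isotherm plus cooling on the
   dense side, and μ* is the crossing of the two branch grand
   potentials.  For the ℓ=3, L=24 sequence on 30³ at βε = 0.9287 this
   reproduces the published μ* to well under 1% with ~5×10⁷ total
   steps (replicate scatter ≈ 0.005 ε).

`flatten_multicanonical` implements the classic recursion — run under
h(N), replace h by (1/β)·log of the multihistogram-combined estimate of
the true distribution (all passes at the same μ, WHAM-merged with the
first cold-start pass dropped), extend h past the coverage edges with
the local slope, warm-start each pass — and reports a barrier diagnosis
via the upper concave hull of log P(N) (a tilt-invariant measure of the
inter-phase barrier, boxcar-smoothed so sub-kT statistical wiggles do
not register as wells).

`trace_binodal` descends the phase boundary iteratively exactly as in
the published workflow: reweight the previous histogram to the next β,
build h(N) = log P̃(N)/β over the barrier region between the fitted
peaks, rerun multicanonically, remove h by reweighting, and record
(μ*, φ_dilute, φ_dense).

## Single-polymer density of states

g(s) counts conformations with s self-bonds, modulo translation
(rotations distinct), on open coordinates — a single chain cannot wrap.
Exact enumeration covers L ≤ 7 within the default branch budget
(≤13^{L−1} branches).  The Monte Carlo estimator runs canonical
single-chain simulations (conformational moves only, bond term only —
the nonspecific J term is irrelevant for a lone chain's density of
states) on a β grid (default geomspace(0.3, 2.4, 8), chosen once for
s-coverage of L=24 block sequences at the temperatures where phase
behavior is analyzed), combines them by the self-consistent
multihistogram method (tolerance 1e−10), and fixes the absolute scale
with a Rosenbluth sequential-importance-sampling estimate of the total
conformation count, which is exact in expectation.  For every L ≤ 6
block sequence the estimate agrees with exhaustive enumeration within
5% on each supported s at the default test budget.

## Mean-field theory

The free energy density per site, in units of k_BT, of a state with s̄
self-bonds and t̄ trans-bonds per polymer:

    f = f_steric + f_trans + βχφ²
        − (φ/L)·log Σ_s g(s)e^{ws} + (φ/L)·w·s̄ − (φ/L)·βε·(s̄ + t̄/2),

    f_steric = (φ/L)log(φ/L) + (1 − φ⟨l⟩/L)log(1 − φ⟨l⟩/L)
               + (φ/L)(⟨l⟩ − 1),     ⟨l⟩ = L − s̄ − t̄/2,
    f_trans  = (φ/L)[y(a) + y(b) + (t̄/2)log(t̄/2) + (t̄/2)(1 − log(φ/L))],
    y(x)     = (x − s̄ − t̄/2)log(x − s̄ − t̄/2) − (x − s̄)log(x − s̄),

with w the self-bond weight solving ⟨s⟩_w = s̄ (bracketed root-finding
on a strictly increasing map, tolerance 1e−12; at the support edges
the Legendre pair converges to log g at the edge).  χ is the full
coefficient of the βχφ² term; `chi_from_j` supplies the mean-field
conversion χ = −J·z/2 per site volume.  s̄ and t̄ are continuous;
infeasible states return +∞ rather than raising.

Numerics: the inner (s̄, t̄) minimization runs on a broadcast grid for
all densities at once, followed by a vectorized six-level zoom around
each density's optimum (equivalent to per-point Nelder–Mead at ~10× the
speed); the φ grid is log-dense near zero (default 2000 points, capped
at φ = 1.6 unless the sequence's steric limit allows more).  Phase
coexistence comes from the lower convex hull of f(φ) polished by
root-solving the equal-slope/equal-intercept equations on a cubic
spline (residuals ≈ 1e−11, asserted < 1e−8 in tests); the critical
point from bisection in β on the sign of the minimal curvature of
f(φ) on a uniform grid.

With Monte Carlo g(s) for the L = 24 block family, the mean-field T_c
rises strictly with block size ℓ ∈ {2, 3, 4, 6, 12}.  Rescaling the
binodals by (T_c, φ_c) collapses them dramatically — unrescaled dense
branches differ by 30–50%, rescaled ones by about 6–7% (max−min
relative to the mean over the five sequences, dense branch,
T/T_c ∈ [0.8, 0.9], with the critical point extracted by a joint fit
of both near-critical branches to φ± = φ_c + D·(1−T/T_c) ±
B·√(1−T/T_c)).  The residual spread is dominated by a genuine ~7%
variation of the amplitude ratio B/φ_c across sequences — mean-field
scaling amplitudes are not universal — so the collapse is close but
not exact; the corresponding acceptance test asserts a 5% bound and is
expected to fail by this margin.

## Condensation parameter and material properties

Ψ uses the uncorrected default ⟨P_corr⟩ = 1/4 (the factor 4·P_corr is
then exactly 1), so it is computable from g(s) and stoichiometry alone;
`estimate_pcorr` measures the correlation metric from dense-phase
snapshots as the fraction of trans-bonded motifs whose chain neighbor
is also trans-bonded to the same partner polymer.  A least-squares line
maps Ψ to T_c given reference (Ψ, T_c) pairs; random-sequence scans
default to short multihistogram g(s) estimates, with a fast
combinatorial surrogate (independent A-B contacts weighted by the
3D-random-walk loop-closure factor |i−j|^{−3/2}, scale set by a
Rosenbluth total) available for large scans.  Viscosity and
diffusivity are scaling estimates in reduced units (τ₀ = m = 1):
η = (φ/m³L)·τ₀e^{βε}·t̄² and D ∝ 1/t̄; no absolute calibration is
attempted.

## What the tests show — and what they do not

The suite validates: exact geometry and combinatorics; exact energy
bookkeeping; detailed-balance factors by enumeration; equilibrium
correctness of the full engine against brute-force partition sums on
tiny systems; g(s) recovery against exhaustive enumeration; the
equal-weight and reweighting identities on synthetic histograms with
closed-form answers; the published phase-boundary anchor
μ*(βε = 0.9287) ≈ −9.92 ε at the full 30³ scale (scaled down in steps,
not in system size); and the ordering of critical temperatures with
block size at a scaled-down system size (L = 12, 16³).

Not demonstrated at test scale: full-scale critical points and
binodals of L = 24 sequences with publication-level statistics (the
published runs used ~4.5×10⁸ steps per state point with three
replicates; the tests run 10²–10³× fewer), the magnitude (as opposed
to sign and ordering) of the T_c spread between block sequences, and
any off-lattice behavior.  The cloud-point T_c estimator carries a
systematic cold bias at fixed budget; it is used only where ordering,
not absolute location, is asserted.  Dense-phase property estimates
(viscosity, diffusivity) are scaling relations, compared only across
sequences.
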