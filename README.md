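# motiflattice

Lattice polymers with specific, saturating, heterotypic binding motifs:
a grand-canonical Monte Carlo engine with multicanonical sampling and
histogram reweighting for phase diagrams of biomolecular condensates,
together with the companion sticker–spacer mean-field theory, a
sequence-level condensation score, and dense-phase material-property
estimators.

## The model

Many intracellular condensates form through *specific* one-to-one
interactions (SH3–PRM, SIM–SUMO, tyrosine–arginine contacts, RNA base
pairing) rather than generic electrostatics.  `motiflattice` studies
the minimal model of this situation: polymers of `L` motifs, each of
type A or B, live on a periodic FCC lattice (coordination number
z = 12).  An A and a B on the same site form a saturating bond of
energy −ε; monomers on adjacent sites attract weakly and nonspecifically
with energy −J (default J = 0.05 ε); two A's or two B's may never share
a site.  With site bond occupancy qᵢ ∈ {0,1} and motif occupancy
rᵢ ∈ {0,1,2},

    H = −ε Σᵢ qᵢ − J Σ_⟨ij⟩ rᵢ rⱼ .

Sampling is grand canonical: conformational moves (end, corner,
reptation, contraction/expansion of contiguous bonds at a 12:1
proposal ratio, cluster translations) plus configurational-bias
insertion/deletion with Rosenbluth weights R = Π Wₖ, using the shifted
chemical-potential convention in which the ideal-chain entropy
ln (z+1)^{L−1} is absorbed into the acceptance probabilities.
Multicanonical weights h(N), exact histogram reweighting of P(N, E),
equal-weight Gaussian-mixture analysis, and matching of the order
parameter N − xE against the universal 3D-Ising distribution yield
phase boundaries (μ*, φ_dilute, φ_dense) and critical points
(β_c, μ_c, φ_c).

The mean-field companion evaluates the free energy density f(s̄, t̄) of
a state with s̄ self-bonds and t̄ trans-bonds per polymer, built on the
single-polymer density of states g(s) (exact enumeration for short
chains, multihistogram Monte Carlo for long ones), and produces binodals
by common-tangent construction.  The condensation parameter

    Ψ = −log[ (r_A^−b r_B^−a) Σ_s g(s) (4⟨P_corr⟩)^{s/2} ]

ranks arbitrary sequences by their critical temperature, and dense-phase
viscosity/diffusivity follow reversible-crosslink scaling
η ∼ (φ/m³L) τ₀ e^{βε} t̄² and D ∼ 1/t̄.

## Worked example

Locate the critical point of the ℓ=3 block sequence of twelve motifs
(AAABBB AAABBB) on a 16³ lattice:

```python
from motiflattice import FccLattice, make_block_sequence
from motiflattice.montecarlo import RunParams
from motiflattice.phase_analysis import GceRunner, locate_critical_point

runner = GceRunner(FccLattice((16, 16, 16)), make_block_sequence(12, 3),
                   RunParams(beta_eps=1.0, mu_over_eps=0.0, seed=101,
                             sample_every=100))
cp, hist = locate_critical_point(runner, 0.80, 1.30, d_beta=0.02)
print(f"beta_c = {cp.beta_c:.3f}, mu_c = {cp.mu_c:.3f}, "
      f"phi_c = {cp.phi_c:.3f}, x = {cp.x:.3f}")
```

prints (about twenty seconds on one core)

```
beta_c = 0.967, mu_c = -6.438, phi_c = 0.409, x = 0.000
```

i.e. this sequence demixes below T_c ≈ 1.03 ε/k_B at a critical monomer
volume fraction of about 0.41, and the mixing parameter of the Ising
order parameter is negligible for this system size.  The same workflow
with longer sequences reproduces the published phase boundary of the
ℓ=3, L=24 sequence on a 30³ lattice: at βε = 0.9287 the dilute and
dense phases exchange stability at μ* ≈ −9.92 ε.

A command-line workbench mirrors the library:

```bash
motiflattice gs --sequence AB --method exact     # prints: 0 12 / 1 1
motiflattice simulate --sequence AABB --lattice-dims 8,8,8 \
    --beta-eps 1.0 --mu-over-eps -6 --steps 2000000 --out hist.txt
motiflattice critical-point --sequence AAABBBAAABBB --lattice-dims 16,16,16
```

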