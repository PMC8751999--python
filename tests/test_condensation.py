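import numpy as np
import pytest

from motiflattice import FccLattice, LatticeConfig, MotifSequence
from motiflattice.condensation import (PsiInputs, PsiTcFit, ViscosityInputs,
                                       approx_gs_combinatorial,
                                       diffusivity_proxy, estimate_pcorr,
                                       fit_tc_vs_psi, pcorr_config, psi,
                                       scan_random_sequences, viscosity)
from motiflattice.sequences import make_block_sequence
from motiflattice.single_polymer import DensityOfStates, enumerate_gs_exact


def toy_g(vals):
    return DensityOfStates("toy", np.arange(len(vals)), vals)


# -- Psi -------------------------------------------------------------------

def test_psi_degenerate_value():
    val = psi(PsiInputs(g=toy_g([1.0]), a=12, b=12))
    assert val == pytest.approx(-24 * np.log(2), rel=1e-12)


def test_psi_monotone_in_g():
    base = psi(PsiInputs(g=toy_g([10.0, 2.0]), a=12, b=12))
    bigger = psi(PsiInputs(g=toy_g([10.0, 3.0]), a=12, b=12))
    assert bigger < base


def test_psi_stoichiometry_imbalance_lowers_psi():
    g = toy_g([1.0])
    balanced = psi(PsiInputs(g=g, a=12, b=12))
    imbalanced = psi(PsiInputs(g=g, a=16, b=8))
    assert imbalanced < balanced


def test_psi_ab_relabeling_invariance():
    g = toy_g([50.0, 10.0, 1.0])
    assert psi(PsiInputs(g=g, a=16, b=8)) == pytest.approx(
        psi(PsiInputs(g=g, a=8, b=16)), rel=1e-12)


def test_psi_pcorr_quarter_cancels_factor():
    """At P_corr = 1/4 the correlation factor is exactly 1."""
    g = toy_g([50.0, 10.0, 1.0])
    val = psi(PsiInputs(g=g, a=4, b=4, p_corr=0.25))
    expected = -(np.log(g.g.sum()) - 4 * np.log(0.5) - 4 * np.log(0.5))
    assert val == pytest.approx(expected, rel=1e-12)


def test_psi_single_type_errors():
    with pytest.raises(ValueError):
        psi(PsiInputs(g=toy_g([1.0]), a=24, b=0))


# -- P_corr ----------------------------------------------------------------

def test_pcorr_fully_zipped_is_one():
    lat = FccLattice((8, 8, 8))
    # chains of ABAB / BABA zipped in register: every monomer bonded to
    # the partner, every chain neighbor bonded to the same partner
    u = int(lat.ravel(2, 2, 2))
    chain = [u]
    for _ in range(3):
        chain.append(int(lat.neighbors(chain[-1])[0]))
    seq = MotifSequence("ABAB")
    cfg = LatticeConfig(lat, seq)
    cfg.add_polymer(chain)
    # second polymer occupies the same sites with complementary types:
    # reversing an even alternating chain flips every type
    cfg.add_polymer(chain[::-1])
    assert pcorr_config(cfg) == 1.0


def test_pcorr_isolated_bond_is_zero():
    lat = FccLattice((8, 8, 8))
    u = int(lat.ravel(2, 2, 2))
    c1 = [u]
    for _ in range(3):
        c1.append(int(lat.neighbors(c1[-1])[0]))  # straight along dir 0
    cfg = LatticeConfig(lat, MotifSequence("ABAB"))
    cfg.add_polymer(c1)
    # second chain shares only the head site: its B sits on c1's head A,
    # the rest runs off in another direction -> one isolated trans-bond
    w = int(lat.neighbors(u)[7])
    x = int(lat.neighbors(u)[9])
    y = int(lat.neighbors(x)[9])
    cfg.add_polymer([w, u, x, y])
    assert pcorr_config(cfg) == 0.0


def test_estimate_pcorr_planted_average():
    lat = FccLattice((8, 8, 8))
    u = int(lat.ravel(2, 2, 2))
    chain = [u]
    for _ in range(3):
        chain.append(int(lat.neighbors(chain[-1])[0]))
    zipped = LatticeConfig(lat, MotifSequence("ABAB"))
    zipped.add_polymer(chain)
    zipped.add_polymer(chain[::-1])
    # zipped snapshot has 4 trans-bonded motif pairs with metric 1;
    # a snapshot with no bonds is skipped
    empty = LatticeConfig(lat, MotifSequence("ABAB"))
    val = estimate_pcorr([zipped, empty, zipped])
    assert val == 1.0
    with pytest.raises(ValueError):
        estimate_pcorr([empty])


# -- Psi -> T_c fit --------------------------------------------------------

def test_fit_exact_line():
    fit = fit_tc_vs_psi([(-10, 1.0), (-5, 1.5), (0, 2.0)])
    assert fit.alpha == pytest.approx(0.1)
    assert fit.gamma == pytest.approx(2.0)
    assert np.allclose(fit.residuals, 0)
    assert fit.predict(-8) == pytest.approx(1.2)


def test_fit_degenerate_errors():
    with pytest.raises(ValueError):
        fit_tc_vs_psi([(-5, 1.0), (-5, 2.0)])
    with pytest.raises(ValueError):
        fit_tc_vs_psi([(-5, 1.0)])


# -- scans -----------------------------------------------------------------

def test_scan_empty_and_deterministic():
    est = lambda seq, i: toy_g([1.0, 0.5])
    assert len(scan_random_sequences(0, 24, 12, 1, g_estimator=est)) == 0
    t1 = scan_random_sequences(5, 12, 6, 3, g_estimator=est)
    t2 = scan_random_sequences(5, 12, 6, 3, g_estimator=est)
    assert t1.equals(t2)
    assert (t1["a"] == 6).all()


def test_combinatorial_gs_tracks_exact_ordering():
    """The fast g(s) stub must reproduce the exact estimator's ordering
    of sequences by total self-bond weight (its only use in scans)."""
    seqs = [make_block_sequence(6, 1), make_block_sequence(6, 3)]
    exact = [enumerate_gs_exact(s) for s in seqs]
    approx = [approx_gs_combinatorial(s, seed=1) for s in seqs]
    # same support bound and same ordering of sum_s g(s>0)
    for e, a in zip(exact, approx):
        assert a.s_max <= min(3, e.s_max + 1)
    exact_ratio = exact[0].g[1:].sum() / exact[1].g[1:].sum()
    approx_ratio = approx[0].g[1:].sum() / approx[1].g[1:].sum()
    assert (exact_ratio > 1) == (approx_ratio > 1)


# -- material properties ---------------------------------------------------

def test_viscosity_limits_and_scaling():
    base = ViscosityInputs(t_bar=0.0, phi_dense=0.5, beta_eps=1.0, L=24)
    assert viscosity(base) == 0.0
    v1 = viscosity(ViscosityInputs(t_bar=2.0, phi_dense=0.5, beta_eps=1.0,
                                   L=24))
    v2 = viscosity(ViscosityInputs(t_bar=4.0, phi_dense=0.5, beta_eps=1.0,
                                   L=24))
    assert v2 == pytest.approx(4 * v1)
    # explicit value: (phi/L) e^{beta} t^2
    assert v1 == pytest.approx(0.5 / 24 * np.e * 4.0)


def test_diffusivity_proxy():
    assert diffusivity_proxy(2.0) == pytest.approx(0.5)
    assert diffusivity_proxy(1.0) / diffusivity_proxy(2.0) == pytest.approx(2)
    with pytest.raises(ValueError):
        diffusivity_proxy(0.0)
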