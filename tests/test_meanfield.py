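import numpy as np
import pytest

from motiflattice.meanfield import (BoundaryError, MeanFieldParams,
                                    chi_from_j, f_curve, free_energy,
                                    mf_binodal_at, mf_phase_diagram,
                                    minimize_bonds, phi_grid, solve_w)
from motiflattice.single_polymer import DensityOfStates


def toy_g(vals):
    return DensityOfStates("toy", np.arange(len(vals)), vals)


def test_solve_w_closed_form():
    # 5 e^w / (10 + 5 e^w) = 1/3  =>  w = 0
    assert solve_w(toy_g([10, 5]), 1 / 3) == pytest.approx(0.0, abs=1e-10)


def test_solve_w_symmetry():
    # symmetric g on {0,1,2}: s_bar = 1 at w = 0
    assert solve_w(toy_g([7, 3, 7]), 1.0) == pytest.approx(0.0, abs=1e-10)


def test_solve_w_monotone():
    g = toy_g([100, 40, 10, 1])
    ws = [solve_w(g, s) for s in (0.2, 0.7, 1.3, 2.1)]
    assert all(a < b for a, b in zip(ws, ws[1:]))


def test_solve_w_boundary_error():
    with pytest.raises(BoundaryError):
        solve_w(toy_g([10, 5]), 0.0)
    with pytest.raises(BoundaryError):
        solve_w(toy_g([10, 5]), 1.0)


def test_free_energy_zero_density():
    p = MeanFieldParams(g=toy_g([1.0]), L=24, a=12, b=12, beta_eps=1.0,
                        chi=0.0)
    f, comps = free_energy(0.0, 0, 0, p)
    assert f == 0.0


def test_free_energy_no_bond_closed_form():
    # s=t=0, chi=0, g={0:1}: f = (phi/L)log(phi/L) + (1-phi)log(1-phi)
    #                            + (phi/L)(L-1)
    L = 24
    p = MeanFieldParams(g=toy_g([1.0]), L=L, a=12, b=12, beta_eps=1.0,
                        chi=0.0)
    for phi in (0.05, 0.3, 0.8):
        f, _ = free_energy(phi, 0.0, 0.0, p)
        expected = ((phi / L) * np.log(phi / L) + (1 - phi) * np.log(1 - phi)
                    + (phi / L) * (L - 1))
        assert f == pytest.approx(expected, rel=1e-12)


def test_free_energy_slope_in_beta():
    # the bond-energy term is -(phi/L) beta (s + t/2)
    g = toy_g([100, 40, 10, 1])
    phi, s, t = 0.4, 1.0, 2.0
    f1, _ = free_energy(phi, s, t, MeanFieldParams(
        g=g, L=24, a=12, b=12, beta_eps=2.0, chi=0.0))
    f2, _ = free_energy(phi, s, t, MeanFieldParams(
        g=g, L=24, a=12, b=12, beta_eps=5.0, chi=0.0))
    slope = (f2 - f1) / 3.0
    assert slope == pytest.approx(-(phi / 24) * (s + t / 2), rel=1e-10)


def test_free_energy_infeasible_returns_inf():
    p = MeanFieldParams(g=toy_g([1, 1, 1]), L=4, a=2, b=2, beta_eps=1.0)
    f, _ = free_energy(0.5, 1.0, 5.0, p)   # s + t/2 > min(a,b)
    assert f == np.inf


def test_ab_exchange_symmetry():
    """f is invariant under swapping the roles of a and b."""
    g = toy_g([50, 20, 4])
    pa = MeanFieldParams(g=g, L=24, a=16, b=8, beta_eps=1.0)
    pb = MeanFieldParams(g=g, L=24, a=8, b=16, beta_eps=1.0)
    for phi in (0.1, 0.5):
        fa, _ = free_energy(phi, 0.8, 1.4, pa)
        fb, _ = free_energy(phi, 0.8, 1.4, pb)
        assert fa == pytest.approx(fb, rel=1e-12)


def test_minimize_bonds_limits():
    g = toy_g([100, 10, 1])
    # beta = 0, chi = 0, g favoring s=0: without binding energy the
    # trans-bond count follows a law of mass action (t ~ phi, never
    # exactly zero because of the t log t mixing entropy) and stays
    # far from saturation at low density
    p0 = MeanFieldParams(g=g, L=24, a=12, b=12, beta_eps=0.0, chi=0.0)
    st = minimize_bonds(0.005, p0)
    assert st.t_bar < 0.1
    st_dense = minimize_bonds(0.4, p0)
    assert st_dense.s_bar + st_dense.t_bar / 2 < 0.3 * min(12, 12)
    # strong binding: saturation s + t/2 -> min(a, b) = 2
    gsat = toy_g([100, 10, 1])
    psat = MeanFieldParams(g=gsat, L=4, a=2, b=2, beta_eps=12.0, chi=0.0)
    st2 = minimize_bonds(0.6, psat)
    assert st2.s_bar + st2.t_bar / 2 == pytest.approx(2.0, abs=0.05)


def test_purely_entropic_f_is_convex():
    # chi = 0 and no binding advantage: no phase separation at any beta
    p = MeanFieldParams(g=toy_g([1.0]), L=8, a=4, b=4, beta_eps=1.0, chi=0.0)
    assert mf_binodal_at(p, phi_grid(400)) is None


def test_common_tangent_residual_small():
    # an attractive system phase separates; tangent equations hold to 1e-8
    g = toy_g([1000.0, 50.0, 1.0])
    p = MeanFieldParams(g=g, L=6, a=3, b=3, beta_eps=2.2,
                        chi=chi_from_j(0.05))
    out = mf_binodal_at(p, phi_grid(800, phi_max=1.98))
    assert out is not None
    phi1, phi2, resid, slope = out
    assert phi1 < phi2
    assert resid < 1e-8


def test_phase_diagram_widens_with_beta():
    g = toy_g([1000.0, 50.0, 1.0])
    diagram = mf_phase_diagram(g, 6, 3, 3, beta_grid=[2.0, 2.2, 2.4],
                               phis=phi_grid(600, phi_max=1.98),
                               locate_critical=False)
    t = diagram.table
    assert len(t) == 3
    width = t["phi_dense"] - t["phi_dilute"]
    assert width.is_monotonic_increasing
    assert (t["tangent_residual"] < 1e-8).all()
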