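import numpy as np
import pytest

from motiflattice.fixtures import (TOY_TRAJ_MOMENTS, toy_bimodal_histogram,
                                   toy_trajectory_frame)
from motiflattice.phase_analysis import (AboveCriticalError, CriticalPoint,
                                         EmptySelectionError, PhaseDiagram,
                                         double_gaussian_reference,
                                         equal_weight_mu, find_critical_point,
                                         fit_two_gaussians, ising_reference,
                                         phase_slice_stats)


# -- Gaussian mixture fitting ---------------------------------------------

def test_fit_two_gaussians_recovers_planted_mixture():
    n = np.arange(300, dtype=float)
    p = (0.3 * np.exp(-0.5 * ((n - 60) / 9.0) ** 2) / 9.0
         + 0.7 * np.exp(-0.5 * ((n - 200) / 20.0) ** 2) / 20.0)
    gm = fit_two_gaussians(n, p)
    assert gm.w[0] == pytest.approx(0.3, abs=0.01)
    assert gm.mean[0] == pytest.approx(60, abs=1.0)
    assert gm.mean[1] == pytest.approx(200, abs=1.0)
    assert gm.sd[1] == pytest.approx(20, rel=0.1)
    assert gm.separation > 2


# -- equal-weight boundary -------------------------------------------------

def test_equal_weight_on_symmetric_double_gaussian():
    h = toy_bimodal_histogram(seed=0, w1=0.5)
    ew = equal_weight_mu(h, h.beta, mu_window=0.3)
    assert ew.mu_star == pytest.approx(h.mu, abs=2e-3)
    assert ew.weights[0] == pytest.approx(0.5, abs=1e-4)
    V, L = 4096, 12
    assert ew.phi_dilute == pytest.approx(40 * L / V, rel=0.05)
    assert ew.phi_dense == pytest.approx(160 * L / V, rel=0.05)


def test_equal_weight_recovers_known_tilt():
    """An asymmetric mixture has an analytically known equal-weight mu.

    Tilting P(N) by e^{beta dmu N} scales each Gaussian component's
    weight by ~ e^{beta dmu mean} (times a variance term identical for
    equal-sd components), so equal weight is restored at
    dmu = log(w1/w2) / (beta (m2 - m1)).
    """
    h = toy_bimodal_histogram(seed=0, w1=0.7, n1=40.0, n2=160.0, sd=12.0)
    beta = h.beta
    dmu_expected = np.log(0.7 / 0.3) / (beta * (160.0 - 40.0))
    ew = equal_weight_mu(h, beta, mu_window=0.3)
    assert ew.mu_star - h.mu == pytest.approx(dmu_expected, abs=1e-4)
    assert abs(ew.weights[0] - ew.weights[1]) < 1e-6


def test_equal_weight_above_critical_errors():
    # unimodal histogram: no equal-weight point exists
    n = np.arange(201, dtype=float)
    counts = np.zeros((201, 4))
    counts[:, 1] = np.exp(-0.5 * ((n - 90) / 30.0) ** 2)
    from motiflattice import JointHistogram
    h = JointHistogram(counts, -500, 100, 1.0, -5.0, total_sweeps=1,
                       meta={"sequence": "AB" * 6, "V": 4096})
    with pytest.raises(AboveCriticalError):
        equal_weight_mu(h, 1.0, mu_window=0.05)


# -- universal reference ---------------------------------------------------

def test_ising_reference_is_normalized_unit_variance_bimodal():
    grid = np.linspace(-5, 5, 2001)
    p = ising_reference(grid)
    assert np.trapezoid(p, grid) == pytest.approx(1.0, abs=1e-3)
    assert np.trapezoid(p * grid ** 2, grid) == pytest.approx(1.0, abs=1e-2)
    mid = p[len(grid) // 2]
    assert p.max() > 1.2 * mid          # double-peaked
    assert np.allclose(p, p[::-1])      # symmetric


def test_double_gaussian_fallback_normalized():
    grid = np.linspace(-5, 5, 2001)
    p = double_gaussian_reference(grid)
    assert np.trapezoid(p, grid) == pytest.approx(1.0, abs=1e-3)


def test_find_critical_point_self_consistency():
    """Data generated from the reference itself is matched at the
    planted parameters."""
    rng = np.random.default_rng(7)
    beta0, mu0, x0 = 1.0, -5.0, 0.05
    grid = np.linspace(-3.5, 3.5, 71)
    p = ising_reference(grid)
    # order parameter m = N - x E with E = -10 N + noise ridge:
    # construct a joint histogram whose standardized N-distribution is
    # the reference (x contribution kept small)
    n = np.arange(301, dtype=float)
    scale, center = 40.0, 150.0
    pn = np.interp((n - center) / scale, grid, p, left=0, right=0)
    counts = np.zeros((301, 140))
    e_min, e_bin = -4000.0, 30.0
    for i in range(301):
        if pn[i] <= 0:
            continue
        e_mean = -10.0 * i
        for de in (-1, 0, 1):
            eb = int((e_mean - e_min) / e_bin) + de
            w = (0.25, 0.5, 0.25)[de + 1]
            counts[i, eb] += pn[i] * w
    from motiflattice import JointHistogram
    h = JointHistogram(counts * 1e5, e_min, e_bin, beta0, mu0,
                       total_sweeps=1e5, meta={"sequence": "AB", "V": 4096})
    cp = find_critical_point(h, beta_trust=0.05, mu_trust=0.2)
    assert cp.beta_c == pytest.approx(beta0, abs=0.02)
    # the E|N ridge is nearly deterministic (E ~ -10N), so beta and mu
    # are close to degenerate: only the combination 10*beta + beta*mu
    # is sharply identified
    assert 10 * cp.beta_c + cp.beta_c * cp.mu_c == pytest.approx(
        10 * beta0 + beta0 * mu0, abs=0.05)
    assert cp.residual < 5e-3
    assert 0 < cp.phi_c < 2


# -- phase diagram container ----------------------------------------------

def test_phase_diagram_validates_ordering():
    import pandas as pd
    with pytest.raises(ValueError, match="phi_dilute"):
        PhaseDiagram(pd.DataFrame([{"beta_eps": 1.0, "mu_star": -5,
                                    "phi_dilute": 0.5, "phi_dense": 0.1}]))


def test_critical_point_requires_positive_beta():
    with pytest.raises(ValueError):
        CriticalPoint(-1.0, 0.0, 0.0, 0.3, 0.0)


# -- phase slice statistics ------------------------------------------------

def test_phase_slice_recovers_planted_moments():
    V, L = 4096, 12
    traj = toy_trajectory_frame(seed=3, n_snapshots=600, V=V, L=L)
    phi = 50 * L / V
    stats = phase_slice_stats(traj, phi, V, L, tol=0.01)
    m = TOY_TRAJ_MOMENTS
    assert stats["n_snapshots"] == 600     # all snapshots at phi exactly
    assert stats["s_mean"] == pytest.approx(m["s_mean"], rel=0.02)
    assert stats["s_sd"] == pytest.approx(m["s_sd"], rel=0.05)
    assert stats["t_mean"] == pytest.approx(m["t_mean"], rel=0.02)
    assert stats["rg_mean"] == pytest.approx(m["rg_mean"], rel=0.02)
    assert stats["rg_sd"] == pytest.approx(m["rg_sd"], rel=0.05)


def test_phase_slice_empty_selection():
    traj = toy_trajectory_frame(seed=3, n_snapshots=10)
    with pytest.raises(EmptySelectionError):
        phase_slice_stats(traj, 1.9, 4096, 12, tol=0.0)
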