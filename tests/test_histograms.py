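import numpy as np
import pytest

from motiflattice import JointHistogram, MulticanonicalWeight
from motiflattice.montecarlo import build_multicanonical_weight
from motiflattice.phase_analysis import reweight


def make_hist(rng, beta=1.0, mu=-4.0, h=None):
    counts = np.zeros((30, 40))
    idx = rng.integers(0, 30, 200), rng.integers(0, 40, 200)
    np.add.at(counts, idx, rng.random(200) * 10)
    return JointHistogram(counts, e_min=-100.0, e_bin=2.5, beta=beta, mu=mu,
                          h=h, total_sweeps=200,
                          meta={"sequence": "AB", "V": 64})


def test_histogram_text_roundtrip(tmp_path, rng):
    h = make_hist(rng)
    path = tmp_path / "hist.txt"
    h.save(path)
    back = JointHistogram.load(path)
    assert np.allclose(back.counts, h.counts)
    assert back.beta == h.beta and back.mu == h.mu
    assert back.e_min == h.e_min and back.e_bin == h.e_bin
    assert back.meta["sequence"] == "AB"


def test_multicanonical_weight_extends_flat(tmp_path):
    w = MulticanonicalWeight(5, 10, np.linspace(0, 2, 6), beta=1.0)
    assert w(5) == 0.0 and w(10) == 2.0
    assert w(0) == w(5) and w(25) == w(10)   # flat boundary extension
    tab = w.table(20)
    assert tab.shape == (21,) and np.isfinite(tab).all()
    path = tmp_path / "h.txt"
    w.save(path)
    back = MulticanonicalWeight.load(path, beta=1.0)
    assert np.allclose(back.values, w.values)
    assert (back.n_lo, back.n_hi) == (5, 10)


def test_build_weight_flattens_p(rng):
    # h(N) = log P~(N)/beta makes the reweighted distribution flat
    p = np.exp(-0.5 * ((np.arange(50) - 25) / 6.0) ** 2) + 1e-3
    h = build_multicanonical_weight(p, beta=2.0, n_lo=10, n_hi=40)
    assert np.allclose(h.values, np.log(p[10:41]) / 2.0)
    with pytest.raises(ValueError, match="positive"):
        build_multicanonical_weight(np.zeros(50), 1.0, 10, 40)


def test_reweight_identity_and_roundtrip(rng):
    h = make_hist(rng)
    same = reweight(h, h.beta, h.mu, ess_warn=0)
    assert np.allclose(same.p_of_n(), h.p_of_n())
    # round trip: forward then back equals a direct (no-op) reweight
    fwd = reweight(h, 1.1, -3.5, ess_warn=0)
    back = reweight(fwd, h.beta, h.mu, ess_warn=0)
    assert np.allclose(back.counts / back.counts.sum(),
                       h.counts / h.counts.sum())


def test_reweight_pure_mu_shift_multiplies_slices(rng):
    h = make_hist(rng)
    dmu = 0.3
    rw = reweight(h, h.beta, h.mu + dmu, ess_warn=0)
    n = np.arange(h.n_max + 1)
    expected = h.counts * np.exp(h.beta * dmu * n)[:, None]
    assert np.allclose(rw.counts / rw.counts.sum(),
                       expected / expected.sum())


def test_reweight_two_level_boltzmann():
    """Two-state toy: reweighting reproduces hand-computed ratios."""
    counts = np.zeros((3, 2))
    b0, m0 = 1.0, 0.0
    e_lo, e_hi = -20.0, -10.0   # bin centers with e_min=-25, width 10
    # state A: N=1, E=-20; state B: N=2, E=-10, equally occupied at b0,m0
    counts[1, 0] = 1000.0
    counts[2, 1] = 1000.0
    h = JointHistogram(counts, e_min=-25.0, e_bin=10.0, beta=b0, mu=m0,
                       total_sweeps=2000, meta={"sequence": "AB", "V": 64})
    b1, m1 = 1.3, 0.7
    rw = reweight(h, b1, m1, ess_warn=0)
    w_a = np.exp(-(b1 - b0) * e_lo + (b1 * m1 - b0 * m0) * 1)
    w_b = np.exp(-(b1 - b0) * e_hi + (b1 * m1 - b0 * m0) * 2)
    p = rw.p_of_n()
    assert p[1] == pytest.approx(w_a / (w_a + w_b), rel=1e-12)
    assert p[2] == pytest.approx(w_b / (w_a + w_b), rel=1e-12)


def test_reweight_low_ess_warns(rng):
    h = make_hist(rng)
    with pytest.warns(UserWarning, match="effective sample size"):
        reweight(h, h.beta + 5.0, h.mu)
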