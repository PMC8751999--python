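import numpy as np
import pytest

from motiflattice import MotifSequence, make_block_sequence
from motiflattice.single_polymer import (DensityOfStates, enumerate_gs_exact,
                                         estimate_gs_mc, multihistogram_gs,
                                         rosenbluth_total)


def test_enumerate_dimers():
    assert enumerate_gs_exact(MotifSequence("AB")).as_dict() == {0: 12, 1: 1}
    assert enumerate_gs_exact(MotifSequence("AA")).as_dict() == {0: 12}


@pytest.mark.parametrize("L,ell", [(4, 1), (4, 2), (6, 1), (6, 3)])
def test_enumeration_total_matches_rosenbluth(L, ell):
    """The Rosenbluth estimator is an unbiased count of all valid
    conformations, so it must agree with the exhaustive total."""
    seq = make_block_sequence(L, ell)
    d = enumerate_gs_exact(seq)
    total, sem = rosenbluth_total(seq, n_samples=3000, seed=11)
    assert d.total() == pytest.approx(total, abs=max(4 * sem, 1e-9))
    assert d.s_max <= min(seq.a, seq.b)


def test_support_bound():
    # a lopsided sequence: s cannot exceed min(a, b) = 1
    d = enumerate_gs_exact(MotifSequence("AAAB"))
    assert d.s_max <= 1
    assert all(g == 0 for s, g in d.as_dict().items() if s > 1)


def test_enumeration_budget_guard():
    with pytest.raises(ValueError, match="budget"):
        enumerate_gs_exact(make_block_sequence(24, 3))


def test_density_of_states_roundtrip(tmp_path):
    d = DensityOfStates("x", [0, 1, 2], [10.0, 5.0, 1.0], method="exact",
                        meta={"note": "toy"})
    path = tmp_path / "gs.txt"
    d.save(path)
    back = DensityOfStates.load(path)
    assert np.allclose(back.g, d.g)
    assert back.method == "exact" and back.label == "x"


def test_multihistogram_single_beta_reduces_to_reweighting():
    """With one histogram, g(s) ~ P_beta(s) e^{-beta s} exactly."""
    g_true = np.array([100.0, 30.0, 4.0])
    beta = 0.8
    p = g_true * np.exp(beta * np.arange(3))
    counts = (1e6 * p / p.sum())[None, :]
    g = multihistogram_gs(counts, [beta])
    expected = g_true / g_true.sum()
    assert np.allclose(g, expected, rtol=1e-10)


def test_multihistogram_beta_order_invariance():
    rng = np.random.default_rng(0)
    g_true = np.array([1000.0, 400.0, 60.0, 3.0])
    betas = np.array([0.2, 0.7, 1.3, 2.0])
    counts = np.empty((4, 4))
    for i, b in enumerate(betas):
        p = g_true * np.exp(b * np.arange(4))
        counts[i] = 5e5 * p / p.sum()
    g1 = multihistogram_gs(counts, betas)
    perm = [2, 0, 3, 1]
    g2 = multihistogram_gs(counts[perm], betas[perm])
    assert np.allclose(g1, g2, rtol=1e-8)


def test_multihistogram_detects_gap():
    counts = np.zeros((2, 6))
    counts[0, 0] = 100   # only s=0 sampled cold... and
    counts[1, 5] = 100   # only s=5 sampled hot: no overlap
    with pytest.raises(RuntimeError, match="overlap"):
        multihistogram_gs(counts, [0.5, 1.0])


@pytest.mark.parametrize("L,ell", [(6, 1), (6, 3)])
def test_mc_estimate_matches_exact_for_short_chains(L, ell):
    seq = make_block_sequence(L, ell)
    exact = enumerate_gs_exact(seq)
    est = estimate_gs_mc(seq, steps=600_000, seed=9, sample_every=10)
    mask = exact.g > 0
    rel = np.abs(est.g[mask] - exact.g[mask]) / exact.g[mask]
    assert rel.max() < 0.05


def test_block_ordering_of_gs_for_L24():
    """Smaller blocks have more conformations at every supported s."""
    g2 = estimate_gs_mc(make_block_sequence(24, 2), steps=150_000, seed=21)
    g12 = estimate_gs_mc(make_block_sequence(24, 12), steps=150_000, seed=22)
    both = (g2.g > 0) & (g12.g > 0)
    assert both.any()
    assert (g2.g[both] > g12.g[both]).all()
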