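"""End-to-end engine behavior: determinism, invariant preservation,
histogram bookkeeping.  (Equilibrium correctness against exact
enumeration is exercised in the acceptance suite.)"""

import numpy as np
import pytest

from motiflattice import FccLattice, MotifSequence, make_block_sequence
from motiflattice.montecarlo import (MoveMixture, RunParams, initialize,
                                     run_gce)


def test_initialize_places_requested_polymers():
    lat = FccLattice((30, 30, 30))
    seq = make_block_sequence(24, 3)
    cfg = initialize(lat, seq, N0=100, seed=1)
    assert cfg.N == 100
    cfg.validate()   # no forbidden overlaps, registry consistent
    # straight-line starts cannot bond with themselves (crossings of
    # different chains may still form trans-bonds)
    from motiflattice import count_bonds
    s, t = count_bonds(cfg)
    assert (s == 0).all()


def test_initialize_empty_and_overfull():
    lat = FccLattice((4, 4, 4))
    seq = MotifSequence("AB")
    cfg = initialize(lat, seq, N0=0, seed=1)
    assert cfg.N == 0 and cfg.energy == 0.0
    with pytest.raises(ValueError):
        initialize(lat, seq, N0=100, seed=1)


def test_run_is_deterministic_and_preserves_invariants():
    lat = FccLattice((5, 5, 5))
    seq = MotifSequence("ABBA")
    params = RunParams(beta_eps=1.0, mu_over_eps=-5.0, steps=120_000,
                       seed=17, n_init=3, sample_every=25, anneal=[],
                       traj_every=5000)
    res1 = run_gce(lat, seq, params)
    res2 = run_gce(lat, seq, params)
    assert np.array_equal(res1.histogram.counts, res2.histogram.counts)
    assert res1.trajectory.equals(res2.trajectory)
    res1.config.validate()   # energy cache and occupancy exact at the end
    # different seed gives a different realization
    params3 = RunParams(beta_eps=1.0, mu_over_eps=-5.0, steps=120_000,
                        seed=18, n_init=3, sample_every=25, anneal=[])
    res3 = run_gce(lat, seq, params3)
    assert not np.array_equal(res1.histogram.counts, res3.histogram.counts)


def test_histogram_totals_conserve_counts():
    lat = FccLattice((4, 4, 4))
    seq = MotifSequence("AB")
    params = RunParams(beta_eps=0.8, mu_over_eps=-4.0, steps=100_000,
                       seed=5, n_init=1, sample_every=20, anneal=[],
                       therm_fraction=0.2)
    res = run_gce(lat, seq, params)
    expected = (100_000 - int(100_000 * 0.2)) // 20
    assert res.histogram.total_sweeps == expected
    assert res.histogram.counts.sum() == expected


def test_trajectory_bond_bookkeeping():
    # s/t sums recorded by the engine agree with the partition rule
    lat = FccLattice((5, 5, 5))
    seq = MotifSequence("ABAB")
    params = RunParams(beta_eps=1.2, mu_over_eps=-4.0, steps=150_000,
                       seed=9, n_init=4, sample_every=50, anneal=[],
                       traj_every=1000)
    res = run_gce(lat, seq, params)
    t = res.trajectory
    assert len(t) > 0
    # each trans-bond is shared by two polymers
    assert np.allclose(t["t_sum"], 2 * t["t_total"])
    assert (t["N"] * seq.L / lat.V <= 2).all()


def test_anneal_schedule_defaults():
    p = RunParams(beta_eps=1.0, mu_over_eps=-5.0, steps=1_000_000, seed=0)
    sched = p.anneal_schedule()
    assert len(sched) == 10
    betas = [b for b, _ in sched]
    assert betas[0] == pytest.approx(0.5 * 2 ** 0.1, rel=1e-6)
    assert betas[-1] == pytest.approx(1.0)
    assert sum(s for _, s in sched) == pytest.approx(100_000, rel=0.01)


def test_multicanonical_flattens_small_system():
    """Attaching h(N) = log P(N)/beta flattens the sampled P~(N)."""
    from motiflattice.montecarlo import build_multicanonical_weight
    lat = FccLattice((4, 4, 4))
    seq = MotifSequence("AB")
    params = RunParams(beta_eps=1.0, mu_over_eps=-4.5, steps=400_000,
                       seed=11, n_init=1, sample_every=20, anneal=[])
    flat = run_gce(lat, seq, params)
    p = flat.diagnostics["p_n"]
    p = p / p.sum()
    lo, hi = 0, int(np.max(np.nonzero(p)))
    h = build_multicanonical_weight(np.maximum(p, 1e-12), 1.0, lo, hi)
    res2 = run_gce(lat, seq, params, h=h)
    p2 = res2.diagnostics["p_n"]
    p2 = p2 / p2.sum()
    # the reweighted-flat run must cover the range much more evenly
    ratio = p2[lo:hi + 1].max() / np.maximum(p2[lo:hi + 1].min(), 1e-12)
    ratio0 = p[lo:hi + 1].max() / np.maximum(p[lo:hi + 1].min(), 1e-12)
    assert ratio < 0.1 * ratio0
    # and removing h by reweighting recovers the original P(N)
    from motiflattice.phase_analysis import _true_logp
    logp = _true_logp(res2.histogram, 1.0, -4.5)
    vis = np.isfinite(logp) & (p > 0)
    rec = np.exp(logp[vis] - logp[vis].max())
    rec = rec / rec.sum()
    orig = p[vis] / p[vis].sum()
    assert np.abs(rec - orig).max() < 0.05
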