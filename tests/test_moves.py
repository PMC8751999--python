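"""Proposal machinery: candidate enumeration, detailed balance factors,
configurational-bias Rosenbluth weights, and acceptance probabilities."""

import math

import numpy as np
import pytest

from motiflattice import (FccLattice, LatticeConfig, MotifSequence,
                          acceptance_probability, cbmc_insert,
                          deletion_rosenbluth)
from motiflattice.montecarlo import (MoveMixture, corner_candidates,
                                     expansion_targets, find_clusters,
                                     propose_cluster_translate,
                                     propose_local_move)


# -- move mixture ----------------------------------------------------------

def test_mixture_enforces_twelve_to_one():
    m = MoveMixture()
    assert m.expansion == pytest.approx(12 * m.contraction)
    assert m.as_array().sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="12x"):
        MoveMixture(contraction=0.1, expansion=0.1)


# -- contraction / expansion asymmetry -------------------------------------

def test_expansion_has_twelve_predecessor_states(lat6):
    """Twelve expanded states feed one contracted state, per mover."""
    ab = MotifSequence("AB")
    u = int(lat6.ravel(2, 2, 2))
    cfg = LatticeConfig.from_polymers(lat6, ab, [[u, u]])
    targets = expansion_targets(cfg, 0, 0)
    per_mover = {}
    for mover, site in targets:
        per_mover.setdefault(mover, set()).add(site)
    assert set(per_mover) == {0, 1}
    assert all(len(sites) == 12 for sites in per_mover.values())


def test_contraction_null_on_same_type_pair(lat6, rng):
    aa = MotifSequence("AA")
    u = int(lat6.ravel(2, 2, 2))
    v = int(lat6.neighbors(u)[0])
    cfg = LatticeConfig.from_polymers(lat6, aa, [[u, v]])
    mix = MoveMixture(end=0, corner=0, reptation=0, contraction=1 / 13,
                      expansion=12 / 13, cluster=0, insert=0, delete=0)
    hits = 0
    for _ in range(50):
        prop = propose_local_move(cfg, mix, rng)
        if prop.move == "contraction":
            hits += 1
            assert not prop.valid
    assert hits > 0


def test_contraction_expansion_detailed_balance(lat6):
    """pi(x) P(x->y) acc = pi(y) P(y->x) acc for a dimer pair of states.

    x: adjacent AB dimer; y: contracted dimer.  With expansion proposed
    at 12x the contraction rate, the specific-state proposal
    probabilities are equal, so the flow ratio must equal the Boltzmann
    factor exactly.
    """
    beta, J = 0.9, 0.05
    ab = MotifSequence("AB")
    u = int(lat6.ravel(2, 2, 2))
    v = int(lat6.neighbors(u)[0])
    ex = LatticeConfig.from_polymers(lat6, ab, [[u, v]], J=J)   # expanded
    co = LatticeConfig.from_polymers(lat6, ab, [[u, u]], J=J)   # contracted
    dH = co.energy - ex.energy
    mix = MoveMixture()
    # specific-state proposal probabilities (N=1 polymer, L-1=1 pair)
    p_x_to_y = mix.contraction * (1 / 1) * (1 / 1) * (1 / 2)
    p_y_to_x = mix.expansion * (1 / 1) * (1 / 1) * (1 / 2) * (1 / 12)
    acc_xy = min(1.0, math.exp(-beta * dH))
    acc_yx = min(1.0, math.exp(+beta * dH))
    pi_x = math.exp(-beta * ex.energy)
    pi_y = math.exp(-beta * co.energy)
    lhs = pi_x * p_x_to_y * acc_xy
    rhs = pi_y * p_y_to_x * acc_yx
    assert lhs == pytest.approx(rhs, rel=1e-12)


# -- corner move -----------------------------------------------------------

def test_corner_candidates_are_common_neighbors(lat6):
    seq = MotifSequence("ABA")
    u0 = int(lat6.ravel(2, 2, 2))
    u = int(lat6.neighbors(u0)[0])
    common = [int(w) for w in lat6.common_neighbors(u0, u)]
    u1 = common[0]
    cfg = LatticeConfig.from_polymers(lat6, seq, [[u0, u, u1]])
    cands = corner_candidates(cfg, 0, 1)
    expected = set(lat6.common_neighbors(u0, u1).tolist()) - {u, u0, u1}
    assert set(cands) == expected


def test_corner_candidates_with_coincident_flanks(lat6):
    # hairpin A-B-B with both flanks of the middle monomer on one site
    seq = MotifSequence("ABB")
    u0 = int(lat6.ravel(2, 2, 2))
    u = int(lat6.neighbors(u0)[0])
    cfg = LatticeConfig.from_polymers(lat6, seq, [[u0, u, u0]])
    cands = corner_candidates(cfg, 0, 1)
    assert set(cands) == set(lat6.neighbors(u0).tolist()) - {u}


# -- CBMC ------------------------------------------------------------------

def test_cbmc_weights_on_empty_lattice():
    lat = FccLattice((8, 8, 8))
    rng = np.random.default_rng(5)
    # alternating sequence: every step has 12 neighbors + the same-site
    # bond option
    ab = MotifSequence("AB")
    cfg = LatticeConfig(lat, ab)
    for _ in range(5):
        sites, R = cbmc_insert(cfg, rng)
        assert R == pytest.approx(13.0)
    # longer alternating chains: the first step has all 13 options; from
    # then on the previously placed same-type monomer always blocks one
    # continuation (it is adjacent to, or shares, the current site), so
    # the maximum Rosenbluth weight is 13 * 12^(L-2)
    ab6 = MotifSequence("ABABAB")
    cfg6 = LatticeConfig(lat, ab6)
    draws = [cbmc_insert(cfg6, rng)[1] for _ in range(300)]
    rmax = 13.0 * 12.0 ** 4
    assert max(draws) == pytest.approx(rmax)
    assert all(r <= rmax + 1e-9 for r in draws)
    assert np.mean(draws) > 0.85 * rmax
    # A-block start: no same-site option between two A's, and the bond
    # option at step two reuses the first monomer's site
    aab = MotifSequence("AAB")
    cfg2 = LatticeConfig(lat, aab)
    sites, R = cbmc_insert(cfg2, rng)
    assert R == pytest.approx(12.0 * 13.0)


def test_cbmc_insert_respects_occupancy(lat4):
    # a fully bonded site cannot receive the head
    ab = MotifSequence("AB")
    cfg = LatticeConfig(lat4, ab)
    for s in range(lat4.V):
        cfg.add_polymer([s, s])   # saturate every site with an A-B pair
    rng = np.random.default_rng(0)
    assert cbmc_insert(cfg, rng) is None


def test_insertion_deletion_reciprocity(lat6, rng):
    """Deleting a freshly inserted polymer reproduces the insertion's R."""
    seq = MotifSequence("ABBA")
    cfg = LatticeConfig(lat6, seq)
    # crowd the box a little first
    for _ in range(8):
        out = cbmc_insert(cfg, rng)
        if out is not None:
            cfg.add_polymer(out[0])
    out = cbmc_insert(cfg, rng)
    assert out is not None
    sites, R = out
    p = cfg.add_polymer(sites)
    assert deletion_rosenbluth(cfg, p) == pytest.approx(R, rel=1e-12)
    assert deletion_rosenbluth(cfg, p) >= 1.0
    cfg.validate()


# -- acceptance probabilities ----------------------------------------------

def test_acceptance_probability_dn0():
    assert acceptance_probability(0.0, 0, None, 5, 64, 2, 1.0, -3.0) == 1.0
    assert acceptance_probability(-2.5, 0, None, 5, 64, 2, 1.0, -3.0) == 1.0
    a = acceptance_probability(1.0, 0, None, 5, 64, 2, 2.0, -3.0)
    assert a == pytest.approx(math.exp(-2.0))


def test_acceptance_probability_insertion_into_empty():
    V, L, beta, mu = 64, 2, 1.0, -3.0
    R = 13.0 ** (L - 1)
    a = acceptance_probability(0.0, +1, R, 0, V, L, beta, mu)
    assert a == pytest.approx(min(1.0, V * math.exp(beta * mu)))


def test_acceptance_satisfies_insert_delete_balance():
    """Pacc(+1)/Pacc(-1) = [V R/(N+1)] 13^-(L-1) exp(-beta(dH - mu))."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        V, L = 216, 4
        N = int(rng.integers(0, 20))
        R = float(rng.uniform(1, 13.0 ** 3))
        dH = float(rng.normal(0, 3))
        beta = float(rng.uniform(0.3, 2))
        mu = float(rng.normal(-5, 2))
        up = acceptance_probability(dH, +1, R, N, V, L, beta, mu)
        dn = acceptance_probability(-dH, -1, R, N + 1, V, L, beta, mu)
        expected = (V * R / (N + 1)) / 13.0 ** (L - 1) * math.exp(
            -beta * (dH - mu))
        assert up / dn == pytest.approx(expected, rel=1e-10)


def test_acceptance_rejects_bad_inputs():
    with pytest.raises(ValueError):
        acceptance_probability(float("nan"), 0, None, 1, 8, 2, 1.0, 0.0)
    with pytest.raises(ValueError):
        acceptance_probability(0.0, 2, 1.0, 1, 8, 2, 1.0, 0.0)
    with pytest.raises(ValueError):
        acceptance_probability(0.0, 1, None, 1, 8, 2, 1.0, 0.0)


# -- cluster moves ---------------------------------------------------------

def test_cluster_connectivity_via_bonds(lat6):
    ab = MotifSequence("AB")
    u = int(lat6.ravel(1, 1, 1))
    v = int(lat6.neighbors(u)[0])
    w = int(lat6.ravel(4, 4, 4))
    # chain 0 and 1 share a bond site; chain 2 is isolated
    cfg = LatticeConfig.from_polymers(
        lat6, ab, [[u, v], [int(lat6.neighbors(u)[5]), u], [w, w]])
    clusters = find_clusters(cfg)
    assert sorted(map(tuple, clusters)) == [(0, 1), (2,)]


def test_cluster_translate_conserves_bonds(lat6, rng):
    ab = MotifSequence("AB")
    u = int(lat6.ravel(1, 1, 1))
    cfg = LatticeConfig.from_polymers(
        lat6, ab, [[u, int(lat6.neighbors(u)[0])],
                   [int(lat6.neighbors(u)[5]), u]])
    for _ in range(20):
        prop = propose_cluster_translate(cfg, rng)
        if prop.valid:
            assert set(prop.detail["cluster"]) == {0, 1}
    cfg.validate()


def test_isolated_polymer_translation_is_free(lat6, rng):
    ab = MotifSequence("AB")
    u = int(lat6.ravel(3, 3, 3))
    cfg = LatticeConfig.from_polymers(lat6, ab, [[u, int(lat6.neighbors(u)[0])]])
    prop = propose_cluster_translate(cfg, rng)
    assert prop.valid and prop.delta_h == pytest.approx(0.0)


# -- local move proposals leave the state unchanged ------------------------

def test_proposals_do_not_mutate(lat6, rng):
    seq = MotifSequence("ABAB")
    u = int(lat6.ravel(2, 2, 2))
    chain = [u]
    for _ in range(3):
        chain.append(int(lat6.neighbors(chain[-1])[0]))  # straight line
    cfg = LatticeConfig.from_polymers(lat6, seq, [chain])
    snapshot = cfg.pos.copy()
    e0 = cfg.energy
    mix = MoveMixture()
    for _ in range(200):
        propose_local_move(cfg, mix, rng)
    assert np.array_equal(cfg.pos, snapshot)
    assert cfg.energy == e0
    cfg.validate()
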